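"""Complex structural variants: 18 rearrangement templates.

A complex SV (CSV) is a single event composed of multiple proximal simple
edits — e.g. ``delINV`` is a deletion immediately followed by an inversion.
Each template is a data-driven component plan laid out left-to-right on the
reference with small random gaps (default 0-100 bp) between components; the
whole composite reserves every component interval, so composites obey the
same global non-overlap invariant as simple variants.

Component kinds:

``del``, ``inv``
    consume a segment and delete / reverse-complement it;
``dup``
    tandem duplication of a segment (extra copies immediately 3');
``invdup``
    tandem duplication whose extra copy is inverted;
``dispdup`` / ``invdispdup``
    one (optionally inverted) copy of a segment inserted at a distant point
    downstream of the segment;
``ins``
    novel random sequence inserted at a point.

The template identifiers (ID1..ID18) follow published complex-SV
taxonomies; the registry is data, so alternative definitions drop in
without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_model import MIN_SV_LEN, OccupancyMask, OverlapError, VariantRecord
from .distribution_learning import LengthDistribution
from .sampling_engine import random_dna, sample_length

logger = logging.getLogger("svforge")

SEGMENT_KINDS = {"del", "inv", "dup", "invdup"}
POINT_SOURCE_KINDS = {"dispdup", "invdispdup"}  # segment + distant dest point
POINT_KINDS = {"ins"}


@dataclass(frozen=True)
class CSVTemplate:
    """One complex-SV archetype: an ordered plan of simple-edit kinds."""

    id: str
    name: str
    plan: tuple[str, ...]
    copies: int = 2  # total tandem copies for 'dup'-kind components

    def __post_init__(self) -> None:
        if not self.plan:
            raise ValueError("template requires at least one component")
        for kind in self.plan:
            if kind not in SEGMENT_KINDS | POINT_SOURCE_KINDS | POINT_KINDS:
                raise ValueError(f"unknown component kind {kind!r}")

    @property
    def n_components(self) -> int:
        return len(self.plan)


_REGISTRY: tuple[CSVTemplate, ...] = (
    CSVTemplate("ID1", "dupINV", ("dup", "inv")),
    CSVTemplate("ID2", "INVdup", ("inv", "dup")),
    CSVTemplate("ID3", "dupINVdup", ("dup", "inv", "dup")),
    CSVTemplate("ID4", "delINV", ("del", "inv")),
    CSVTemplate("ID5", "INVdel", ("inv", "del")),
    CSVTemplate("ID6", "delINVdel", ("del", "inv", "del")),
    CSVTemplate("ID7", "delINVdup", ("del", "inv", "dup")),
    CSVTemplate("ID8", "dupINVdel", ("dup", "inv", "del")),
    CSVTemplate("ID9", "tandem-inverted-duplication", ("invdup",)),
    CSVTemplate("ID10", "dispersed-duplication", ("dispdup",)),
    CSVTemplate("ID11", "inverted-dispersed-duplication", ("invdispdup",)),
    CSVTemplate("ID12", "deletion+dispersed-duplication", ("del", "dispdup")),
    CSVTemplate(
        "ID13", "deletion+inverted-dispersed-duplication", ("del", "invdispdup")
    ),
    CSVTemplate("ID14", "multi-copy-tandem-duplication", ("dup",), copies=3),
    CSVTemplate(
        "ID15", "deletion-flanked-inversion-pair", ("del", "inv", "inv", "del")
    ),
    CSVTemplate("ID16", "deletion+insertion", ("del", "ins")),
    CSVTemplate("ID17", "duplication+deletion", ("dup", "del")),
    CSVTemplate("ID18", "insertion-within-inversion", ("inv", "ins", "inv")),
)


def catalog() -> list[CSVTemplate]:
    """The 18 supported complex-SV templates."""
    return list(_REGISTRY)


def get_template(csv_id: str) -> CSVTemplate:
    for t in _REGISTRY:
        if t.id == csv_id:
            return t
    raise KeyError(f"unknown CSV template {csv_id!r}")


def build_csv(
    template: CSVTemplate,
    anchor: int,
    length_params: LengthDistribution | tuple[int, int],
    mask: OccupancyMask,
    rng: np.random.Generator,
    vid: int = 0,
    gap_range: tuple[int, int] = (0, 100),
    dest_offset_range: tuple[int, int] = (MIN_SV_LEN, 1000),
) -> VariantRecord:
    """Instantiate a template at ``anchor``, reserving all component intervals.

    Components are laid left-to-right from ``anchor`` with independent gaps
    drawn from ``gap_range``; each component's length comes from
    ``length_params`` (a learned distribution or a uniform range).
    Dispersed-duplication destinations land ``dest_offset_range`` bp past the
    plan's right edge.  All reservations are atomic: if any interval is
    occupied, nothing is reserved and :class:`OverlapError` propagates so the
    caller can retry at a new anchor.
    """

    def gap() -> int:
        lo, hi = gap_range
        return int(rng.integers(lo, hi + 1))

    cursor = anchor
    layout: list[tuple[str, int, int, int | None, int]] = []
    for kind in template.plan:
        if layout:
            cursor += gap()
        length = sample_length(length_params, rng)
        if kind in POINT_KINDS:
            layout.append((kind, cursor, cursor + 1, None, length))
            cursor += 1
        elif kind in POINT_SOURCE_KINDS:
            seg_end = cursor + length
            lo, hi = dest_offset_range
            dest = seg_end + int(rng.integers(lo, hi + 1))
            layout.append((kind, cursor, seg_end, dest, length))
            cursor = seg_end
        else:
            layout.append((kind, cursor, cursor + length, None, length))
            cursor += length
            if kind in ("dup", "invdup"):
                cursor += 1  # skip the reserved tandem copy-insertion point

    intervals = []
    for kind, s, e, dest, _ in layout:
        intervals.append((s, e))
        if dest is not None:
            intervals.append((dest, dest + 1))
        elif kind in ("dup", "invdup"):
            intervals.append((e, e + 1))  # tandem copy-insertion point
    if any(e > mask.length for _, e in intervals):
        raise OverlapError("composite extends past the end of the sequence")
    mask.reserve_all(intervals)  # atomic: raises OverlapError without reserving

    components: list[VariantRecord] = []
    for idx, (kind, s, e, dest, length) in enumerate(layout, start=1):
        common = dict(id=vid * 1000 + idx, csv_type=template.id, csv_index=idx)
        if kind == "del":
            rec = VariantRecord(vtype="DEL", start=s, end=e, length=length, **common)
        elif kind == "inv":
            rec = VariantRecord(vtype="INV", start=s, end=e, length=length, **common)
        elif kind == "dup":
            rec = VariantRecord(
                vtype="DUP", start=s, end=e, length=length, dest=e,
                copies=template.copies, **common,
            )
        elif kind == "invdup":
            rec = VariantRecord(
                vtype="DUP", start=s, end=e, length=length, dest=e,
                copies=template.copies, inverted=True, **common,
            )
        elif kind in POINT_SOURCE_KINDS:
            rec = VariantRecord(
                vtype="DUP", start=s, end=e, length=length, dest=dest,
                copies=2, inverted=(kind == "invdispdup"), **common,
            )
        else:  # ins
            rec = VariantRecord(
                vtype="INS", start=s, end=s, length=length,
                payload=random_dna(length, rng), **common,
            )
        components.append(rec)

    span_end = max(e for _, e in intervals)
    return VariantRecord(
        id=vid,
        vtype="CSV",
        start=anchor,
        end=span_end,
        length=span_end - anchor,
        components=components,
        csv_type=template.id,
    )
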