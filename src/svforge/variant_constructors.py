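"""Builders for simple variant records and application of a finalized set.

Every simple variant reduces to one or two *replace primitives*
``(start, end, replacement)`` on the reference: a deletion replaces its
interval with nothing, an insertion replaces an empty interval with its
payload, an inversion with the reverse complement, and so on.  Because the
occupancy mask guarantees the consumed intervals are pairwise disjoint, the
primitives commute and can be applied in a single ascending sweep per
haplotype, recording donor coordinates as the running offset accumulates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    OccupancyMask,
    OverlapError,
    VariantRecord,
    reverse_complement,
)

logger = logging.getLogger("svforge")


# ---------------------------------------------------------------------------
# Record builders (reserve their footprint on construction)
# ---------------------------------------------------------------------------

def make_deletion(
    mask: OccupancyMask, start: int, length: int, vid: int = 0, small: bool = False
) -> VariantRecord:
    mask.reserve(start, start + length)
    return VariantRecord(
        id=vid,
        vtype="SMALL_DEL" if small else "DEL",
        start=start,
        end=start + length,
        length=length,
    )


def make_insertion(
    mask: OccupancyMask, start: int, payload: str, vid: int = 0, small: bool = False
) -> VariantRecord:
    if not payload:
        raise ValueError("insertion payload must be non-empty")
    # point events reserve one base so later variants cannot collide
    mask.reserve(start, start + 1)
    return VariantRecord(
        id=vid,
        vtype="SMALL_INS" if small else "INS",
        start=start,
        end=start,
        length=len(payload),
        payload=payload,
    )


def make_inversion(
    mask: OccupancyMask, start: int, length: int, vid: int = 0
) -> VariantRecord:
    mask.reserve(start, start + length)
    return VariantRecord(
        id=vid, vtype="INV", start=start, end=start + length, length=length
    )


def make_tandem_duplication(
    mask: OccupancyMask,
    src_start: int,
    src_len: int,
    copies: int = 2,
    vid: int = 0,
    inverted: bool = False,
) -> VariantRecord:
    """Duplicate ``[src_start, src_start+src_len)`` to ``copies`` total copies,
    the extra copies inserted immediately 3' of the source segment."""
    if copies < 2:
        raise ValueError("a duplication needs at least 2 total copies")
    end = src_start + src_len
    if end + 1 > mask.length:
        raise OverlapError("no room for the tandem copy insertion point")
    # the 1 bp insertion point is reserved so no other edit can share it
    mask.reserve_all([(src_start, end), (end, end + 1)])
    return VariantRecord(
        id=vid,
        vtype="DUP",
        start=src_start,
        end=end,
        length=src_len,
        dest=end,
        copies=copies,
        inverted=inverted,
    )


def make_dispersed_duplication(
    mask: OccupancyMask,
    src_start: int,
    src_len: int,
    dest: int,
    vid: int = 0,
    inverted: bool = False,
) -> VariantRecord:
    """One extra copy of the source segment inserted at a distant point."""
    end = src_start + src_len
    if src_start <= dest < end:
        raise ValueError("duplication destination inside the source segment")
    mask.reserve_all([(src_start, end), (dest, dest + 1)])
    return VariantRecord(
        id=vid,
        vtype="DUP",
        start=src_start,
        end=end,
        length=src_len,
        dest=dest,
        copies=2,
        inverted=inverted,
    )


def make_translocation(
    mask: OccupancyMask,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
    balanced: bool,
    vid: int = 0,
    unbalanced_copy: bool = False,
) -> VariantRecord:
    """Intrachromosomal translocation of two disjoint regions.

    Balanced: A and B exchange places (total length conserved).  Unbalanced:
    A's bases are lost and B's bases land at A's start; by default B is
    *moved* from its source (donor shrinks by ``|A|``), with
    ``unbalanced_copy=True`` B is copied and also kept in place (donor
    changes by ``|B| - |A|``).
    """
    (a1, a2), (b1, b2) = region_a, region_b
    if a1 >= a2 or b1 >= b2:
        raise ValueError("translocation regions must be non-empty")
    if max(a1, b1) < min(a2, b2):
        raise ValueError("translocation regions must be disjoint")
    mask.reserve_all([region_a, region_b])
    return VariantRecord(
        id=vid,
        vtype="TRA_BAL" if balanced else "TRA_UNBAL",
        start=a1,
        end=a2,
        length=a2 - a1,
        region_b=(b1, b2),
        copy_b=unbalanced_copy and not balanced,
    )


def make_snp(
    mask: OccupancyMask, pos: int, ref_base: str, alt_base: str, vid: int = 0
) -> VariantRecord:
    if alt_base == ref_base:
        raise ValueError("SNP alternative equals the reference base")
    mask.reserve(pos, pos + 1)
    return VariantRecord(
        id=vid, vtype="SNP", start=pos, end=pos + 1, length=1, payload=alt_base
    )


# ---------------------------------------------------------------------------
# Replace primitives and donor construction
# ---------------------------------------------------------------------------

def edits_for(record: VariantRecord, bases: str) -> list[tuple[int, int, str]]:
    """Expand a variant record into replace primitives on the reference."""
    if record.is_composite:
        out: list[tuple[int, int, str]] = []
        for comp in record.components:
            out.extend(edits_for(comp, bases))
        return out
    t = record.vtype
    s, e = record.start, record.end
    if t in ("DEL", "SMALL_DEL"):
        return [(s, e, "")]
    if t in ("INS", "SMALL_INS"):
        return [(s, s, record.payload or "")]
    if t == "INV":
        return [(s, e, reverse_complement(bases[s:e]))]
    if t == "DUP":
        seg = bases[s:e]
        copy = reverse_complement(seg) if record.inverted else seg
        dest = record.dest if record.dest is not None else e
        return [(dest, dest, copy * (record.copies - 1))]
    if t == "TRA_BAL":
        b1, b2 = record.region_b
        return [(s, e, bases[b1:b2]), (b1, b2, bases[s:e])]
    if t == "TRA_UNBAL":
        b1, b2 = record.region_b
        if record.copy_b:  # B stays in place; only A is rewritten
            return [(s, e, bases[b1:b2])]
        return [(s, e, bases[b1:b2]), (b1, b2, "")]
    if t == "SNP":
        return [(s, s + 1, record.payload or "")]
    raise ValueError(f"unknown variant type {t}")


@dataclass
class CoordinateMap:
    """Donor coordinates of each applied variant, per haplotype.

    ``positions[h][variant_id] = (donor_start, donor_end)`` for the variant's
    primary edit on haplotype ``h``; variants absent from a haplotype have no
    entry there.  ``donor_lengths[h]`` is the resulting sequence length.
    """

    ploidy: int
    positions: list[dict] = field(default_factory=list)
    donor_lengths: list[int] = field(default_factory=list)

    def lookup(self, hap: int, variant_id: int) -> tuple[int, int] | None:
        return self.positions[hap].get(variant_id)


def apply_edits(bases: str, edits: list[tuple[int, int, str]]) -> tuple[str, list]:
    """Apply disjoint replace primitives in one ascending sweep.

    Returns the edited sequence and, aligned with the (sorted) edit list,
    the donor-coordinate interval each replacement occupies.
    """
    ordered = sorted(edits, key=lambda t: (t[0], t[1]))
    for (s1, e1, _), (s2, _, _) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise ValueError("edits touch the same reference bases")
    pieces: list[str] = []
    donor_spans: list[tuple[int, int]] = []
    cursor = 0
    out_len = 0
    for s, e, repl in ordered:
        pieces.append(bases[cursor:s])
        out_len += s - cursor
        donor_spans.append((out_len, out_len + len(repl)))
        pieces.append(repl)
        out_len += len(repl)
        cursor = e
    pieces.append(bases[cursor:])
    return "".join(pieces), list(zip(ordered, donor_spans))


def apply_variants(
    reference, variants: list[VariantRecord], ploidy: int
) -> tuple[list[str], CoordinateMap]:
    """Apply a genotyped, non-overlapping variant set to the reference.

    Returns one donor sequence per haplotype plus the coordinate map used by
    the truth table.  The donor-length identity
    ``len(donor) = G - deleted + inserted`` holds per haplotype by
    construction and is re-checked here as an internal invariant.
    """
    bases = reference.bases
    cmap = CoordinateMap(ploidy=ploidy)
    donors: list[str] = []
    for hap in range(ploidy):
        tagged: list[tuple[int, int, str, int, bool]] = []
        for rec in variants:
            if rec.genotype is None or hap not in rec.genotype:
                continue
            for sub in rec.simple_records():
                for s, e, repl in edits_for(sub, bases):
                    # the primary edit carries the record's own interval
                    # (dest-side for duplications, which have no source edit)
                    primary = (s, e) == (sub.start, sub.end) or sub.vtype == "DUP"
                    tagged.append((s, e, repl, sub.id, primary))
        tagged.sort(key=lambda t: (t[0], t[1]))
        for (s1, e1, *_), (s2, *_rest) in zip(tagged, tagged[1:]):
            if s2 < e1:
                raise ValueError("edits touch the same reference bases")
        pieces: list[str] = []
        pos: dict[int, tuple[int, int]] = {}
        cursor = 0
        out_len = 0
        for s, e, repl, vid, primary in tagged:
            pieces.append(bases[cursor:s])
            out_len += s - cursor
            if primary or vid not in pos:
                pos[vid] = (out_len, out_len + len(repl))
            pieces.append(repl)
            out_len += len(repl)
            cursor = e
        pieces.append(bases[cursor:])
        donor = "".join(pieces)
        expected = len(bases) + sum(
            len(repl) - (e - s) for (s, e, repl, _, _) in tagged
        )
        if len(donor) != expected:
            raise AssertionError("donor length identity violated")
        donors.append(donor)
        cmap.positions.append(pos)
        cmap.donor_lengths.append(len(donor))
    return donors, cmap
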