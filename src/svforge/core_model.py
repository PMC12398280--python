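"""Core data model: variant records, the occupancy mask, and run configuration.

Everything downstream of the samplers speaks in terms of the types defined
here.  Coordinates are 0-based half-open throughout the package; conversion
to 1-based happens only at the VCF boundary (:mod:`svforge.genome_io`).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger("svforge")

# ---------------------------------------------------------------------------
# Variant-type vocabulary and the fixed generation order
# ---------------------------------------------------------------------------

#: Complex-SV template identifiers (see :mod:`svforge.csv_constructors`).
CSV_IDS = tuple(f"ID{i}" for i in range(1, 19))

#: Simple structural-variant classes (events of at least MIN_SV_LEN bp).
SV_TYPES = ("TRA_BAL", "TRA_UNBAL", "INV", "DUP", "DEL", "INS")

#: Small-variant classes.
SMALL_TYPES = ("SMALL_DEL", "SMALL_INS", "SNP")

#: Generation order for a simulation run: translocations first, then
#: inversions, tandem duplications, the 18 complex templates, deletions,
#: insertions, small indels and finally SNPs.  Later classes are placed
#: around the intervals already reserved by earlier ones.
GENERATION_ORDER = (
    "TRA",
    "INV",
    "DUP",
    *CSV_IDS,
    "DEL",
    "INS",
    "SMALL_DEL",
    "SMALL_INS",
    "SNP",
)

MIN_SV_LEN = 50
MAX_SMALL_INDEL_LEN = 5

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class OverlapError(ValueError):
    """An interval collides with an existing reservation."""


class PlacementExhausted(RuntimeError):
    """No admissible start position remains for a requested placement."""


# ---------------------------------------------------------------------------
# Variant records
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One planned variant on the reference sequence.

    ``start``/``end`` delimit the primary reference interval the event
    consumes (half-open).  Insertions and SNP-like point events reserve a
    single base so later variants cannot collide with them.  Translocations
    carry the second exchanged region in ``region_b``; duplications carry the
    insertion point of the copies in ``dest`` and the total copy number in
    ``copies`` (``copies=2`` means one extra copy).  Composite events hold
    their ordered simple sub-events in ``components``.
    """

    id: int
    vtype: str
    start: int
    end: int
    length: int
    payload: str | None = None
    region_b: tuple[int, int] | None = None
    dest: int | None = None
    copies: int = 2
    inverted: bool = False
    copy_b: bool = False  # unbalanced TRA: copy B instead of moving it
    genotype: tuple[int, ...] | None = None
    components: list["VariantRecord"] = field(default_factory=list)
    csv_type: str | None = None
    csv_index: int | None = None

    def __post_init__(self) -> None:
        if self.vtype in ("DEL", "INS", "INV", "DUP", "TRA_BAL", "TRA_UNBAL"):
            if self.length < MIN_SV_LEN:
                raise ValueError(
                    f"{self.vtype} length {self.length} below the {MIN_SV_LEN} bp "
                    "structural-variant threshold"
                )
        elif self.vtype in ("SMALL_DEL", "SMALL_INS"):
            if not 1 <= self.length <= MAX_SMALL_INDEL_LEN:
                raise ValueError(f"small indel length must be 1..{MAX_SMALL_INDEL_LEN}")
        elif self.vtype == "SNP":
            if self.length != 1:
                raise ValueError("SNP length must be 1")
        elif self.vtype == "CSV":
            if not self.components:
                raise ValueError("composite variant requires components")

    @property
    def is_composite(self) -> bool:
        return self.vtype == "CSV"

    def simple_records(self) -> list["VariantRecord"]:
        """The flat list of simple events this record contributes."""
        return list(self.components) if self.is_composite else [self]

    def reserved_intervals(self) -> list[tuple[int, int]]:
        """All reference intervals this record (incl. components) consumes."""
        out: list[tuple[int, int]] = []
        for rec in self.simple_records():
            # point events (insertions) reserve one base at their site
            out.append((rec.start, rec.end if rec.end > rec.start else rec.start + 1))
            if rec.region_b is not None:
                out.append(rec.region_b)
            # duplications reserve the copy-insertion point (tandem included)
            # so no other edit can share that breakpoint
            if rec.dest is not None:
                out.append((rec.dest, rec.dest + 1))
        return out


# ---------------------------------------------------------------------------
# Occupancy mask
# ---------------------------------------------------------------------------

class OccupancyMask:
    """Disjoint set of reserved half-open intervals on ``[0, G)``.

    Enforces the global non-overlap invariant: every reference base is
    consumed by at most one variant.  Blocked regions (user supplied or
    N-runs) are ordinary reservations made before simulation starts.
    Half-open adjacency (``[10,20)`` next to ``[20,30)``) is disjoint.
    """

    def __init__(self, length: int):
        if length < 1:
            raise ValueError("mask length must be >= 1")
        self.length = length
        self._starts: list[int] = []
        self._ends: list[int] = []

    def __len__(self) -> int:
        return len(self._starts)

    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self._starts, self._ends))

    def is_free(self, start: int, end: int) -> bool:
        if not 0 <= start < end <= self.length:
            return False
        i = bisect.bisect_right(self._starts, start)
        if i > 0 and self._ends[i - 1] > start:
            return False
        if i < len(self._starts) and self._starts[i] < end:
            return False
        return True

    def reserve(self, start: int, end: int) -> None:
        if not 0 <= start < end <= self.length:
            raise ValueError(f"interval [{start},{end}) outside [0,{self.length})")
        if not self.is_free(start, end):
            raise OverlapError(f"interval [{start},{end}) overlaps a reservation")
        i = bisect.bisect_right(self._starts, start)
        self._starts.insert(i, start)
        self._ends.insert(i, end)

    def reserve_all(self, intervals: Iterable[tuple[int, int]]) -> None:
        """Reserve several intervals atomically (all free, then all added)."""
        ivs = sorted(intervals)
        for a, b in ivs:
            if not self.is_free(a, b):
                raise OverlapError(f"interval [{a},{b}) overlaps a reservation")
        for i in range(1, len(ivs)):
            if ivs[i][0] < ivs[i - 1][1]:
                raise OverlapError("requested intervals overlap each other")
        for a, b in ivs:
            self.reserve(a, b)

    def free_ranges(
        self, bin_start: int, bin_end: int, length: int
    ) -> list[range]:
        """Admissible start positions for a ``length``-bp event starting in
        ``[bin_start, bin_end)``.

        A start ``s`` is admissible when ``[s, s+length)`` is disjoint from
        every reservation and ``s + length <= G``.  The event may extend past
        the bin's right edge; only its start is constrained to the bin.
        Returned as a list of ``range`` objects (possibly empty).
        """
        if length < 1:
            raise ValueError("length must be >= 1")
        bin_start = max(bin_start, 0)
        bin_end = min(bin_end, self.length)
        if bin_start >= bin_end:
            return []
        window_end = min(bin_end + length, self.length)
        # Gaps in the reservation set overlapping [bin_start, window_end).
        gaps: list[tuple[int, int]] = []
        i = bisect.bisect_right(self._starts, bin_start) - 1
        cursor = bin_start
        if i >= 0 and self._ends[i] > bin_start:
            cursor = self._ends[i]
        i += 1
        while cursor < window_end:
            nxt = self._starts[i] if i < len(self._starts) else self.length
            gap_end = min(nxt, window_end)
            if cursor < gap_end:
                gaps.append((cursor, gap_end))
            if i >= len(self._starts):
                break
            cursor = max(cursor, self._ends[i])
            i += 1
        out: list[range] = []
        for a, b in gaps:
            lo = max(a, bin_start)
            hi = min(b - length, bin_end - 1, self.length - length)
            if hi >= lo:
                out.append(range(lo, hi + 1))
        return out

    def count_free(self, bin_start: int, bin_end: int, length: int) -> int:
        return sum(len(r) for r in self.free_ranges(bin_start, bin_end, length))


def find_n_runs(bases: str) -> list[tuple[int, int]]:
    """Maximal runs of 'N' in a sequence, as half-open intervals."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(bases):
        if b == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(bases)))
    return runs


# ---------------------------------------------------------------------------
# Genotype assignment
# ---------------------------------------------------------------------------

def assign_genotypes(
    variants: Sequence[VariantRecord],
    ploidy: int,
    het_prob: float,
    rng: np.random.Generator,
) -> list[VariantRecord]:
    """Assign each variant to haplotypes.

    With probability ``1 - het_prob`` a variant is homozygous (present on all
    ``ploidy`` haplotypes); otherwise it lands on one haplotype chosen
    uniformly.  A haploid reference forces homozygous assignment.
    """
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    if not 0.0 <= het_prob <= 1.0:
        raise ValueError("het_prob must be in [0, 1]")
    out = []
    for rec in variants:
        if ploidy == 1 or rng.random() >= het_prob:
            gt = tuple(range(ploidy))
        else:
            gt = (int(rng.integers(ploidy)),)
        out.append(replace(rec, genotype=gt))
    return out


# ---------------------------------------------------------------------------
# Substitution matrix
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionMatrix:
    """4x4 base-substitution transition matrix (rows: reference base).

    Rows sum to one and the diagonal is zero, so a sampled alternative can
    never equal the reference base.  The default is uniform over the three
    alternatives; a user matrix (e.g. learned from a variation database) can
    be loaded from a tab-separated file.
    """

    probs: np.ndarray  # shape (4, 4), row/col order A,C,G,T

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (4, 4):
            raise ValueError("substitution matrix must be 4x4")
        if np.any(p < 0):
            raise ValueError("substitution probabilities must be nonnegative")
        if not np.allclose(np.diag(p), 0.0):
            raise ValueError("substitution matrix diagonal must be zero")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("substitution matrix rows must sum to 1")
        self.probs = p

    @classmethod
    def uniform(cls) -> "SubstitutionMatrix":
        p = np.full((4, 4), 1.0 / 3.0)
        np.fill_diagonal(p, 0.0)
        return cls(p)

    @classmethod
    def from_tsv(cls, path) -> "SubstitutionMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.loc[list(DNA_BASES), list(DNA_BASES)]
        return cls(df.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.probs, index=list(DNA_BASES), columns=list(DNA_BASES)).to_csv(
            path, sep="\t"
        )

    def row(self, base: str) -> np.ndarray:
        return self.probs[DNA_BASES.index(base)]


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

DEFAULT_BIN_SIZE = 500_000


@dataclass
class SimulationConfig:
    """Resolved configuration for one simulation run.

    ``counts`` maps generation-order type keys (``TRA``, ``INV``, ``DUP``,
    ``DEL``, ``INS``, ``SMALL_DEL``, ``SMALL_INS``, ``SNP``) to requested
    totals; ``csv_counts`` maps template ids (``ID1``..``ID18``) to totals.
    ``rates`` (events per bp) are converted to totals as ``round(rate * G)``
    and override absent counts.  ``sum_flag`` derives a type's total from its
    learned spatial profile instead.
    """

    mode: str = "uniform"
    counts: dict = field(default_factory=dict)
    csv_counts: dict = field(default_factory=dict)
    rates: dict = field(default_factory=dict)
    sum_flag: bool = False
    allocation_option: str = "random"  # 'fixed' | 'random'
    bin_size: int = DEFAULT_BIN_SIZE
    tr_weights: tuple[float, float] | None = None  # (TR, non-TR)
    seed: int = 0
    ploidy: int = 2
    het_prob: float = 0.5
    cores: int = 1
    segments: int | None = None
    retry_cap: int = 1000
    blocked_regions: list = field(default_factory=list)
    auto_block_n: bool = True
    tra_balanced_prob: float = 0.5
    tra_unbalanced_copy: bool = False  # copy B (length-conserving at B) vs move
    dup_copies: int = 2
    sv_length_range: tuple[int, int] = (MIN_SV_LEN, 500)
    csv_length_range: tuple[int, int] = (MIN_SV_LEN, 500)
    csv_gap_range: tuple[int, int] = (0, 100)
    snp_matrix: SubstitutionMatrix | None = None
    chromosome: str | None = None

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not 0.0 <= self.het_prob <= 1.0:
            raise ValueError("het_prob must be in [0, 1]")
        if self.allocation_option not in ("fixed", "random"):
            raise ValueError("allocation_option must be 'fixed' or 'random'")
        for k, v in {**self.counts, **self.csv_counts}.items():
            if v < 0:
                raise ValueError(f"count for {k} must be >= 0")
        if self.tr_weights is not None:
            w_tr, w_non = self.tr_weights
            if w_tr < 0 or w_non < 0 or w_tr + w_non <= 0:
                raise ValueError("tr_weights must be nonnegative and not both zero")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("sv_length_range", "csv_length_range", "csv_gap_range", "tr_weights"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "blocked_regions" in raw and raw["blocked_regions"]:
            raw["blocked_regions"] = [tuple(iv) for iv in raw["blocked_regions"]]
        return cls(**raw)

    def describe(self) -> dict:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "snp_matrix"
        }
        d["snp_matrix"] = "user" if self.snp_matrix is not None else "uniform"
        return d

    def log_resolved(self) -> None:
        logger.info("resolved config: %s", self.describe())
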