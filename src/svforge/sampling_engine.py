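"""Turning learned profiles into concrete draws.

Count allocation, position and length sampling, the empirical small-indel
length law, and SNP alternative-base sampling.  All randomness flows through
an explicit :class:`numpy.random.Generator` so runs are reproducible from a
single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_model import (
    DNA_BASES,
    OccupancyMask,
    PlacementExhausted,
    SubstitutionMatrix,
)
from .distribution_learning import LengthDistribution, SpatialProfile

logger = logging.getLogger("svforge")

#: Empirical small-indel (1-5 bp) length law derived from database-scale
#: indel catalogues: P(len = 1..5) = 6/8, 1/8, 1/16, 1/32, 1/32.
SMALL_INDEL_LENGTH_PROBS = np.array([6 / 8, 1 / 8, 1 / 16, 1 / 32, 1 / 32])


@dataclass
class CountAllocation:
    """Per-bin simulated counts ``k_1..k_M`` summing to ``v_total``."""

    vtype: str
    v_total: int
    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=int)
        if np.any(self.k < 0):
            raise ValueError("per-bin counts must be nonnegative")
        if int(self.k.sum()) != self.v_total:
            raise ValueError("per-bin counts must sum to v_total")


def resolve_total(
    user_total: int | None,
    sum_flag: bool,
    profile: SpatialProfile | None,
) -> int:
    """Total number of events of one type to simulate.

    A user-specified total always wins.  With the sum-preserving flag, the
    total is taken from the profile instead: the sum of observed counts
    (single sample) or the rounded sum of per-bin means (multi sample).
    """
    if user_total is not None:
        return int(user_total)
    if sum_flag and profile is not None:
        if profile.is_multi:
            return int(round(float(profile.mu.sum())))
        return int(round(float(profile.counts.sum())))
    raise ValueError("no total requested: give a per-type count or enable sum mode")


def sample_nonneg_discrete_normal(
    mu: float, sigma: float, rng: np.random.Generator
) -> int:
    """Draw from Normal(mu, sigma^2), round to nearest int, clamp at zero."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    draw = mu if sigma == 0 else rng.normal(mu, sigma)
    return max(0, int(round(draw)))


def allocate_counts(
    profile: SpatialProfile,
    v_total: int,
    option: str,
    rng: np.random.Generator,
) -> CountAllocation:
    """Allocate ``v_total`` events of a type across bins.

    *fixed*: reproduce the observed spatial counts exactly — ``k_j = c_j``
    for a single sample, ``k_j = floor(mu_j)`` for a cohort.  When this
    realised total differs from a requested ``v_total``, the realised total
    wins and the discrepancy is logged.

    *random*: for a cohort, first redraw ``c_j`` from the nonnegative
    discrete normal with the learned per-bin moments; a single sample's
    ``c_j`` stays as observed.  Then draw
    ``(k_1..k_M) ~ Multinomial(v_total, p)`` with ``p_j = c_j / sum_k c_k``.
    """
    if v_total < 0:
        raise ValueError("v_total must be >= 0")
    if option == "fixed":
        if profile.is_multi:
            k = np.floor(profile.mu).astype(int)
        else:
            k = profile.counts.astype(int)
        realized = int(k.sum())
        if realized != v_total:
            logger.warning(
                "fixed allocation for %s realises %d events (requested %d); "
                "realised count wins",
                profile.vtype,
                realized,
                v_total,
            )
        return CountAllocation(vtype=profile.vtype, v_total=realized, k=k)
    if option != "random":
        raise ValueError("allocation option must be 'fixed' or 'random'")
    if profile.is_multi:
        c = np.array(
            [
                sample_nonneg_discrete_normal(m, s, rng)
                for m, s in zip(profile.mu, profile.sigma)
            ],
            dtype=float,
        )
    else:
        c = profile.counts.astype(float)
    total = c.sum()
    if total <= 0:
        logger.warning(
            "all-zero bin counts for %s; falling back to uniform bin probabilities",
            profile.vtype,
        )
        p = np.full(profile.M, 1.0 / profile.M)
    else:
        p = c / total
    k = rng.multinomial(v_total, p)
    return CountAllocation(vtype=profile.vtype, v_total=v_total, k=k)


def _split_ranges_by_tr(
    ranges: list[range], tr_regions: list[tuple[int, int]]
) -> tuple[list[range], list[range]]:
    """Partition admissible-start ranges into TR and non-TR pools (by start)."""
    tr_pool: list[range] = []
    non_pool: list[range] = []
    ivs = sorted(tr_regions)
    for r in ranges:
        lo, hi = r.start, r.stop  # half-open on starts
        cursor = lo
        for a, b in ivs:
            if b <= cursor:
                continue
            if a >= hi:
                break
            if cursor < min(a, hi):
                non_pool.append(range(cursor, min(a, hi)))
            seg_lo, seg_hi = max(a, cursor), min(b, hi)
            if seg_lo < seg_hi:
                tr_pool.append(range(seg_lo, seg_hi))
            cursor = max(cursor, seg_hi)
            if cursor >= hi:
                break
        if cursor < hi:
            non_pool.append(range(cursor, hi))
    return tr_pool, non_pool


def _draw_from_ranges(ranges: list[range], rng: np.random.Generator) -> int:
    total = sum(len(r) for r in ranges)
    if total == 0:
        raise PlacementExhausted("no admissible start positions")
    idx = int(rng.integers(total))
    for r in ranges:
        if idx < len(r):
            return r[idx]
        idx -= len(r)
    raise AssertionError("unreachable")


def sample_position(
    bin_interval: tuple[int, int],
    mask: OccupancyMask,
    length: int,
    rng: np.random.Generator,
    tr_weights: tuple[float, float] | None = None,
    tr_regions: list[tuple[int, int]] | None = None,
) -> int:
    """Sample a start uniformly from the admissible positions of a bin.

    With ``tr_weights = (w_tr, w_non)`` the admissible starts are split into
    tandem-repeat and non-repeat pools; the pool is chosen with the given
    probabilities, then the start is uniform within the chosen pool.  An
    empty chosen pool falls through to the other one.
    """
    ranges = mask.free_ranges(bin_interval[0], bin_interval[1], length)
    if not ranges:
        raise PlacementExhausted(
            f"bin [{bin_interval[0]},{bin_interval[1]}) has no room for {length} bp"
        )
    if tr_weights is None or not tr_regions:
        return _draw_from_ranges(ranges, rng)
    tr_pool, non_pool = _split_ranges_by_tr(ranges, tr_regions)
    w_tr, w_non = tr_weights
    pools = []
    weights = []
    if tr_pool:
        pools.append(tr_pool)
        weights.append(w_tr)
    if non_pool:
        pools.append(non_pool)
        weights.append(w_non)
    if not pools:
        raise PlacementExhausted("no admissible start positions")
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(pools))
    chosen = pools[int(rng.choice(len(pools), p=w / w.sum()))]
    return _draw_from_ranges(chosen, rng)


def sample_length(
    dist: LengthDistribution | tuple[int, int],
    rng: np.random.Generator,
) -> int:
    """Draw a variant length from a learned distribution or a uniform range."""
    if isinstance(dist, LengthDistribution):
        return int(rng.choice(dist.lengths, p=dist.probs))
    lo, hi = dist
    if lo > hi or lo < 1:
        raise ValueError(f"invalid length range [{lo},{hi}]")
    return int(rng.integers(lo, hi + 1))


def sample_small_indel_length(rng: np.random.Generator) -> int:
    """Small-indel length in 1..5 under the fixed empirical law."""
    return int(rng.choice(5, p=SMALL_INDEL_LENGTH_PROBS)) + 1


def sample_snp_alt(
    ref_base: str, matrix: SubstitutionMatrix, rng: np.random.Generator
) -> str:
    """Replacement base for a SNP at a site with reference base ``ref_base``."""
    if ref_base not in DNA_BASES:
        raise ValueError(f"cannot substitute at reference base {ref_base!r}")
    return DNA_BASES[int(rng.choice(4, p=matrix.row(ref_base)))]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform-random A/C/G/T string (novel insertion alleles)."""
    return "".join(DNA_BASES[i] for i in rng.integers(0, 4, size=length))
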