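"""Learning length and spatial distributions from empirical variant cohorts.

Given BED-derived observations of real variants, this module estimates, per
variant type:

* a **length distribution** — the normalised histogram of observed lengths,
  ``P_t(l) = n_{t,l} / sum_{l'} n_{t,l'}``, pooled across all input samples;
* a **spatial profile** — the genome is tiled into bins of size ``L``
  (default 500 kbp, terminal bin absorbing residual bases) and per-bin
  counts are tallied.  With a single sample the observed counts ``c_j``
  directly define bin probabilities ``p_j = c_j / sum_k c_k``; with ``N``
  samples a per-bin mean ``mu_j`` and standard deviation ``sigma_j`` are
  estimated and ``p_j`` is normalised from the means.

A variant is attributed to the bin containing its **start** coordinate, even
when it spans a bin boundary.  Profiles serialise to a tab-separated sidecar
so precomputed distributions can be reused without the original BEDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("svforge")


@dataclass
class BinPartition:
    """Tiling of ``[0, G)`` into ``M`` bins of nominal width ``L``.

    ``M = floor(G / L)`` (forced to 1 when ``G < L``); bins ``1..M-1`` have
    width exactly ``L`` and the terminal bin stretches to ``G``, so it is at
    least ``L`` wide whenever ``M >= 1`` bins fit.
    """

    G: int
    L: int
    bins: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        if self.G < 1 or self.L < 1:
            raise ValueError("sequence length and bin size must be >= 1")
        M = max(1, self.G // self.L)
        self.bins = [((j) * self.L, (j + 1) * self.L) for j in range(M - 1)]
        self.bins.append(((M - 1) * self.L, self.G))

    @property
    def M(self) -> int:
        return len(self.bins)

    def widths(self) -> np.ndarray:
        return np.array([b - a for a, b in self.bins])

    def bin_index(self, position: int) -> int:
        if not 0 <= position < self.G:
            raise ValueError(f"position {position} outside [0,{self.G})")
        return min(position // self.L, self.M - 1)


def partition_bins(G: int, L: int) -> BinPartition:
    """Partition a length-``G`` sequence into bins of size ``L``."""
    return BinPartition(G=G, L=L)


@dataclass
class LengthDistribution:
    """Normalised histogram of variant lengths for one type."""

    vtype: str
    lengths: np.ndarray  # sorted unique observed lengths
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.lengths.size == 0:
            raise ValueError("length distribution requires non-empty support")
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("length probabilities must be nonnegative and sum to 1")

    def prob_of(self, length: int) -> float:
        idx = np.searchsorted(self.lengths, length)
        if idx < self.lengths.size and self.lengths[idx] == length:
            return float(self.probs[idx])
        return 0.0


@dataclass
class SpatialProfile:
    """Per-bin counts / statistics and normalised probabilities for one type."""

    vtype: str
    counts: np.ndarray  # c_j (single) or mean-equivalent counts
    probs: np.ndarray
    mu: np.ndarray | None = None
    sigma: np.ndarray | None = None
    n_samples: int = 1
    sample_counts: np.ndarray | None = None  # (N, M) when multi-sample

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.counts.shape != self.probs.shape:
            raise ValueError("counts and probs must align")
        if self.counts.sum() > 0 and abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("bin probabilities must sum to 1")

    @property
    def M(self) -> int:
        return self.counts.size

    @property
    def is_multi(self) -> bool:
        return self.n_samples > 1


def learn_length_distribution(observations: Sequence, vtype: str) -> LengthDistribution:
    """Tally observed lengths of ``vtype`` into a normalised distribution.

    Counts are pooled across every input sample before normalising, so the
    denominator is the total number of type-``t`` observations in the cohort.
    """
    lens = [o.length for o in observations if o.vtype == vtype]
    if not lens:
        raise ValueError(
            f"no observations of type {vtype}: fall back to a user length range"
        )
    vals, cnts = np.unique(np.asarray(lens, dtype=int), return_counts=True)
    return LengthDistribution(vtype=vtype, lengths=vals, probs=cnts / cnts.sum())


def learn_spatial_profile(
    observations: Sequence,
    partition: BinPartition,
    vtype: str,
    mode: str = "single",
    ddof: int = 0,
) -> SpatialProfile:
    """Bin observation starts and derive bin probabilities.

    ``mode='single'`` pools everything into one count vector ``c_j``.
    ``mode='multi'`` tallies per sample (grouped by ``sample_id``), then
    reduces to ``mu_j`` / ``sigma_j`` per bin; probabilities normalise the
    means.  ``sigma`` uses the population estimator (``ddof=0``) by default;
    pass ``ddof=1`` for the sample estimator.
    """
    obs = [o for o in observations if o.vtype == vtype]
    for o in obs:
        if not 0 <= o.start < partition.G:
            raise ValueError(
                f"observation start {o.start} outside [0,{partition.G})"
            )
    M = partition.M
    if mode == "single":
        c = np.zeros(M)
        for o in obs:
            c[partition.bin_index(o.start)] += 1
        total = c.sum()
        p = c / total if total > 0 else np.zeros(M)
        return SpatialProfile(vtype=vtype, counts=c, probs=p, n_samples=1)
    if mode != "multi":
        raise ValueError("mode must be 'single' or 'multi'")
    sample_ids = sorted({o.sample_id for o in obs}) or [None]
    mat = np.zeros((len(sample_ids), M))
    idx = {s: i for i, s in enumerate(sample_ids)}
    for o in obs:
        mat[idx[o.sample_id], partition.bin_index(o.start)] += 1
    mu = mat.mean(axis=0)
    sigma = mat.std(axis=0, ddof=ddof) if mat.shape[0] > ddof else np.zeros(M)
    total = mu.sum()
    p = mu / total if total > 0 else np.zeros(M)
    return SpatialProfile(
        vtype=vtype,
        counts=mu,
        probs=p,
        mu=mu,
        sigma=sigma,
        n_samples=len(sample_ids),
        sample_counts=mat,
    )


def deduplicate_cohort(sample_sets: Sequence[Sequence]) -> list:
    """Merge observation collections, dropping repeated sample ids.

    When the same sample id appears in more than one input collection, only
    the first collection's observations for that id are kept (benchmark
    cohorts may share individuals).
    """
    seen: set = set()
    merged: list = []
    for collection in sample_sets:
        ids_here = {o.sample_id for o in collection}
        fresh = ids_here - seen
        dropped = ids_here & seen
        if dropped:
            logger.info("deduplicated overlapping samples: %s", sorted(dropped))
        merged.extend(o for o in collection if o.sample_id in fresh)
        seen |= fresh
    return merged


@dataclass
class TRPartitionStats:
    """Per-type counts of observations inside vs outside tandem-repeat regions."""

    inside: dict
    outside: dict

    def proportion_tr(self, vtype: str) -> float:
        a = self.inside.get(vtype, 0)
        b = self.outside.get(vtype, 0)
        return a / (a + b) if (a + b) > 0 else 0.0


def tr_partition_stats(
    observations: Sequence, tr_regions: Sequence[tuple[int, int]]
) -> TRPartitionStats:
    """Count, per type, how many observation starts fall in TR intervals."""
    ivs = sorted(tr_regions)
    starts = np.array([a for a, _ in ivs]) if ivs else np.empty(0)
    ends = np.array([b for _, b in ivs]) if ivs else np.empty(0)
    inside: dict = {}
    outside: dict = {}
    for o in observations:
        i = int(np.searchsorted(starts, o.start, side="right")) - 1 if ivs else -1
        in_tr = i >= 0 and o.start < ends[i]
        bucket = inside if in_tr else outside
        bucket[o.vtype] = bucket.get(o.vtype, 0) + 1
    return TRPartitionStats(inside=inside, outside=outside)


# ---------------------------------------------------------------------------
# Profile sidecar serialisation
# ---------------------------------------------------------------------------

def save_profile(profile: SpatialProfile, partition: BinPartition, path) -> None:
    """Write a spatial profile as a tab-separated sidecar.

    Columns: bin index (1-based), bin start, bin end, c (observed count or
    mean), sigma (0 for single-sample), p.  This is the mechanism behind
    shipping precomputed genome-wide distributions.
    """
    sigma = profile.sigma if profile.sigma is not None else np.zeros(profile.M)
    df = pd.DataFrame(
        {
            "bin": np.arange(1, partition.M + 1),
            "start": [a for a, _ in partition.bins],
            "end": [b for _, b in partition.bins],
            "c": profile.counts,
            "sigma": sigma,
            "p": profile.probs,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"#vtype={profile.vtype}\tn_samples={profile.n_samples}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_profile(path) -> tuple[SpatialProfile, BinPartition]:
    with open(path) as fh:
        header = fh.readline().strip()
        meta = dict(kv.split("=") for kv in header.lstrip("#").split("\t"))
        df = pd.read_csv(fh, sep="\t")
    G = int(df["end"].iloc[-1])
    L = int(df["end"].iloc[0]) - int(df["start"].iloc[0]) if len(df) > 1 else G
    partition = BinPartition(G=G, L=L)
    n_samples = int(meta.get("n_samples", 1))
    profile = SpatialProfile(
        vtype=meta.get("vtype", "DEL"),
        counts=df["c"].to_numpy(),
        probs=df["p"].to_numpy(),
        mu=df["c"].to_numpy() if n_samples > 1 else None,
        sigma=df["sigma"].to_numpy() if n_samples > 1 else None,
        n_samples=n_samples,
    )
    return profile, partition
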