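"""Synthetic inputs for testing every stage without external downloads.

The cohort generator emulates the salient features of real benchmark
variant sets: spatial counts enriched near chromosome ends (telomere bias),
multi-modal SV length spectra (modes near 300 / 2,500 / 6,000 bp, echoing
published human SV length peaks), and per-sample count noise.  Ground-truth
parameters are returned alongside each fixture so recovery tests can
compare learned distributions against what generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distribution_learning import BinPartition, partition_bins
from .genome_io import ReferenceSequence, VariantObservation

#: Default SV length mixture: (length, weight) modes echoing the empirical
#: human SV spectrum.  Fixture parameters, not claims about any dataset.
DEFAULT_LENGTH_MIXTURE = ((300, 0.6), (2500, 0.3), (6000, 0.1))


def make_reference(
    length: int,
    seed: int,
    n_run_spec: list[tuple[int, int]] | None = None,
    name: str = "chrSim",
) -> ReferenceSequence:
    """Uniform-random A/C/G/T sequence with optional embedded N-runs."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    arr = rng.integers(0, 4, size=length)
    bases = np.array(list("ACGT"))[arr]
    for a, b in n_run_spec or []:
        bases[a:b] = "N"
    return ReferenceSequence(name=name, bases="".join(bases))


def telomere_biased_probs(n_bins: int, terminal_weight: float = 5.0) -> np.ndarray:
    """Bin probabilities with the two terminal bins up-weighted."""
    w = np.ones(n_bins)
    w[0] *= terminal_weight
    if n_bins > 1:
        w[-1] *= terminal_weight
    return w / w.sum()


@dataclass
class CohortTruth:
    """Ground-truth parameters behind a synthetic cohort."""

    profile_probs: np.ndarray
    length_mixture: tuple
    mean_count: int
    partition: BinPartition
    counts_per_sample: np.ndarray = field(default=None)


def make_cohort(
    n_samples: int,
    profile_truth: np.ndarray,
    seed: int,
    reference_length: int,
    bin_size: int = 500_000,
    mean_count: int = 1000,
    count_noise_sd: float = 0.0,
    length_mixture: tuple = DEFAULT_LENGTH_MIXTURE,
    vtype: str = "DEL",
    out_dir=None,
    chrom: str = "chrSim",
) -> tuple[list, CohortTruth]:
    """Generate a multi-sample observation cohort from known truth.

    Per sample, the observation count is drawn around ``mean_count`` with
    Gaussian noise of ``count_noise_sd`` (zero noise gives identical
    counts); bins are drawn from ``profile_truth``; positions are uniform
    within the chosen bin; lengths come from the discrete mixture.

    Returns either in-memory observation lists (``out_dir=None``) or paths
    to written BED files, plus the :class:`CohortTruth`.
    """
    partition = partition_bins(reference_length, bin_size)
    probs = np.asarray(profile_truth, dtype=float)
    if probs.size != partition.M:
        raise ValueError("profile_truth must have one probability per bin")
    probs = probs / probs.sum()
    lengths = np.array([l for l, _ in length_mixture])
    weights = np.array([w for _, w in length_mixture], dtype=float)
    weights /= weights.sum()
    rng = np.random.Generator(np.random.PCG64(seed))

    all_obs: list[list[VariantObservation]] = []
    counts = np.zeros(n_samples, dtype=int)
    for i in range(n_samples):
        n = mean_count if count_noise_sd == 0 else max(
            0, int(round(rng.normal(mean_count, count_noise_sd)))
        )
        counts[i] = n
        bins = rng.choice(partition.M, size=n, p=probs)
        sample_obs = []
        for j in bins:
            a, b = partition.bins[j]
            length = int(rng.choice(lengths, p=weights))
            start = int(rng.integers(a, b))
            end = start if vtype == "INS" else min(start + length, reference_length)
            if vtype != "INS" and end <= start:
                continue
            sample_obs.append(
                VariantObservation(
                    sample_id=f"s{i + 1}", chrom=chrom, start=start, end=end,
                    vtype=vtype,
                    length=length if vtype == "INS" else end - start,
                )
            )
        all_obs.append(sample_obs)

    truth = CohortTruth(
        profile_probs=probs, length_mixture=length_mixture,
        mean_count=mean_count, partition=partition, counts_per_sample=counts,
    )
    if out_dir is None:
        return all_obs, truth
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sample_obs in enumerate(all_obs):
        p = out_dir / f"sample_{i + 1}.bed"
        with open(p, "w") as fh:
            for o in sample_obs:
                end = o.start + o.length if o.vtype == "INS" else o.end
                fh.write(f"{o.chrom}\t{o.start}\t{end}\t{o.vtype}\t{o.length}\n")
        paths.append(p)
    return paths, truth


def make_tr_bed(
    reference: ReferenceSequence,
    coverage_fraction: float,
    seed: int,
    mean_width: int = 2000,
    out_path=None,
) -> list[tuple[int, int]]:
    """Disjoint intervals covering roughly ``coverage_fraction`` of the
    sequence (tandem-repeat region stand-in).  Deterministic per seed."""
    if not 0 < coverage_fraction < 1:
        raise ValueError("coverage_fraction must be in (0, 1)")
    G = reference.length
    rng = np.random.Generator(np.random.PCG64(seed))
    target = coverage_fraction * G
    n = max(1, int(round(target / mean_width)))
    width = max(1, int(round(target / n)))
    # place n intervals on an even grid with jitter, guaranteeing disjointness
    stride = G // n
    intervals = []
    for i in range(n):
        slack = max(0, stride - width - 1)
        off = int(rng.integers(0, slack + 1)) if slack > 0 else 0
        a = i * stride + off
        b = min(a + width, G)
        if a < b:
            intervals.append((a, b))
    if out_path is not None:
        with open(out_path, "w") as fh:
            for a, b in intervals:
                fh.write(f"{reference.name}\t{a}\t{b}\n")
    return intervals
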