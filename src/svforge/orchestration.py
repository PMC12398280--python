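"""End-to-end simulation: mode dispatch, generation order, parallel segments.

A run proceeds as: partition the sequence into bins; resolve per-type totals
and allocate them to bins; split the bin sequence into contiguous segments;
simulate each segment independently (own RNG stream, own occupancy mask,
variants confined to the segment); merge; assign genotypes; apply to the
reference and emit outputs.

Variant classes are generated in a fixed order — translocations,
inversions, tandem duplications, the complex templates ID1..ID18,
deletions, insertions, small deletions, small insertions, SNPs — and every
later variant is placed around the intervals already reserved, so the final
set is non-overlapping by construction.

Determinism contract: the segment layout depends only on the configuration
(never on the worker count), and every segment draws from its own counted
RNG stream, so identical (config, seed) gives byte-identical outputs for
any ``cores`` value.
"""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import (
    CSV_IDS,
    GENERATION_ORDER,
    MIN_SV_LEN,
    OccupancyMask,
    OverlapError,
    PlacementExhausted,
    SimulationConfig,
    SubstitutionMatrix,
    VariantRecord,
    assign_genotypes,
    find_n_runs,
)
from .csv_constructors import build_csv, get_template
from .distribution_learning import (
    BinPartition,
    LengthDistribution,
    SpatialProfile,
    learn_length_distribution,
    learn_spatial_profile,
    partition_bins,
)
from .genome_io import (
    ExactTableError,
    ExactVariantRow,
    ReferenceSequence,
    emit_outputs,
    filter_population_vcf,
    read_bed_regions,
    read_bed_variants,
    read_exact_table,
    validate_exact_table,
    write_exact_table,
)
from .sampling_engine import (
    allocate_counts,
    random_dna,
    resolve_total,
    sample_length,
    sample_position,
    sample_small_indel_length,
    sample_snp_alt,
)
from .variant_constructors import (
    apply_variants,
    make_deletion,
    make_insertion,
    make_inversion,
    make_snp,
    make_tandem_duplication,
    make_translocation,
)

logger = logging.getLogger("svforge")

SIMPLE_TYPE_KEYS = ("TRA", "INV", "DUP", "DEL", "INS", "SMALL_DEL", "SMALL_INS", "SNP")

MODES = (
    "mimic", "wave", "wave_region", "csv",
    "uniform", "uniform_parallel", "exact", "vcf_filter",
)


@dataclass
class RunResult:
    """Everything a simulation run produces."""

    config: SimulationConfig
    variants: list = field(default_factory=list)
    donors: list = field(default_factory=list)
    coordinate_map: object = None
    realized_counts: dict = field(default_factory=dict)
    skipped_counts: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    exact_rows: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Planning: totals and per-bin allocations
# ---------------------------------------------------------------------------

def _flat_profile(partition: BinPartition, vtype: str) -> SpatialProfile:
    """Uniform profile: bin probability proportional to bin width, so the
    bin-then-position hierarchy reduces to a global uniform placement."""
    w = partition.widths().astype(float)
    return SpatialProfile(vtype=vtype, counts=w, probs=w / w.sum(), n_samples=1)


def plan_allocations(
    config: SimulationConfig,
    partition: BinPartition,
    profiles: dict | None,
    rng: np.random.Generator,
) -> dict:
    """Per-bin counts for every requested type key (simple types + CSV ids)."""
    profiles = profiles or {}
    allocations: dict = {}

    def total_for(key: str, profile: SpatialProfile | None) -> int | None:
        if key in config.counts:
            return int(config.counts[key])
        if key in config.rates:
            return int(round(config.rates[key] * partition.G))
        if config.sum_flag and profile is not None:
            return resolve_total(None, True, profile)
        return None

    for key in SIMPLE_TYPE_KEYS:
        profile = profiles.get(key)
        total = total_for(key, profile)
        if not total:
            continue
        prof = profile if profile is not None else _flat_profile(partition, key)
        option = config.allocation_option if profile is not None else "random"
        allocations[key] = allocate_counts(prof, total, option, rng)
    for csv_id, total in config.csv_counts.items():
        if not total:
            continue
        prof = profiles.get(csv_id) or profiles.get("CSV") or _flat_profile(
            partition, csv_id
        )
        option = (
            config.allocation_option
            if (csv_id in profiles or "CSV" in profiles)
            else "random"
        )
        allocations[csv_id] = allocate_counts(prof, int(total), option, rng)
    return allocations


def _segment_layout(partition: BinPartition, n_segments: int) -> list[tuple[int, int]]:
    """Split the bin sequence into contiguous runs of bins, as
    (first_bin, last_bin+1) index pairs."""
    M = partition.M
    n = max(1, min(n_segments, M))
    base, rem = divmod(M, n)
    out = []
    start = 0
    for i in range(n):
        size = base + (1 if i < rem else 0)
        out.append((start, start + size))
        start += size
    return out


# ---------------------------------------------------------------------------
# Per-segment generation
# ---------------------------------------------------------------------------

def _max_event_length(config: SimulationConfig, length_dists: dict) -> int:
    candidates = [config.sv_length_range[1], config.csv_length_range[1]]
    for d in length_dists.values():
        candidates.append(int(d.lengths.max()))
    return max(candidates)


def _place_simple(
    key: str,
    bin_iv: tuple[int, int],
    mask: OccupancyMask,
    bases: str,
    length_dists: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
    tr_regions,
) -> VariantRecord | None:
    """One placement attempt loop for a simple variant; None when exhausted."""
    tr_kwargs = dict(tr_weights=config.tr_weights, tr_regions=tr_regions)
    for _ in range(config.retry_cap):
        try:
            if key == "TRA":
                ldist = length_dists.get("TRA", config.sv_length_range)
                len_a = sample_length(ldist, rng)
                len_b = sample_length(ldist, rng)
                a = sample_position(bin_iv, mask, len_a, rng, **tr_kwargs)
                b = sample_position(
                    (0, mask.length), mask, len_b, rng, **tr_kwargs
                )
                if max(a, b) < min(a + len_a, b + len_b):
                    continue  # regions collided with each other; redraw
                balanced = rng.random() < config.tra_balanced_prob
                return make_translocation(
                    mask, (a, a + len_a), (b, b + len_b), balanced,
                    unbalanced_copy=config.tra_unbalanced_copy,
                )
            if key == "INV":
                length = sample_length(
                    length_dists.get("INV", config.sv_length_range), rng
                )
                s = sample_position(bin_iv, mask, length, rng, **tr_kwargs)
                return make_inversion(mask, s, length)
            if key == "DUP":
                length = sample_length(
                    length_dists.get("DUP", config.sv_length_range), rng
                )
                s = sample_position(bin_iv, mask, length, rng, **tr_kwargs)
                return make_tandem_duplication(
                    mask, s, length, copies=config.dup_copies
                )
            if key == "DEL":
                length = sample_length(
                    length_dists.get("DEL", config.sv_length_range), rng
                )
                s = sample_position(bin_iv, mask, length, rng, **tr_kwargs)
                return make_deletion(mask, s, length)
            if key == "INS":
                length = sample_length(
                    length_dists.get("INS", config.sv_length_range), rng
                )
                s = sample_position(bin_iv, mask, 1, rng, **tr_kwargs)
                return make_insertion(mask, s, random_dna(length, rng))
            if key == "SMALL_DEL":
                length = sample_small_indel_length(rng)
                s = sample_position(bin_iv, mask, length, rng, **tr_kwargs)
                return make_deletion(mask, s, length, small=True)
            if key == "SMALL_INS":
                length = sample_small_indel_length(rng)
                s = sample_position(bin_iv, mask, 1, rng, **tr_kwargs)
                return make_insertion(mask, s, random_dna(length, rng), small=True)
            if key == "SNP":
                s = sample_position(bin_iv, mask, 1, rng, **tr_kwargs)
                ref_base = bases[s]
                if ref_base == "N":
                    continue
                matrix = config.snp_matrix or SubstitutionMatrix.uniform()
                return make_snp(mask, s, ref_base, sample_snp_alt(ref_base, matrix, rng))
        except (PlacementExhausted, OverlapError):
            continue
    return None


def _simulate_segment(
    bases: str,
    seg_start: int,
    seg_end: int,
    seg_bins: list[tuple[int, tuple[int, int]]],
    allocations_k: dict,
    length_dists: dict,
    config: SimulationConfig,
    blocked: list[tuple[int, int]],
    tr_regions: list[tuple[int, int]] | None,
    seed_state: tuple,
) -> tuple[list[VariantRecord], dict]:
    """Generate all variants confined to one segment.

    The mask spans ``[0, seg_end)`` with ``[0, seg_start)`` pre-reserved, so
    no event can leave the segment; blocked regions intersecting the segment
    are reserved up front.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed_state)))
    mask = OccupancyMask(seg_end)
    if seg_start > 0:
        mask.reserve(0, seg_start)
    for a, b in blocked:
        a2, b2 = max(a, seg_start), min(b, seg_end)
        if a2 < b2:
            try:
                mask.reserve(a2, b2)
            except OverlapError:
                pass
    variants: list[VariantRecord] = []
    skipped: dict = {}
    for key in GENERATION_ORDER:
        if key not in allocations_k:
            continue
        k = allocations_k[key]
        for bin_idx, bin_iv in seg_bins:
            n = int(k[bin_idx])
            for _ in range(n):
                if key in CSV_IDS:
                    rec = _place_csv(
                        key, bin_iv, mask, length_dists, config, rng
                    )
                else:
                    rec = _place_simple(
                        key, bin_iv, mask, bases, length_dists, config,
                        rng, tr_regions,
                    )
                if rec is None:
                    skipped[key] = skipped.get(key, 0) + 1
                else:
                    variants.append(rec)
    if skipped:
        logger.warning(
            "segment [%d,%d): skipped after retry cap: %s",
            seg_start, seg_end, skipped,
        )
    return variants, skipped


def _place_csv(
    csv_id: str,
    bin_iv: tuple[int, int],
    mask: OccupancyMask,
    length_dists: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> VariantRecord | None:
    template = get_template(csv_id)
    ldist = length_dists.get("CSV", config.csv_length_range)
    for _ in range(config.retry_cap):
        try:
            anchor = sample_position(bin_iv, mask, 1, rng)
            return build_csv(
                template, anchor, ldist, mask, rng,
                gap_range=config.csv_gap_range,
            )
        except (PlacementExhausted, OverlapError):
            continue
    return None


def _segment_worker(args):
    return _simulate_segment(*args)


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

def simulate(
    config: SimulationConfig,
    reference: ReferenceSequence,
    profiles: dict | None = None,
    length_dists: dict | None = None,
    tr_regions: list[tuple[int, int]] | None = None,
) -> RunResult:
    """Run a full simulation and return the genotyped variant set + donors."""
    length_dists = length_dists or {}
    G = reference.length
    partition = partition_bins(G, config.bin_size)

    blocked = [tuple(iv) for iv in config.blocked_regions]
    if config.auto_block_n:
        blocked += find_n_runs(reference.bases)
    blocked.sort()

    root = np.random.SeedSequence(config.seed)
    alloc_seed, genotype_seed, segments_seed = root.spawn(3)
    allocations = plan_allocations(
        config, partition, profiles,
        np.random.Generator(np.random.PCG64(alloc_seed)),
    )
    alloc_k = {key: a.k for key, a in allocations.items()}

    n_segments = config.segments if config.segments else min(partition.M, 4)
    layout = _segment_layout(partition, n_segments)
    max_len = _max_event_length(config, length_dists)
    for lo, hi in layout:
        seg_start = partition.bins[lo][0]
        seg_end = partition.bins[hi - 1][1]
        if seg_end - seg_start < max_len:
            raise ValueError(
                f"segment [{seg_start},{seg_end}) shorter than the largest "
                f"requested variant ({max_len} bp); use fewer segments"
            )

    jobs = []
    for i, (lo, hi) in enumerate(layout):
        seg_bins = [(j, partition.bins[j]) for j in range(lo, hi)]
        jobs.append(
            (
                reference.bases,
                partition.bins[lo][0],
                partition.bins[hi - 1][1],
                seg_bins,
                alloc_k,
                length_dists,
                config,
                blocked,
                tr_regions,
                # counted per-segment stream: depends only on (seed, index)
                (config.seed, 2, i),
            )
        )

    if config.cores > 1 and len(jobs) > 1:
        with ProcessPoolExecutor(max_workers=config.cores) as pool:
            results = list(pool.map(_segment_worker, jobs))
    else:
        results = [_segment_worker(j) for j in jobs]

    merged: list[VariantRecord] = []
    skipped: dict = {}
    order_index = {key: i for i, key in enumerate(GENERATION_ORDER)}
    per_segment = [r[0] for r in results]
    for key in GENERATION_ORDER:
        for seg_variants in per_segment:
            for rec in seg_variants:
                rec_key = rec.csv_type if rec.is_composite else (
                    "TRA" if rec.vtype.startswith("TRA") else rec.vtype
                )
                if rec_key == key:
                    merged.append(rec)
    for _, seg_skipped in results:
        for key, n in seg_skipped.items():
            skipped[key] = skipped.get(key, 0) + n

    counter = 1
    for rec in merged:
        rec.id = counter
        counter += 1
        for comp in rec.components:
            comp.id = counter
            counter += 1

    gt_rng = np.random.Generator(np.random.PCG64(genotype_seed))
    merged = assign_genotypes(merged, config.ploidy, config.het_prob, gt_rng)

    donors, cmap = apply_variants(reference, merged, config.ploidy)
    realized: dict = {}
    for rec in merged:
        key = rec.csv_type if rec.is_composite else (
            "TRA" if rec.vtype.startswith("TRA") else rec.vtype
        )
        realized[key] = realized.get(key, 0) + 1
    logger.info("realized per-type counts: %s (skipped: %s)", realized, skipped)
    return RunResult(
        config=config,
        variants=merged,
        donors=donors,
        coordinate_map=cmap,
        realized_counts=realized,
        skipped_counts=skipped,
    )


def run_parallel(
    config: SimulationConfig,
    reference: ReferenceSequence,
    profiles: dict | None = None,
    length_dists: dict | None = None,
    tr_regions=None,
) -> RunResult:
    """Segmented simulation with a worker pool (``config.cores`` workers).

    The segment layout and per-segment RNG streams depend only on the
    configuration and seed, so any core count yields identical results.
    """
    if config.cores >= 2 and (config.segments or 2) < 2:
        raise ValueError("parallel run requires at least 2 segments")
    return simulate(config, reference, profiles, length_dists, tr_regions)


# ---------------------------------------------------------------------------
# Exact mode
# ---------------------------------------------------------------------------

def _record_from_exact_row(row: ExactVariantRow, counter: int) -> VariantRecord:
    s = row.position - 1
    t = row.vtype
    if t in ("DEL", "INS") and row.length < MIN_SV_LEN:
        if row.length <= 5:
            t = "SMALL_" + t
        else:
            raise ExactTableError(
                f"{row.vtype} of length {row.length} is neither a structural "
                "variant (>=50 bp) nor a small indel (<=5 bp)"
            )
    if t in ("DEL", "SMALL_DEL"):
        return VariantRecord(
            id=counter, vtype=t, start=s, end=s + row.length, length=row.length
        )
    if t in ("INS", "SMALL_INS"):
        # exact-mode insertions get a novel random allele of the given length
        rng = np.random.Generator(np.random.PCG64(counter))
        return VariantRecord(
            id=counter, vtype=t, start=s, end=s, length=row.length,
            payload=random_dna(row.length, rng),
        )
    if t == "INV":
        return VariantRecord(
            id=counter, vtype="INV", start=s, end=s + row.length, length=row.length
        )
    if t == "DUP":
        src_s = row.source_start - 1
        src_e = row.source_end
        return VariantRecord(
            id=counter, vtype="DUP", start=src_s, end=src_e,
            length=src_e - src_s, dest=row.dest - 1, copies=2,
        )
    if t in ("TRA", "TRA_BAL"):
        b = (row.region_b_start - 1, row.region_b_end)
        return VariantRecord(
            id=counter, vtype="TRA_BAL", start=s, end=s + row.length,
            length=row.length, region_b=b,
        )
    if t == "TRA_UNBAL":
        b = (row.region_b_start - 1, row.region_b_end)
        return VariantRecord(
            id=counter, vtype="TRA_UNBAL", start=s, end=s + row.length,
            length=row.length, region_b=b,
        )
    if t == "SNP":
        return VariantRecord(id=counter, vtype="SNP", start=s, end=s + 1, length=1)
    raise ExactTableError(f"unsupported exact-mode type {t}")


def build_exact_variants(
    rows: list[ExactVariantRow], reference: ReferenceSequence
) -> list[VariantRecord]:
    """Construct records at exactly the specified positions.

    Rows sharing a ``csv_group`` label become one composite event.  The
    occupancy mask still applies: conflicting rows raise an error rather
    than silently moving a variant.
    """
    rows = validate_exact_table(rows, reference)
    mask = OccupancyMask(reference.length)
    records: list[VariantRecord] = []
    groups: dict[str, list[VariantRecord]] = {}
    counter = 1
    for row in rows:
        rec = _record_from_exact_row(row, counter)
        counter += 1
        if rec.vtype == "SNP" and rec.payload is None:
            ref_base = reference.bases[rec.start]
            alts = [b for b in "ACGT" if b != ref_base]
            rec.payload = alts[0] if ref_base != "N" else "A"
        try:
            mask.reserve_all(rec.reserved_intervals())
        except OverlapError as exc:
            raise ExactTableError(
                f"exact-mode variant at position {row.position} overlaps "
                f"another row: {exc}"
            ) from exc
        if row.csv_group:
            groups.setdefault(row.csv_group, []).append(rec)
        else:
            records.append(rec)
    for label, comps in groups.items():
        for i, comp in enumerate(comps, start=1):
            comp.csv_type = label
            comp.csv_index = i
        start = min(c.start for c in comps)
        end = max(c.end if c.end > c.start else c.start + 1 for c in comps)
        records.append(
            VariantRecord(
                id=counter, vtype="CSV", start=start, end=end,
                length=end - start, components=comps, csv_type=label,
            )
        )
        counter += 1
    records.sort(key=lambda r: r.start)
    return records


# ---------------------------------------------------------------------------
# Mode dispatch
# ---------------------------------------------------------------------------

def _require(value, flag: str):
    if value is None:
        raise ValueError(f"this mode requires {flag}")
    return value


def learn_profiles_from_beds(
    bed_paths, sample_ids, reference: ReferenceSequence, bin_size: int
) -> tuple[dict, dict]:
    """Learn per-type spatial profiles and length distributions from BEDs."""
    obs = read_bed_variants(bed_paths, sample_ids, strict=False)
    obs = [o for o in obs if 0 <= o.start < reference.length]
    partition = partition_bins(reference.length, bin_size)
    mode = "multi" if len(set(sample_ids)) > 1 else "single"
    profiles: dict = {}
    length_dists: dict = {}
    for vtype in sorted({o.vtype for o in obs}):
        key = "TRA" if vtype.startswith("TRA") else vtype
        profiles[key] = learn_spatial_profile(obs, partition, vtype, mode=mode)
        try:
            length_dists[key] = learn_length_distribution(obs, vtype)
        except ValueError:
            pass
    return profiles, length_dists


def run_mode(
    config: SimulationConfig,
    reference: ReferenceSequence | None = None,
    *,
    bed_paths=None,
    sample_ids=None,
    tr_bed=None,
    tr_regions=None,
    exact_rows=None,
    exact_path=None,
    vcf_path=None,
    vcf_expression=None,
    profiles=None,
    length_dists=None,
    out_prefix=None,
) -> RunResult:
    """Dispatch one of the eight operational modes and (optionally) emit files."""
    mode = config.mode
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "vcf_filter":
        rows = filter_population_vcf(
            _require(vcf_path, "-vcf_file"), _require(vcf_expression, "a filter expression")
        )
        result = RunResult(config=config, exact_rows=rows)
        if out_prefix is not None:
            path = Path(out_prefix).with_suffix(".exact.tsv")
            path.parent.mkdir(parents=True, exist_ok=True)
            write_exact_table(rows, path)
            result.paths["exact_table"] = path
        return result

    reference = _require(reference, "a reference sequence")

    if mode == "exact":
        if exact_rows is None:
            exact_rows = read_exact_table(_require(exact_path, "-exact table"))
        records = build_exact_variants(exact_rows, reference)
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
        records = assign_genotypes(records, config.ploidy, config.het_prob, rng)
        donors, cmap = apply_variants(reference, records, config.ploidy)
        result = RunResult(
            config=config, variants=records, donors=donors, coordinate_map=cmap,
            realized_counts={"exact": len(records)},
        )
    else:
        if tr_regions is None and tr_bed is not None:
            tr_regions = read_bed_regions(tr_bed)
        if mode in ("mimic", "wave", "wave_region"):
            if profiles is None:
                bed_paths = _require(bed_paths, "empirical BED file(s)")
                sample_ids = sample_ids or [f"s{i+1}" for i in range(len(bed_paths))]
                profiles, learned_lengths = learn_profiles_from_beds(
                    bed_paths, sample_ids, reference, config.bin_size
                )
                length_dists = {**learned_lengths, **(length_dists or {})}
            if mode == "wave_region":
                _require(tr_regions, "a tandem-repeat BED")
                _require(config.tr_weights, "tr_weights")
        elif mode in ("csv", "uniform", "uniform_parallel"):
            profiles = profiles  # flat profiles are synthesized per type
        result = simulate(config, reference, profiles, length_dists, tr_regions)

    if out_prefix is not None:
        result.paths = emit_outputs(
            reference, result.variants, result.donors,
            result.coordinate_map, out_prefix,
        )
    return result
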