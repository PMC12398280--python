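# Methods

`svforge` simulates genomic variation on a single reference sequence: simple
structural variants (deletions, insertions, inversions, tandem and dispersed
duplications, balanced and unbalanced intrachromosomal translocations),
eighteen complex rearrangement templates, small indels (1–5 bp) and SNPs.
It produces haplotype-resolved donor sequences, a machine-readable truth
table, and a VCF 4.3 file. This note records the model, the numerical
choices, and what the tests do and do not demonstrate.

## Distribution learning

Real structural variants are not uniform along chromosomes: their density
rises near telomeres and inside tandem-repeat (TR) regions, and their
length spectrum is multi-modal. `svforge` learns both features
nonparametrically from cohorts of observed variants (BED-like tables, one
file per sample).

**Length distribution.** For a variant type *t*, the probability of length
*l* is the observed count of length-*l* events divided by the total count of
type-*t* events, pooled over all samples:
`P_t(l) = n_{t,l} / Σ_{l'} n_{t,l'}`. No smoothing is applied; simulation
draws only lengths that occurred in the input. When a type has no
observations the learner raises and the caller falls back to a user length
range (uniform integer draw).

**Spatial profile.** The sequence of length *G* is tiled into `M = ⌊G/L⌋`
bins of size *L* (default **500 kbp**; `M` is forced to 1 when `G < L`).
Bins 1..M−1 have width exactly *L* and the terminal bin absorbs the
residual bases, so it is between *L* and 2*L* wide. An observation is
attributed to the bin containing its **start** coordinate, even when it
spans a boundary — a documented choice; binning by midpoint or overlap
fraction would change counts only for the small fraction of events that
straddle a 500 kbp edge. With one input sample the per-bin counts `c_j`
are used directly; with *N* samples the per-bin mean `μ_j` and standard
deviation `σ_j` are computed. `σ_j` uses the population estimator
(divide by *N*, `ddof=0`) by default; the sample estimator is available
via `ddof=1`. Bin probabilities are `p_j = c_j / Σ c_k` (or normalised
means).

Cohorts that share individuals are deduplicated by sample identifier: the
first collection containing an identifier wins.

## Sampling hierarchy

Each variant type gets a total `v_total`: a user count, a per-bp rate
converted as `round(rate · G)`, or — in sum-preserving mode — the profile
total (`Σ c_j`, or `round(Σ μ_j)` for cohorts).

Totals are spread over bins in one of two ways:

* **fixed** — `k_j = c_j` (single sample) or `k_j = ⌊μ_j⌋` (cohort).
  Flooring can undershoot a requested total; the realised total wins and
  the discrepancy is logged.
* **random** — for cohorts, the counts are first redrawn from a
  nonnegative discrete normal with moments `(μ_j, σ_j²)` — realised as
  draw-round-clamp-at-zero, chosen over rejection resampling because it
  always terminates and biases only bins whose mean is within ~2σ of
  zero; a single sample's counts stay as observed. Then
  `(k_1..k_M) ~ Multinomial(v_total, p)`. All-zero count vectors fall
  back to uniform `p` with a warning.

Within its bin, a variant start is uniform over the *admissible* positions:
starts `s` with `[s, s+len)` clear of every reservation and `s+len ≤ G`.
In TR-aware modes the admissible starts are split into TR and non-TR pools,
the pool is chosen with the configured probabilities (an empty pool falls
through to the other), and the draw is uniform within the pool.

Small-indel lengths follow a fixed empirical law:
`P(1..5) = 6/8, 1/8, 1/16, 1/32, 1/32`. SNP alternatives are drawn from a
4×4 substitution matrix with zero diagonal; the default is uniform over the
three alternatives, and any user matrix (e.g. learned from a variant
database) can be supplied as a TSV. Insertion alleles are novel uniform
A/C/G/T strings; the provenance of inserted sequence is not modelled.

## Non-overlap and generation order

Types are generated strictly in the order: translocations, inversions,
tandem duplications, complex templates ID1–ID18, deletions, insertions,
small deletions, small insertions, SNPs. An occupancy mask (sorted disjoint
half-open intervals) records every base a variant consumes; later variants
are placed only on free positions, so the final set is non-overlapping by
construction. Conventions:

* Point events (insertions, SNPs) reserve 1 bp at their site.
* Duplications also reserve the 1 bp copy-insertion point (tandem and
  dispersed). This guarantees no two edits ever share a breakpoint, which
  makes truth-table re-application order-free.
* Runs of `N` in the reference are auto-added to the blocked regions
  (disable with `auto_block_n=False`); user blocked regions behave the same.
* Placement is rejection-based with a per-variant retry cap (default
  1,000 attempts, resampling both length and position). On exhaustion the
  variant is skipped with a logged warning; skipped counts are reported
  per type and are **not** redistributed to other bins.

Unbalanced translocations **move** region B to region A's start by default
(donor shrinks by |A|); a length-conserving copy semantics (B also kept in
place) is available via `tra_unbalanced_copy`. Balanced vs unbalanced is
chosen per event with probability 0.5 by default.

## Complex templates

A complex SV is one event composed of proximal simple edits. The 18
templates are a data-driven registry (`csv_constructors`); each plan lays
components left-to-right from an anchor with independent gaps of 0–100 bp
(configurable). Published taxonomies describe these rearrangements
graphically and not always unambiguously; the registry encodes one
reasonable reading per name, and alternative definitions drop in by editing
the registry, not the code. Component lengths come from a user length
distribution or range (default 50–500 bp); every component classed as an SV
respects the 50 bp floor. All component reservations are atomic — either
the whole composite fits or nothing is reserved and the anchor is
resampled.

## Donor construction and outputs

Every simple variant reduces to one or two replace primitives
`(start, end, replacement)`. Because reserved intervals are disjoint and
breakpoints are never shared, the primitives commute; they are applied in
one ascending sweep per haplotype, which also yields each variant's donor
coordinates. The donor-length identity
`len(donor) = G − deleted + inserted` is asserted on every application.

Genotypes: each variant is homozygous with probability `1 − het_prob`
(default `het_prob = 0.5`), else assigned to one uniformly chosen
haplotype; ploidy 1 forces homozygosity. Ploidy is arbitrary (`ploidy ≥ 1`),
so polyploid genomes are simulated by raising it, or by processing
homologous chromosome sets in separate runs.

Outputs: a donor FASTA with one record per haplotype; a tab-separated truth
table with one row per simple event (composites expanded, linked by
`event_id`/`csv_type`/`csv_index`), 0-based half-open coordinates, payloads
and per-haplotype donor coordinates — sufficient to re-derive the donor
with a plain string editor; and a VCF 4.3 with symbolic ALT alleles,
`SVTYPE`/`SVLEN`/`END`, full insertion alleles in `INSSEQ`, and
`CSV-TYPE`/`CSV-INDEX` on composite components. VCF positions follow the
left-anchor convention (POS names the base before the event), so for a
deletion `END = POS + length`. Small indels are written as explicit
REF/ALT sequences. Note the hyphenated `CSV-TYPE`/`CSV-INDEX` keys sit
outside the letter-of-the-grammar INFO name set; htslib-based parsers
(pysam, cyvcf2, bcftools) accept them with at most a pedantic warning.

## Parallel execution and determinism

The bin sequence is split into contiguous segments (default
`min(M, 4)`, configurable); each segment gets its own occupancy mask and
its own counted RNG stream derived from `(seed, segment index)`, and no
variant may cross a segment boundary. Per-bin allocations are computed
globally before segmentation, so segments inherit exactly their bins'
counts. Worker count affects only scheduling: any `cores` value produces
identical output for the same seed and segmentation — reproducibility is a
contract here, not an accident. A segment narrower than the largest
requested variant raises a configuration error. Genotype assignment and
allocation use separate streams spawned from the root seed, applied after
the merge, so they are also segment-layout-stable.

## Modes

* **mimic / wave** — learn profiles and length distributions from BEDs,
  then simulate. The original tool's built-in human distributions
  (hg19/hg38 benchmark sets) are not bundled; the same mechanism runs from
  any user BED cohort or precomputed profile sidecar (TSV of bin, counts,
  σ, p).
* **wave-region** — wave plus TR/non-TR placement weights against a TR BED.
* **csv** — per-template composite counts, plus any simple types.
* **uniform / uniform-parallel** — flat profile with `p_j` proportional to
  bin width, which makes the bin-then-position hierarchy exactly a global
  uniform draw (and makes uniform mode a special case of wave mode — a
  tested equivalence).
* **exact** — validated table of fixed positions; rows sharing a
  `csv_group` label become one composite. Overlapping rows are an error,
  never silently moved. Deletion/insertion rows shorter than 50 bp are
  routed to the small-indel classes; lengths 6–49 bp fit neither class and
  are rejected.
* **vcf** — filter a population SV VCF by AND-ed `KEY OP NUMBER` clauses
  on INFO fields (every key must be declared in the header), drop
  overlapping survivors keep-first-by-coordinate, and emit an exact-mode
  table. No sequence is generated.

## What the synthetic fixtures do and do not show

The fixture cohort generator plants a known truth: telomere-biased bin
probabilities, a discrete length mixture with modes near 300 / 2,500 /
6,000 bp (echoing published human SV length peaks), per-sample count
noise, and uniform positions within bins. Recovery tests (total-variation
distance of learned vs true profile < 0.05 at 10,000 observations;
chi-square goodness-of-fit of simulate-then-rebin counts at α = 0.01)
therefore validate the learning/sampling machinery, not biological realism:
real cohorts have correlated breakpoints, reference-specific repeat
structure, and caller-specific ascertainment that the fixtures deliberately
omit.

Test and acceptance problem sizes are deliberately modest — 10 kb fuzz
references with ~50 variants, 1–5 Mb references for binning and
parallelism checks, 10⁴–10⁵ draws for distributional laws — chosen so the
whole suite exercises every code path in about a minute while keeping
every statistical assertion well-powered at its stated α.

## Known limitations

* Single-sequence architecture: no interchromosomal events.
* Insertion content is random; no mobile-element or tandem-expansion
  sequence models.
* No breakpoint microhomology or junction context.
* The default substitution matrix is uniform; empirical transition
  matrices must be supplied by the user.
* Exact-mode deletions/insertions of 6–49 bp are rejected (between the
  small-indel and SV classes).
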