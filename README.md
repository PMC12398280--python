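# svforge

Benchmarking studies of structural-variant (SV) callers need truth sets:
genomes whose variants are known exactly. Real SVs are not uniform — they
cluster near telomeres and inside tandem-repeat regions, and their length
spectrum has pronounced modes — so simulators that scatter variants
uniformly produce misleading benchmarks. `svforge` learns the spatial and
length distributions of variants nonparametrically from empirical cohorts
(BED tables of called variants, one per sample) and then simulates
non-overlapping, haplotype-resolved variation on any reference sequence:
simple SVs (deletion, insertion, inversion, duplication, intrachromosomal
translocation), 18 complex rearrangement templates (dupINV, delINV,
dispersed duplications, …), small indels and SNPs. Each run emits a donor
FASTA (one record per haplotype), a truth table, and a VCF 4.3 ready for
read simulators and benchmarking tools (Truvari, vcfdist, …).

The core model: for variant type *t* the length law is the empirical
histogram `P_t(l) = n_{t,l} / Σ_{l'} n_{t,l'}`; the sequence is tiled into
bins of size *L* (default 500 kbp, terminal bin absorbing the residue) and
per-bin counts `c_j` (or cohort means `μ_j` and standard deviations `σ_j`)
define bin probabilities `p_j = c_j / Σ_k c_k`. A type's total `v_total` is
allocated to bins either *fixed* (`k_j = c_j` or `⌊μ_j⌋`) or *random*
(`(k_1..k_M) ~ Multinomial(v_total, p)`, cohort counts first redrawn from a
nonnegative discrete normal), then starts are uniform over the positions
still free under a global non-overlap mask. Small-indel lengths follow
`P(1..5) = 6/8, 1/8, 1/16, 1/32, 1/32`; SNP alternatives come from a
substitution matrix with zero diagonal. Details: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a mixed variant set, uniformly placed, on a 1 Mb toy reference
(`svforge.fixtures.make_reference` writes one, or bring your own FASTA):

```bash
svforge uniform -r chrToy.fa -o demo --seed 11 \
    --sv-del 20 --sv-ins 15 --sv-inv 5 --sv-dup 5 --sv-trans 2 \
    --small-del 30 --small-ins 30 --snp 50
```

prints

```
realized counts: {'TRA': 2, 'INV': 5, 'DUP': 5, 'DEL': 20, 'INS': 15,
                  'SMALL_DEL': 30, 'SMALL_INS': 30, 'SNP': 50}
fasta: demo.donor.fasta
truth: demo.truth.tsv
vcf: demo.vcf
```

`realized counts` are the per-type numbers actually placed (they can fall
below a request only when the mask runs out of room; skips are reported
separately). The truth table holds one row per simple event with 0-based
half-open reference coordinates, the allele payload, the genotype and the
donor coordinates per haplotype:

```
id  event_id  csv_type  csv_index  vtype      ref_start  ref_end  length  ...  genotype
1   1         .         .          TRA_UNBAL  344285     344395   110     ...  1|1
2   2         .         .          TRA_BAL    494124     494336   212     ...  0|1
```

and the VCF uses symbolic SV alleles with 1-based left-anchored positions:

```
chrToy  3074  sv37   C  <INS>  .  PASS  SVTYPE=INS;SVLEN=138;END=3074;INSSEQ=CGACACGG...  GT  1|1
chrToy  5482  sv119  C  T      .  PASS  SVTYPE=SNP                                        GT  0|1
```

The same library surface drives the other modes: `wave`/`mimic` (learn
profiles from `--bed` cohorts), `wave-region` (TR-weighted placement),
`csv` (complex templates, e.g. `--csv-count ID4=10`), `exact` (fixed
positions from a table), and `vcf` (filter a population SV VCF, e.g.
`--filter "AF_fin > 0.001"`, into an exact-mode table). From Python:

```python
from svforge import SimulationConfig, run_mode
from svforge.fixtures import make_reference

ref = make_reference(1_000_000, seed=7)
cfg = SimulationConfig(mode="uniform", counts={"DEL": 100, "SNP": 500}, seed=11)
result = run_mode(cfg, ref, out_prefix="demo")
```

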