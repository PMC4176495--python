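# compscan

Dosage-compensation analysis of the *Drosophila* male X chromosome, as a
tested, reusable pipeline with a fully seeded synthetic-data generator.

In *Drosophila melanogaster* males the single X chromosome is
transcriptionally upregulated to match the two female copies.  The MSL
complex (MSL1/2/3, MLE, MOF and the roX RNAs) binds the male X and
deposits H4K16 acetylation over gene bodies, but many expressed X-linked
genes carry no detectable MSL/MOF signal.  This package implements the
chain of analyses that quantifies that situation:

- **Compensation calls** — genes expressed (log2 ≥ 6) in both sexes are
  dosage compensated when the male−female log2 ratio lies strictly
  within the reference autosomal arm's mean ± 1 SD (3L by default).
- **Gene binding values** — per-nucleotide IP and input read counts are
  median smoothed (10 bp), turned into floored log2 IP/input ratios,
  median-centered, re-smoothed (200 bp, windows with < 10 points
  discarded); a gene's binding value is the mean of the top 50 % of the
  ratio values at 10 bp grid points in its exons, excluding the first
  200 bp of exonic sequence.  Genes are **bound** above the reference
  arm's mean + 1 SD and binned into (3,4], (4,5], (5,∞).
- **Copy-number ratios** — 1 kb-median-smoothed input coverage averaged
  per gene gives log2 male/female ratios; X vs autosomes is tested with
  a Mann–Whitney U (exact, tie-aware, for small samples).
- **Downstream comparisons** — knock-down/mutant effect scores by
  binding bin, long (> 10 kb) vs short bound genes, the length–effect
  correlation, distances to high-affinity sites, and under-replication /
  housekeeping overlap fractions.
- **Synthetic data** — a generator emulating every input (annotation,
  two-sex expression, IP/input coverage with exon-restricted enrichment
  and promoter-only autosomal signal, knock-down expression, sites and
  labels) with ground truth always emitted, so every step's recovery is
  testable.

See `docs/methods.md` for the full model and parameter documentation.

## Worked example

The numbered drivers under `analysis/` run the whole study on the shared
synthetic dataset (seed 42, two 6.5 Mb arms, 850 genes each):

```sh
python analysis/01_simulate_study.py
python analysis/02_expression_compensation.py
python analysis/03_chip_binding.py
python analysis/04_copy_number.py
python analysis/05_downstream_comparisons.py
```

which prints, among other lines:

```
3L ratio mean +0.005, SD 0.483 -> compensation bounds (-0.48, +0.49)
89.2% of expressed X genes classified dosage compensated (truth label: 91.3%)
238 of 606 compensated X genes are unbound by the MSL/MOF proxy
median log2 male/female ratio: X +0.000, autosomes +0.000
knock-down effect by binding bin (median log2):
   Unbound: -0.010 (n=261)
     (3,4]: -0.147 (n=67)
     (4,5]: -0.182 (n=89)
   (5,inf): -0.263 (n=70)
housekeeping: 66% of bound vs 30% of unbound genes
```

Reading this: the 3L male/female ratio spread sets the compensation
bounds; ~89 % of expressed X genes fall inside them, close to the 91 %
simulated as truly compensated.  A large minority of compensated genes
carries no MOF-type binding, yet their male/female copy-number ratio is
indistinguishable from autosomes (so compensation is not a copy-number
artifact), and knock-down effects grow monotonically with binding
strength while unbound genes are essentially unaffected — the structure
the analysis is designed to expose.

The same pipeline runs end-to-end from a YAML config:

```sh
compscan run --seed 7 --out results/run
compscan expression --table expr.tsv --annotation genes.bed --reference-arm 3L
```

Every run writes a `manifest.yaml` recording the seed, the config
snapshot and every threshold actually used.

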