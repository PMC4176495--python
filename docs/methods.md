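# Methods

`compscan` re-implements, as a tested pipeline over synthetic data, an
analysis of dosage compensation on the *Drosophila melanogaster* male X
chromosome: which expressed X-linked genes are compensated, which of them
are bound by the MSL complex (using MOF/H4K16ac ChIP enrichment over gene
bodies as the proxy), whether apparent compensation could be a
copy-number artifact of polytene under-replication, and how knock-down /
mutant expression effects relate to binding strength and gene length.

## The analysis procedure

### Expression and compensation calls

Input is a table of log2 expression values, one row per gene, one column
per condition (biological replicates are collapsed to their median at
read time).  A gene is **expressed** when its value is ≥ 6 (log2) in
every sample considered; "expressed in both sexes" is the intersection
over the male and female samples, and the boundary is inclusive.

For expressed genes the statistic of interest is the ratio
r<sub>g</sub> = log2(male) − log2(female).  A reference autosomal arm
(default 3L) provides the calibration: with mean m and sample standard
deviation s (n−1 denominator) of the reference ratios, a gene is
**dosage compensated** iff

  m − s < r<sub>g</sub> < m + s   (both inequalities strict).

Per-arm descriptive statistics (n, mean, SD, skewness) are reported for
all arms.

### ChIP enrichment and gene binding values

Starting from per-nucleotide read counts for an IP sample and its input:

1. counts are median smoothed with a 10 bp centered window and sampled at
   10 bp intervals genome-wide;
2. at every grid position where the smoothed IP has at least one read, a
   log2 IP/input ratio is formed; the input value is floored at the
   genome-wide input mean, and the floor itself is never below 4 reads
   (protection against near-zero denominators);
3. all ratios are reduced by their genome-wide median, absorbing the
   IP/input sequencing-depth difference;
4. the centered ratio is median smoothed with a 200 bp window; windows
   with fewer than 10 data points are discarded (missing).

The **gene binding value** collects the final ratio at the grid points
inside a gene's exons (introns excluded), removes points whose spliced
exonic offset from the gene's 5′ end is below 200 bp, and — if at least
10 points remain — takes the mean of the top 50 % (count ⌈n/2⌉) of the
values.  Genes with fewer than 10 points are unqualified and excluded.
A gene is **bound** when its value strictly exceeds the reference-arm
mean + 1 SD (computed over expressed, qualified reference genes).  Bound
genes are grouped into the non-overlapping bins (3,4], (4,5], (5,∞);
bound genes with values ≤ 3 fall between the cutoff and the first bin
and are excluded from binned analyses.

Window geometry is centered half-open, [pos − w/2, pos + w/2), truncated
at arm boundaries; an even-size window median is the mean of the two
central values.

### Copy number

Per-nucleotide input coverage of each sex is median smoothed with a 1 kb
window, sampled at 10 bp, averaged over each gene's full genomic span
(introns included), and the per-gene statistic is
log2(mean male / mean female).  Because the two input libraries may
differ in depth, each smoothed track is first normalized to its
autosomal median (a flag disables this).  X ratios are compared to pooled
autosomal ratios with a two-sided Mann–Whitney U test.

### Downstream comparisons

Knock-down / mutant **effect scores** are log2(treatment) − log2(control)
for genes expressed (≥ 6) in the control.  The pipeline reports: per-bin
effect summaries with Mann–Whitney tests of each bin against pooled
autosomal effects; bound long (> 10 kb) vs short (< 10 kb) gene effects
(a gene of exactly 10 kb goes to the short class); the Pearson
correlation of effect with transcript length (bp scale, and log10 as an
alternative since the axis transform of the original figure is
unstated); distances from gene spans to the nearest high-affinity site
(0 on overlap, else the bp gap to the nearest site edge on the same arm;
genes on arms without sites are undefined and excluded from group
means); and overlap/label fractions (under-replicated regions,
housekeeping flags).  Transcript length is the difference between gene
start and end positions, introns included.  No multiple-testing
correction is applied — each comparison reports its raw p-value and the
report carries the number of tests performed.

### Mann–Whitney U implementation

U counts pairwise wins plus half-ties (computed via midranks).  When the
smaller group has ≤ 8 values and the pooled size is ≤ 500, the p-value
is exact: the permutation distribution of U over all C(n, n₁) group
labelings is obtained by a subset-sum counting recursion over doubled
midranks, which equals full enumeration (verified against it) but is
polynomial in n and remains valid under ties.  Larger samples use the
normal approximation with tie-corrected variance and continuity
correction.  Two-sided p-values are 2·min(P(U ≤ u), P(U ≥ u)), capped at
1.  The approximation and the exact distribution agree closely in the
tails but can differ by > 0.02 at mid-range p for tiny groups — which is
precisely why those sizes are routed to the exact branch.

## The synthetic-data generator

The generator emulates every input of the analysis with known ground
truth, fully determined by one seed (each stage draws from its own
derived stream, so stages re-run in isolation reproduce exactly).

**Annotation** — two arms (X and 3L by default), non-overlapping genes
with log-normal lengths (median 3 kb, log-SD 1.1, matching the
right-skewed fly gene-length distribution), 1–6 exons per gene, both
strands.

**Expression** — a fraction of genes (default 20 %) sits below the
detection floor; expressed genes draw a base level from a normal
truncated above the floor (mean 8.5, SD 1.2).  The male−female ratio has
two variance components: technical ratio noise (SD 0.2, split equally
between the sexes) applied to every gene, and a per-gene biological sex
bias, N(0, 0.45), on autosomes only.  Compensated X genes have zero sex
bias; non-compensated X genes are shifted by −1 in males (the ~2-fold
deficit expected without compensation).  The split into two components
is what makes the compensation classifier meaningful: the autosomal
reference spread (√(0.2² + 0.45²) ≈ 0.49, matching the observed
autosomal ratio SDs of ~0.33–0.51 and reference bounds near (−0.55,
0.47)) is wide relative to the compensated-gene spread (0.2), so truly
compensated genes fall inside the reference mean ± 1 SD with probability
≈ 0.99 and the classified fraction tracks the simulated fraction.

**ChIP coverage** — per-nucleotide counts are Poisson around a
configurable depth (default 10 reads/bp for IP and both inputs).  Bound
genes multiply the IP rate over their exons by a per-gene fold drawn
log-uniformly from [2, 64]; autosomal genes multiply the IP rate by 4
over a fixed promoter window (TSS − 200 to TSS + 200) only, mimicking
NSL-type promoter binding.  The X-arm rates of the IP and the male input
carry the configured male copy-number multiplier.

**Knock-down expression** — the log2 drop of a gene with true fold f and
length L is

  drop = d·(f − 1)/(f − 1 + k) · s/(s + L),

with d = 0.4, half-saturation k = 15 and length scale s = 20 kb, plus
ratio noise of SD 0.1, clamped so residual expression never falls below
50 % of wild-type.  The defaults place a strongly bound short gene at
≈ 80 % residual expression and an unbound gene at no change, and make the
drop provably monotone increasing in binding and decreasing in length.

**Sites, labels, regions** — high-affinity sites (default 50) are placed
on X, preferentially (p = 0.8) near bound genes with a 5 kb positional
SD; housekeeping flags are Bernoulli with separate rates for bound (0.7)
and unbound (0.3) genes; under-replicated regions (default 10 × 50 kb)
are uniform.

### What the generator does not emulate

Coverage rates are flat along the genome — there is no GC/mappability
bias, no fragment-length autocorrelation beyond the smoothing window,
and no read-level simulation.  Expression has no probe effects or
between-replicate structure (replicates are assumed pre-collapsed).
Binding folds are independent of gene length and expression level.
Consequently, passing recovery tests demonstrates the correctness and
calibration of the procedure under these idealized conditions, not its
robustness to array/sequencing artifacts.  Two observed consequences:
the synthetic length–effect Pearson correlation (~0.1) is weaker than
the corresponding observed value in real mutant data, because most
synthetic genes are much shorter than the 20 kb attenuation scale; and
flat Poisson coverage makes 1 kb window medians almost surely equal to a
single integer, so under equal copy number the per-gene copy ratios are
massively tied at 0 and the X-vs-autosome Mann–Whitney is conservative
(rejecting ~2 % at nominal 5 %) — a knife-edge property of integer count
medians that disappears as soon as coverage rates vary along the genome.

## Numerical choices and degenerate inputs

- Internal coordinates are 0-based half-open everywhere; GFF3 is
  converted on read, BED taken as-is.
- The 200 bp exonic exclusion is strand-aware in spliced exonic
  coordinates by default (a flag selects the strand-blind variant), since
  "exonic sequence" is transcript-oriented.
- Top-50 % count uses the ceiling for odd n.
- The "at least one mapped read" condition is evaluated on the smoothed
  IP track, following the order of the procedure.
- The input mean used for flooring is per-sample and genome-wide (all
  grid positions with data, all arms).
- The binding reference statistics are computed over expressed genes by
  default (with an option to use all qualified genes).
- Genes whose copy-number mean is zero or undefined in either sex are
  reported as NaN and logged, not dropped silently.
- Median smoothing of an empty window, or a window below the minimum
  point count, yields missing, never zero.
- The promoter-immunity property (autosomal promoter signal does not
  move binding values) holds exactly for the typical gene; the 200 bp
  second-pass window can smear promoter signal into roughly one grid
  point past the exonic exclusion, shifting minimum-size (10–20 point)
  genes by up to ~0.1 log2.  Genes with ≥ 40 exonic points are immune to
  < 0.05 log2.

## Problem sizes

The bundled analysis drivers and the acceptance script use two arms of
6.5 Mb with 850 genes each (~1300 expressed genes), which reproduces the
headline fractions stably; recovery and calibration tests use 500–2500
genes and 20–500 seeds as appropriate for the quantity under test.
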