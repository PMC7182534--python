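# Methods

## Scope and coordinate conventions

`methtiles` starts at the methylation-call level: its inputs are
methcounts-dialect tables (chrom, 0-based position, strand, context,
methylation fraction, coverage), BED interval files, a UCSC-style
chrom.sizes file, and a gene-level log₂ fold-change table. Read QC,
trimming, alignment, duplicate removal and bisulfite-conversion estimation
are upstream of the package and out of scope. All coordinates are 0-based
half-open throughout; chromosome names are compared by exact string match
(an opt-in flag harmonizes a leading "chr", off by default, because silent
renaming is a classic source of cross-file mismatches). Sex and
mitochondrial chromosomes ({chrX, chrY, chrM}) are excluded by default, as
haploid/hemizygous and organellar methylation is not comparable across the
diploid autosomal model.

## Site-level processing

CpG-context rows are retained, others dropped with a logged count. Sites
with coverage 0 are kept by the readers — they mark assayed-but-uncovered
CpGs — but their methylation value is stored as missing (NaN), never 0, and
they carry zero weight in every average; a `drop_uncovered` flag removes
them at read time for users who prefer the compact form. Symmetric-CpG
merging pairs a + strand site at *p* strictly with a − strand site at
*p* + 1 on the same chromosome and pools them by coverage weighting; the
merge conserves total read count, is idempotent, and anchors the merged
site at the + strand C. Replicate pooling uses the same coverage-weighted
union: a site present in only some replicates enters with the data it has.

## Regions and regional methylation

Two region families: a genome-wide grid of fixed-width tiles (default
1,000 bp — the scale over which CpG methylation is strongly correlated),
the last tile per chromosome truncated; and SNP-centred windows
[*p* − w/2, *p* + w/2), clipped at chromosome ends. For even widths the
centre base is the first base of the right half (a half-open symmetric
choice; nothing downstream depends on it). Overlapping or duplicate
SNP-centred windows are deliberately *not* merged: each locus is its own
unit of analysis, so per-list counts remain interpretable.

Regional methylation is the coverage-weighted mean (methylated reads over
total reads) of the covered CpGs whose anchor position falls in the
region; an unweighted per-CpG mean is available behind a flag. Regions
with no covered CpG are reported with missing methylation rather than
dropped, so "tiles with data" is always an explicit, logged quantity.

## DMR calling and bookkeeping

A call exists only for regions with data in both conditions — a
methylation difference is undefined otherwise, and this "tiles with data
in both" count is the denominator of every reported percentage. The call
is a pure threshold: |Δ| > 0.2 with Δ = m_ref − m_test, strict at the
boundary. Comparisons use a 1e-9 guard so float64 representation noise
(0.9 − 0.7 evaluates just above 0.2) cannot flip a boundary call. There
is deliberately no statistical DMR model (no smoothing, no beta-binomial
test): the method under study is the threshold on regional means, and the
package reproduces exactly that. Reported percentages are rounded half-up
to two decimals, matching conventional table formatting; summaries carry
raw counts so every percentage is recomputable (the pipeline's
self-consistency check does exactly this on its own outputs).

## Depletion testing

The null for "does locus set S contain fewer DMRs than chance?" is built
by drawing |S| windows from the background call set *without replacement*
(each draw is a pseudo locus set), counting DMRs, and repeating B times
(default 100, configurable upward). Significance is the add-one empirical
lower tail p = (1 + #{draws ≤ observed})/(1 + B), which is never exactly 0
under finite resampling and is conservative for discrete draws. An
upper-tail mode exists for enrichment questions. The analytic
hypergeometric tail appears only as a test oracle — the headline inference
is purely resampling-based, matching the method under study. A separate
binomial lower-tail calculator (regularised incomplete beta via
scipy.stats.binom) supports threshold-adjustment arguments.

## Annotation and expression integration

Annotation intervals are coordinate-merged within each class before any
assignment, making results invariant to input order. Each locus — a SNP
position or a tile midpoint — receives exactly one class with precedence
promoter > exon > intron > intergenic; promoters win because they are the
regulatory class of interest, and the precedence is a configurable
argument. Closest-gene lookup uses interval gap distance (0 on overlap,
bookended = 1, upstream/downstream not distinguished), with exact ties
broken by a seeded uniform choice so runs are reproducible.

Class-count comparisons between locus lists use the Pearson chi-square
statistic (no continuity correction, df = k − 1 for 2×k) with an optional
Monte-Carlo Fisher exact test: tables are sampled with margins held fixed
(scipy.stats.random_table) and the add-one fraction with null probability
≤ the observed table's is reported. The Monte-Carlo route (default 10⁵
tables, seeded) was chosen over network-algorithm exactness for bounded
memory and reproducibility on tables larger than 2×2.

Genes are split at |log₂FC| > 1, strict, so "exactly one log-fold" falls
in the low class; log₂ is assumed because it is the standard RNA-seq logFC
scale. Correlation of per-annotation Δ with the proximal gene's logFC is
Pearson by default (Spearman behind a flag), reported with n, and returned
as missing under zero variance or n < 3.

## Synthetic data: what it emulates, and what it does not

The generator emulates the post-alignment data regime of an
EBV-transformation WGBS comparison:

* **Baseline methylome** — per-CpG true methylation drawn from
  Beta(8.5, 1.5) (mean 0.85), matching the high methylation of activated
  B cells; CpG positions by exponential spacing with mean 100 bp.
* **Hypomethylated blocks** — non-overlapping blocks (default 20 kb)
  totalling a set genome fraction *f* (default 0.46), placed uniformly
  with starts snapped to the 1-kb tile grid so the planted fraction is an
  exact tile-scale property (arbitrary offsets would create half-shifted
  boundary tiles and bias recovery low). The shift *d* applies in the test
  condition only, mirroring the near-absence of hypermethylated tiles.
* **Observation model** — per strand and replicate, coverage ~
  Poisson(λ/(2·n_reps)) with methylated reads ~ Binomial(cov, true m);
  λ defaults to 6 (the shallow-coverage regime) over 3 replicates, and
  data are emitted strand-split so symmetric merging is exercised.
* **Locus sets** — background loci uniform over the genome; the
  "depleted" set accepts in-block candidates with probability ρ, giving
  expected inside-block fraction ρf/(ρf + 1 − f); ρ = 1 is the
  calibration null, ρ = 0 avoids blocks entirely.
* **Annotations and expression** — a deterministic gene layout (1-kb
  promoter, alternating exons/introns, one gene per 20 kb); promoters are
  exempt from the block shift by default, mirroring the observed
  promoter-sparing of EBV hypomethylation; logFC = α·(expected gene-body
  methylation loss) + N(0, σ), so exon/intron methylation carries
  expression signal and promoter methylation does not.

Presets: `paperlike` (f = 0.46, d = 0.25, λ = 6) for realistic noise, and
`crisp` (d = 0.4, λ = 20) for fast high-signal recovery tests. All
randomness flows from one seed; outputs are byte-identical per seed; truth
(blocks, locus flags, gene effects) is emitted alongside and never read by
the pipeline.

The generator does **not** simulate bisulfite reads, sequencing error,
mapping bias, CpG-density heterogeneity (islands/shores), chromosome-scale
covariates, or biological replicate heterogeneity (replicates share the
true methylome and differ only in sampling). Passing recovery tests
therefore demonstrates correctness of the bookkeeping and inference on
data satisfying the stated model, not robustness to real-data artefacts
upstream of the methylation calls.

## Problem sizes and determinism

Recovery and calibration checks run on a 1-Mb single-chromosome genome
(1,000 grid tiles, ~10,000 CpG dyads), a 1,500-locus background, 40-locus
query sets, 200 resampling draws per test and 200 simulated null queries;
the hypergeometric convergence check uses 10⁵ draws on a 20-tile
background. These sizes give binomial/resampling standard errors well
inside the asserted tolerances. Every stochastic component (simulation,
resampling, Monte-Carlo Fisher, tie-breaks) takes an explicit seed, and
the pipeline stamps outputs with the config hash and seed.

## Known limitations

* The depletion test conditions on the background call set; uncertainty in
  the background's own DMR calls is not propagated.
* The empirical p is discrete (resolution 1/(B + 1)) and conservative
  under heavy ties; raise `n_resample_draws` when finer resolution
  matters.
* Tile-level percentages depend on the coverage regime through the "tiles
  with data" denominator; comparisons across datasets with very different
  coverage should be interpreted with care.
* `closest_gene` scans per locus; for very large locus sets against large
  gene models an interval-tree batch implementation would be preferable.
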