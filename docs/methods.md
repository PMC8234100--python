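# Methods

## Gene models and the reference-exon reconstruction

A gene model holds two exon views: the exon chain of each annotated
transcript ("transcript exons", ordered in transcription direction, with
roles first/internal/last/only) and the locus's reference units ("genomic
exons"). Reference exon databases build the latter from curated annotation;
reconstructing them from the transcripts alone requires care, because a
naive merged union of all transcript exons absorbs exactly the features the
classifier must see:

* a transcript exon that retains an intron would fuse the two flanking
  reference exons, deleting the intron from the reference structure;
* a first/last exon extending into a flanking intron would move the
  reference boundary outward, making the terminal 10-nt rules vacuously
  untriggerable.

The package therefore (a) subtracts from each transcript exon every intron
of another transcript that it fully contains before taking the union, so
retained introns stay introns; and (b) anchors boundary comparisons on
*internal-exon evidence*: for each genomic exon, the reference first
position is the 5′-most first position among internal, non-retaining
transcript exons assigned to it (by maximal overlap, ties to the 5′-most
exon in transcription direction), and symmetrically for the last position.
Exon labels are `e1..eN` in transcription order; the gap after exon *k* is
intron `i<k>`. Coordinates are 1-based inclusive; BED output is 0-based
half-open. Single-exon transcripts get role `only` and are excluded from
the terminal-exon rules.

## Event classification

Six rules, evaluated per transcript exon against its corresponding genomic
exon, with first/last exons routed only to the terminal rules and internal
exons only to the splice-site rules (this precedence prevents a terminal
extension from also being called an acceptor/donor variant):

* **alternative first exon** — first exon of a transcript whose start lies
  ≥ `min_terminal_offset` nt (default 10) upstream, in transcription
  direction, of the internal-exon reference first position, provided other
  transcripts have internal exons at that genomic exon;
* **alternative terminal exon** — the mirror rule on last exons (labelled
  `ae<k>`);
* **alternative acceptor / donor site** — internal exon whose first / last
  position differs from the reference first / last position;
* **intron retention** — a whole reference intron contained in one
  transcript exon (retaining exons are excluded from boundary rules and
  boundary evidence);
* **exon cassette** — a genomic exon absent from a transcript that has
  exons strictly on both sides of it (a transcript that merely ends early
  is a terminal-exon phenomenon, not skipping).

Events are deduplicated on (gene, type, feature label), merging transcript
sets. A seventh category, `unknown`, is assigned by the quantification
stage to differentially used exon/intron regions matching none of the six
rules — e.g. a regulated intron with no retention evidence or a regulated
exon present in all transcripts.

## Splicing-index quantification

Size factors are median-of-ratios: factor_s = median over features with
all-positive counts of count_{f,s} / geometric mean_s(count_{f,·}).
Genes pass the expression filter when mean RPKM in at least one group
exceeds the 97.5th percentile (linear interpolation between order
statistics) of intergenic background RPKM; at least 20 background regions
are required for a stable threshold.

The splicing index itself is a reconstruction — the commercial exon-array
lineage of the statistic does not publish a formula. The package uses the
simplest statistic consistent with reporting a magnitude plus an up/down
direction: per sample, SI = (normalized feature count + 1) / (normalized
constitutive count + 1); per event, the fold-change is the ratio of group
mean SIs, reported as magnitude ≥ 1 with direction (ties report "up", +1)
and as a ± signed value. The pseudocount (default 1) regularizes
low-count features at a small attenuation cost (≈1% at the default
simulation depths). Significance is a two-sided Welch t-test on log2 SI —
no test is canonical here; Welch is the least-assumption parametric choice
and needs ≥ 2 samples per group (with 2-vs-2 designs it is fragile, which
is why the recovery suites run 5-vs-5). Events are retained at |SI-FC| ≥
1.5 and *uncorrected* p ≤ 0.05; no multiple-testing correction is applied,
by design. A consequence worth stating: with ~30 features tested at
uncorrected α = 0.05, a fully null dataset still yields at least one
passing feature in roughly half of replicates — the per-feature type-I
rate is controlled (measured ≈1.6%), the family-wise rate deliberately is
not.

Tallies report per-type counts and percentages rounded half-up to one
decimal; 58/113 computes to 51.3% (summary tables elsewhere print 51.4%
for this entry; the computed value is reported, the discrepancy is noted,
never emulated).

## qPCR quantification and tests

Replicate Cts are collapsed by arithmetic mean; ΔCt = target − reference
(GAPDH-style single reference gene); expression = 2^(−ΔCt). Group
fold-changes are ratios of geometric means — equivalent to 2^(−ΔΔCt) on
mean ΔCts — reported on the ±1 signed convention (no values in (−1, 1));
an arithmetic-mean variant sits behind a flag. The Long/Short ratio is
summarized per group as the arithmetic mean ± sample SD of per-subject
ratios. Expression comparisons are always nonparametric: two-sided
Mann–Whitney U (exact when min(n) ≤ 8 and tie-free, tie-corrected normal
approximation otherwise), Wilcoxon signed-rank for paired Long-vs-Short
contrasts (all-tied differences report p = 1), Kruskal–Wallis for three
groups with Dunn's rank post hoc and Bonferroni adjustment. A one-sample
KS test against a fitted normal is reported per group as an advisory
normality screen only.

## Biomarker combination and ROC

The two markers are combined by maximum-likelihood logistic regression on
(log2 long, log2 short); the score is the linear predictor. Under complete
separation the MLE diverges; scores along the diverging (Fisher
discriminant) direction are still returned with a warning — AUC depends
only on the ranking, which the diverging direction fixes. AUC uses the
rank (Mann–Whitney) formula with half-credit for ties, which equals the
trapezoidal area under the empirical curve; the 95% CI is DeLong's
structural-components estimator (point-checked against R pROC to 1e-10),
clipped to [0, 1]. Pearson panels report r, R² = r², the t-based two-sided
p on n−2 df, and the OLS line; incomplete pairs are dropped listwise and
counted, which is what produces panel sizes of 19/24 and 28/32 under the
generator's planted missingness.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of a two-stage design — a small
(default 2-vs-2) RNA-seq screen followed by a 24/72/32 three-group qPCR
cohort — with every planted quantity recorded in a truth file.

Counts: per (sample, gene), a gamma biological expression factor with
mean 1 and variance equal to the dispersion (default 0.1) multiplies all
of the gene's feature means; counts are Poisson given the factor, hence
marginally negative binomial with var = μ + 0.1 μ². The factor is shared
across the gene's exon, intron and constitutive features because all come
from the same RNA — this is what makes the splicing index cancel
biological variance, and it is the property that gives the planted −2.64
cassette event ~100% detection at 5-vs-5. Per-sample library depth is
drawn uniform(0.8, 1.2) so size-factor normalization is exercised.
Intergenic regions (40 × 1 kb, mean 1 count) set a meaningful background
threshold.

Cohort: reference Ct ~ N(24, 0.3); target Ct = reference Ct − log2(planted
expression) + ε, with (long, short) ε bivariate normal, SD 0.25 cycles and
the planted within-group correlation (0.601/0.890/0.528); two technical
replicates with 0.05-cycle noise. Planted geometric-mean expressions
encode the fold-changes −3.3 (long, AMI vs CTR), −4.5 and −4.2 (short, AMI
vs CTR/CAD) and the AMI long/short ratio 9.7. These planted values
over-determine the remaining ratios: the control-group ratio is forced to
3.3·9.7/4.5 ≈ 7.1 and is not independently adjustable. Covariates (HDL ~
N(50, 12), TG ~ N(150, 60) mg/dl, clipped at 1) get their planted Pearson
correlation to long log2 expression by the orthogonal-mixture
construction; 5 control and 4 AMI subjects carry missing lipids.

What passing tests therefore show: the pipeline's arithmetic and
inference recover known planted effects at the study's sample sizes. What
they do not show: performance on real cohorts. In particular, the 0.25-
cycle noise needed for tight fold-change recovery makes the two groups
almost perfectly separable, so the synthetic combined ROC sits at the
generator's analytic AUC (≈1.0) — real between-subject biological
variability is far larger, and clinical discrimination correspondingly
weaker. The generator makes no attempt to model batch structure,
amplification-efficiency differences, or read-level artifacts.

## Numerical choices and problem sizes

* Percentile convention: linear interpolation (numpy default).
* Percent rounding: half-up via Decimal, one digit.
* SI-FC tie at exactly 1: direction "up", signed +1.
* Welch test with zero variance in both groups: p = 1 if means equal,
  else 0.
* Exact Mann–Whitney only for tie-free inputs with min(n) ≤ 8.
* Recovery suites: 100 replicates for the count stage (5-vs-5) and
  cohort fold-changes, 50 for the acceptance script's cohort panel —
  chosen to keep each suite in seconds while leaving the medians stable
  to well under the stated tolerances.
* Seeds: all randomness flows from integer seeds through
  `numpy.random.default_rng`; replicate seeds are derived affinely and
  kept below 2^31.
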