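# splicedex

Alternative-splicing event detection and splice-variant biomarker analysis
for bulk RNA-seq + qRT-PCR study designs, motivated by the use of the two
*RECK* splice variants (Long, containing exon 18; Short, with an alternate
3′ terminal exon) as candidate blood biomarkers for distinguishing acute
myocardial infarction (AMI) from stable coronary artery disease (CAD).

The package implements the full analysis chain as a library with numbered
driver scripts:

1. **Gene models** (`gene_model`) — parse GTF/GFF3 into per-gene reference
   ("genomic") exons, per-transcript exon chains, constitutive regions
   (exonic intervals shared by every transcript), and intergenic background
   regions.
2. **Event classification** (`as_classifier`) — six rule-based event types
   per gene: alternative first exon and alternative terminal exon (10-nt
   boundary rules), alternative acceptor (3′) and donor (5′) splice sites,
   intron retention, and exon cassette/skipping, plus an `unknown` category
   for differentially used regions matching no rule.
3. **Splicing-index quantification** (`splicing_quant`) — median-of-ratios
   size factors, an RPKM background filter against the 97.5th percentile of
   intergenic RPKM, and per-event splicing-index fold-changes

   SI_s = (x_s/f_s + 1) / (c_s/f_s + 1),  SI-FC = mean_case SI / mean_ref SI,

   where `x_s` is the exon/intron count, `c_s` the gene's constitutive
   count and `f_s` the size factor of sample `s`; significance is a Welch
   t-test on log2 SI, and events are kept at |SI-FC| ≥ 1.5, p ≤ 0.05.
4. **Tallies** (`event_summary`) — per-type counts and one-decimal
   percentages of filtered events.
5. **qPCR expression** (`qpcr_expression`) — comparative-Ct quantification
   (expression = 2^(−ΔCt), ΔCt = Ct_target − Ct_GAPDH), geometric-mean
   group fold-changes on the ±1 signed convention, Long/Short ratios, and
   the nonparametric test battery (Mann–Whitney, Wilcoxon, Kruskal–Wallis
   with Dunn/Bonferroni post hoc, KS normality screen).
6. **Biomarker combination** (`biomarker_roc`) — logistic combination of
   the two markers' log2 levels, rank-formula AUC with tie half-credit and
   DeLong 95% confidence intervals (validated against R's pROC).
7. **Correlation panels** (`correlation`) — Pearson r, R², two-sided
   t-based p, and OLS line between expression and clinical covariates
   (HDL, triglycerides), with listwise deletion of incomplete pairs.
8. **Synthetic data** (`synthetic_data`) — seeded generators for all
   inputs: a toy annotation with a hand-derived event truth table, a
   2-vs-2 negative-binomial count simulator with planted splicing-index
   fold-changes, and a 24/72/32-subject three-group qPCR cohort with
   planted fold-changes (−3.3, −4.5, −4.2), ratio shift, and covariate
   correlations.

## Worked example

```
python analysis/01_simulate_inputs.py
python analysis/02_classify_events.py
python analysis/03_quantify_splicing.py
python analysis/04_qpcr_expression.py
python analysis/05_biomarkers.py
```

prints (seed 17):

```
[02] 8 events classified; output MATCHES the truth table
[03] planted event recovered: signed SI-FC -2.94 (planted -2.64), p = 0.00693
[04] long AMI vs CTR: FC = -3.11
[04] short AMI vs CTR: FC = -4.38
[04] short AMI vs CAD: FC = -4.13
[04] long/short ratio means: CTR 7.1, CAD 5.7, AMI 9.9
[05] combined ROC CAD vs AMI: AUC 1.000 [1.000, 1.000] (generator analytic AUC 1.000)
[05] CTR hdl: n=19 r=+0.695 R^2=0.483 (planted +0.545)
```

Reading: the classifier reproduces the expected event for each of the six
rules; the planted cassette-exon splicing-index fold-change of −2.64 comes
back as −2.94 from a single 2-vs-2 replicate (the median over 100
replicates sits within a few percent of −2.64); the cohort fold-changes
and covariate correlations recover their planted values within sampling
noise; and at the generator's default measurement noise the two markers
separate the CAD and AMI groups essentially perfectly, so the measured AUC
matches the generator's analytic AUC of 1.0 rather than any clinical
value. Tables land under `results/`.

The same stages are available as a CLI (`splicedex simulate|model|
classify|quantify|summarize|qpcr|roc|correlate`).

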