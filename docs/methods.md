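# Methods

## Model and procedure

The pipeline treats a perturbation's transcriptional footprint as a pair of
gene lists — *induced* and *repressed* — and measures, in any independent
expression profile, how coordinately those two lists separate. It has four
stages.

**1. Signature derivation.** Input is a log2 gene × sample matrix with a
group assignment (reference vs treated; more groups are allowed in the
ANOVA). Optionally, a matching raw-linear-intensity matrix gates the
candidate features first: a feature is kept when its per-row summary raw
intensity lies inside a detection window (default 50.0–35272.484, the span
of a typical microarray's reliable linear range). The window is applied to
the row **maximum** by default — a feature whose brightest measurement never
reaches the detection floor carries no usable signal — with `min` and `all`
variants exposed, since reasonable pipelines differ here. Per gene, a
classical fixed-effects one-way ANOVA on the log2 values yields an
F-statistic and its upper-tail p from the F distribution (with exactly two
groups, F = t² of the pooled two-sample t; asserted in the tests).
Benjamini–Hochberg step-up adjustment (delegated to statsmodels, validated
against a literal step-up enumeration) gives q-values. Genes with
q ≤ `q_cutoff` (default 0.05) split by linear fold change
FC = 2^(mean_treated − mean_reference): FC > `fc_cutoff` (default 1.2) →
induced, FC < 1/`fc_cutoff` → repressed; "absolute fold change" for the
threshold means max(FC, 1/FC). Halves are ordered by ascending q, ties by
gene id, for determinism. ANOVA runs on log2 values while fold change is
reported on the linear scale via 2^Δ — the standard reconciliation of
log-scale summarisation with linear-scale fold-change reporting; a
linear-group-mean-ratio variant is selectable because summarisation
software differs on this point.

**2. Projection onto a cohort.** Probe-level cohort matrices are collapsed
to genes by keeping, per gene, the probe with the largest cross-sample
variance (n−1 denominator; exact ties go to the lexicographically smallest
probe id). Each gene row is then centered to standard deviations from the
median: (x − median(x)) / sd(x), computed **on the cohort being scored**,
never imported from the training data — the centering statistics describe
the population the sample is compared against. Zero-variance rows become
zeros and are flagged rather than fatal. Signature genes are translated onto
the cohort's symbols with precedence: explicit one-to-one ortholog map,
else case-normalised identity (mouse/human symbols differ only in case for
most orthologs, so upper-casing at load makes the identity route usable);
ambiguous ortholog rows are rejected at load. Scoring refuses to run when
fewer than `min_per_half` (default 3) genes of either half are found.

**3. The per-sample t-score.** For one sample, the centered values of the
induced genes form group 1 and those of the repressed genes group 2; the
score is the plain two-sample t statistic, positive when the induced mean is
higher. Default is the pooled-variance t with df = n₁+n₂−2; a Welch variant
with Welch–Satterthwaite df is selectable — the classical pooled form is the
default because the mean-difference-over-pooled-error form is the canonical
definition of this score, and the two differ negligibly on signatures of
comparable half sizes. A profile with zero variance in both halves scores 0
when the means agree and is rejected as pathological when they differ.
Samples are ranked by descending score (rank 1 = strongest manifestation),
ties broken by sample id. Scoring internally canonicalises the cohort's
column order, so per-sample scores are bit-identical under any input column
permutation.

**4. Association statistics.** The correlation screen computes, per gene,
Pearson r between the gene's (collapsed, uncentered) values and the sample
scores, with the two-sided p from the exact transform
t = r√((n−2)/(1−r²)) on n−2 df, and calls positive / negative / ns at raw
p < α (default 0.05) — matching the convention of signed-correlation
heat-map annotations — while BH-adjusted calls are reported alongside for
stricter use. `group_compare` reports the two-sided pooled t-test on the
supplied scale and the fold change as the ratio of linear-scale group means
(log2 inputs are exponentiated first; a 2^Δ-of-log-means option exists);
its t is signed treated-minus-reference so the sign always agrees with the
fold-change direction. Over-representation uses the one-sided upper-tail
hypergeometric: drawing |hits| from |universe| with |pathway ∩ universe|
marked, p = P(overlap ≥ observed). The universe is a required explicit
input — enrichment against "all genes ever annotated" and against "genes on
the array" answer different questions, and the choice belongs to the caller.

## Synthetic data: what it emulates and what it does not

`simulate_two_group` emulates the training side: per gene a baseline drawn
uniformly from log2 4–12 (the occupied range of a log2 microarray after
normalisation), a ±`effect_log2` shift on the planted induced/repressed
genes in treated samples, and i.i.d. homoscedastic Gaussian noise. Defaults
mirror a minimal overexpression experiment: 3 samples per group,
`effect_log2 = 2`, `noise_sd = 0.25` (a typical residual SD for replicate
ventricle pools on arrays). `simulate_activity_cohort` emulates the scoring
side: each sample carries a latent activity a_s ~ N(0, activity_sd²) that
moves every induced gene by +a_s and every repressed gene by −a_s against
gene-level noise, and a seed-chosen fraction of signature genes is removed
to emulate platform gaps. Signature direction is encoded as ±1 with a shared
magnitude; per-gene loadings are deliberately out of scope — the score being
tested is itself unweighted, so a loading model would test a different
statistic.

Both draw all variates from one explicitly seeded generator (gene-major
order), so outputs are bit-reproducible from the seed. The simulators omit
microarray artifacts (probe saturation, background, batch effects),
gene–gene correlation beyond the planted signal, and heavy-tailed noise.
Passing the recovery and calibration tests therefore shows the pipeline is
correct and well-calibrated under its own model assumptions; it does not
certify performance on real arrays, where correlated noise inflates the
score variance and platform effects can bias probe collapsing.

## Numerical choices

* Degenerate ANOVA rows (zero within-group variance everywhere) get p = 0
  when group means differ and p = 1 when all values are identical — a
  documented convention that avoids NaN propagation; detection uses a
  relative tolerance of 1e−24 on squared sums against the row's magnitude.
* BH q-values preserve input order; q ≥ p pointwise and monotonicity in p
  are asserted properties.
* Centering uses the n−1 standard deviation; collapsing uses the n−1
  variance.
* Text output writes floats via Python's shortest round-tripping repr, so
  write→read cycles are exact and reruns are byte-identical.
* All rankings and orderings break ties lexicographically (gene id, probe
  id, sample id) — determinism over arbitrary hash order.

## Problem sizes used in tests and the acceptance script

Recovery and calibration checks run at the sizes the method is meant for and
that make the assertions statistically stable: signature derivation on 1000
genes (50 up, 50 down, 3 vs 3, effect 2.0, noise 0.25); activity recovery on
100 samples with a 50+50 signature against 2000 background genes
(activity_sd 1.0, noise_sd 0.5); null calibration over 20 seeded inactive
cohorts and a 1000-background-gene correlation screen; oracle fuzzing over
1000 random profiles. The whole suite completes in a few seconds.

## Intended real-data usage and known limitations

On real cohorts the inputs are the already-summarised (e.g. RMA + quantile)
expression matrices, a probe→symbol annotation table, and the cohort's
sample-selection rules — e.g. for a two-cohort DCM analysis, nonfailing vs
idiopathic-DCM ventricle selections of 6+13 and 16+86 samples respectively.
CEL-level summarisation, GEO SOFT parsing and pathway-database retrieval are
out of scope; the package ingests matrices and GMT files. The mouse→human
gene mapping is the user's responsibility (annotation table and optional
ortholog map are explicit inputs), because no single authoritative mapping
exists and silent defaults would be irreproducible. The score is unweighted:
a gene with a weak but consistent response counts as much as a strong one.
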