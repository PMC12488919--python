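# Methods

## Data model

The expression container is a probes × samples matrix of normalized,
background-subtracted relative expression on a nominal 0–20 scale, with a
sample design assigning each sample a sex (F/M) and a dose (control, d0.5,
d50). Values slightly outside [0, 20] raise a warning rather than an error:
the bound describes a normalization convention, not a mathematical constraint,
and clipping noise in synthetic data may cross it. Groups for comparison are
sets of (sex, dose) cells; pooled exposure groups (both doses of one sex) are
unions of cells. All tabular formats are plain TSV (UTF-8, decimal point, no
quoting) with `#` header comments carrying version, seed and checksums.

## Moderated t differential expression

Per probe, a pooled-variance two-sample comparison. Under the hierarchical
model

    s²_g | σ²_g ~ σ²_g · χ²_{d_g} / d_g,      1/σ²_g ~ χ²_{d₀} / (d₀ s₀²),

the marginal of s²_g is a scaled F. The hyperparameters are estimated by
moment matching on the log scale: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the prior satisfies
E[e] = log s₀² − ψ(d₀/2) + log(d₀/2)... inverted as
trigamma(d₀/2) = Var(e) − mean(trigamma(d_g/2)), solved by a monotone Newton
iteration on the trigamma function (tolerance 1e-8, ≤ 100 iterations,
asymptotic starting values at the extremes). When the observed log-variance
spread does not exceed its sampling expectation, d₀ is declared infinite and
s₀² is the arithmetic mean of the sample variances; every probe then shares
one variance. Zero sample variances are offset by the smallest positive
variance × 1e-6 before taking logs. The moderated statistic is
t_g = (mean_a − mean_b)/√(s̃²_g (1/n_a + 1/n_b)) on d₀ + d_g df (normal when
d₀ is infinite); d₀ = 0 reduces exactly to the Student t, which is also
selectable directly. A matrix with a single probe falls back to d₀ = 0, since
a one-probe ensemble gives the prior nothing to borrow from. The
implementation is cross-checked in the test suite against Bioconductor limma
(lmFit/eBayes) on a simulated fixture, agreeing to ~1e-8 in t and p.

DEG filtering keeps probes with p strictly below α (default 0.05, no
multiple-testing adjustment; Benjamini–Hochberg is available as an option) and
a group-mean relative expression of at least 1.5 in one group, ordered by
ascending p with probe-id tie-breaks. Up/down percentages in summaries are
integers rounded half-up.

## Fold change and the cutoff bias

FC is defined as the ratio of the larger to the smaller group-mean relative
expression, directly on the normalized scale. Only this definition produces
the diagnostic's bias mechanism: an absolute shift of fixed size yields a
smaller ratio at a high expression level, so an FC cutoff preferentially
removes high-expression DEGs. A log2-difference FC (2^|Δ|) is available behind
a switch. Probes whose smaller group mean is ≤ 0 have undefined FC and are
excluded with a count. The diagnostic reports the retained-set size and the
ratio of mean retained expression after/before the cutoff, plus the
(FC, expression) pairs for plotting.

## Shift classification

The sex-biased universe is the control-F vs control-M DEG list (same α and
expression filter as all other comparisons). Exposure DEGs (exposed group vs
same-sex controls; both doses pooled by default) are intersected with that
universe by identical probe id — distinct probes covering one gene sit at
systematically different levels, so cross-probe matching is not meaningful
for level comparisons. For each overlapping probe with exposed-group mean m,
same-sex control mean c_s and opposite-sex control mean c_o:

- towards = opposite iff (m − c_s) and (c_o − c_s) have the same strict sign;
- proximity = closer_to_opposite iff |m − c_o| < |m − c_s|;
- exact ties (zero shift, equidistance) are recorded as tie/equidistant and
  excluded from towards-opposite numerators rather than silently assigned.

Group means, not per-animal values, are classified. The summary reports the
nesting chain n_closer ≤ n_towards ≤ n_classified ≤ n_overlap ≤ n_exposure
(asserted on construction); towards_percent is relative to the classified
overlap and closer_percent relative to the towards-opposite count.

### A selection caveat

When the exposure comparison and the sex-bias comparison reuse the same
control samples, probes that are false positives in *both* comparisons are
almost always classified "towards opposite": the shared control-sample noise
makes the apparent exposure shift the mirror image of the apparent sex gap
(a winner's-curse coupling). In null simulations (no exposure effect) we
observe ~99.8% towards-opposite among such doubly-false-positive probes,
versus ~50% — the correct symmetric behavior — among false-positive exposure
calls on probes with a genuine sex gap. Interpretation of very high
towards-opposite percentages should therefore lean on probes whose sex bias
is well established; the test suite verifies both regimes.

## Metabolite statistics

Two-way ANOVA uses Type II sums of squares (each main effect adjusted for the
other, ignoring the interaction), computed by QR-based residual sums of
squares of the four nested design matrices; Type II is the standard default
for main-effect interpretation on the near-balanced 2×2 cells analyzed here
(each dose separately against controls), and equals Type I on balanced
designs (asserted to 1e-8). A vectorized path evaluates thousands of analytes
sharing one design in a single call. Within-cell degeneracy is judged
relative to the response scale (RSS ≤ 1e-12 × Σy²). Missing values are
dropped listwise per analyte. Post-hoc comparisons of the four cell means use
the studentized-range (Tukey) distribution with the Tukey–Kramer allowance
for unequal n, via statsmodels, and are cross-checked against the
studentized-range distribution directly. Note that the Tukey-adjusted p
dominates the *pooled-MSE* pairwise t, not a two-sample t with its own
variance estimate. Summary-statistic t-tests are pooled (Student) by default,
Welch optional, and reproduce raw-data t-tests exactly when summaries are
exact.

## Concordance scoring

A signed-change table pairs each analyte's rat direction (increased/reduced)
with its human direction (increased/reduced/ns/missing). Missing rows are not
comparable; aligned means identical directions. Under the default `strict`
policy an `ns` row is comparable but never aligned. The `count_aligned`
policy counts an `ns` row as aligned only when it carries an explicit per-row
override flag — the packaged male table flags one lipoprotein row whose
relative (between-sex) change matched despite non-significance, reproducing
the published judgement call without making it a silent default. Percentages
are rounded half-up (5/6 → 83%). Uncertainty comes from a seeded row-resampling
bootstrap (percentile interval; resamples with no comparable rows are
dropped).

## Synthetic data generator

The expression simulator emulates the study design it tests: 10,000 probes
(study scale ~36,685) × three dose groups of 5 females and 3 males; per-probe
baselines uniform on [2, 12] (spanning the low/high-expression regimes the FC
diagnostic needs); a fraction 0.07 of probes sex-biased (the control-sex DEG
fraction at study scale) with a fixed expression gap (default 1.2 = 4× the
noise SD) whose female-higher probability is 0.83 (the observed up-fraction
of the control comparison); a fraction of sex-biased probes shifted in all
exposed groups a chosen fraction of the way to the opposite-sex control mean
(default: complete shift). Noise is Gaussian (SD 0.3, matching printed
per-group SDs of 0.1–0.6) on the normalized scale — the input matrix is
post-normalization, so no count model is appropriate. Values are clipped to
[0, 20] (<1% of values under defaults, asserted). The predominance of
down-shifts in exposed females is emergent from the female-higher bias, not
planted. One seeded generator drives all draws in documented order, so a
whole run replays bit-identically from its seed.

What the simulator does **not** emulate: probe-level hybridization artifacts,
batch or litter effects, correlated probes within genes, heavy-tailed or
heteroscedastic noise, and exposure effects on non-sex-biased probes.
Passing recovery tests therefore demonstrates correctness of the analysis
logic under the stated model, not robustness to real-array pathologies.

The metabolite panel simulator draws Gaussian cell values around planted
(sex, dose) cell means with a common SD, 12 controls and 8 exposed per sex by
default, mirroring the blood panels.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use 10,000 probes at n=5/3
(the study's group sizes), 20 seeds for pooled null-symmetry checks, and
2,000 analytes for ANOVA null calibration; smaller unit fixtures use 300–6,000
probes. Binomial checks use 99% CIs. Percentages print as integers rounded
half-up. Ties at p = α are excluded (strict inequality). Trigamma inversion
is bracketed Newton with tolerance 1e-8. The classifier treats exact floating
ties explicitly; on continuous data they occur with probability zero but are
exercised by the tests.

## Limitations

- The moderated test assumes independent probes; correlated probes inflate
  the effective false-positive count though not its expectation.
- The same-probe-id restriction discards exposure DEGs whose sex-bias
  evidence comes from a different probe of the same gene; a gene-symbol mode
  is intentionally out of scope here because probe levels are not comparable.
- Exact replication of published ANOVA p-values from raw panels is not
  promised: the sums-of-squares type of the original analysis is not
  recoverable from its description, though types differ little on
  near-balanced cells.
- Concordance scoring is direction-only; magnitudes are not weighted.
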