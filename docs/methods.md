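# Methods

## The measurement model

Each case carries relative expression of two antiphase circadian clock
genes measured in heart tissue at autopsy. The package's two statistics
are the ratios N/B = E_NR1D1 / E_BMAL1 and its reciprocal B/N. Working
with the ratio has two consequences that the code exploits and the tests
assert:

- any multiplicative factor common to both transcripts cancels —
  reference-gene normalization, uniform RNA degradation with postmortem
  interval, input-amount variation;
- if each gene is log-normal around a cosinor mean, the log-ratio is
  Gaussian with the *sum* of the two log-amplitudes, which is what makes
  the ratio a sharper clock hand than either gene.

When raw qPCR Ct values are the entry point, the ratio is computed as
`(1 + efficiency)^(ct_bmal1 - ct_nr1d1)` under a shared amplification
efficiency for both assays (default 1.0, i.e. perfect doubling). The
shared-efficiency assumption is surfaced as a parameter rather than
hidden; no standard-curve fitting is attempted. Ct values above a ceiling
(default 40 cycles) are non-detects; such cases are excluded from all
downstream statistics and counted, never imputed.

## The synthetic cohort generator

The original per-case data are available only on request, so analyses are
exercised on synthetic cohorts. Each gene follows a multiplicative
(log-scale) cosinor

    E(t) = exp(mesor + amplitude * cos(2*pi*(t - acrophase)/24) + sigma*z)

with z standard normal per case and gene. Log-scale noise guarantees
positive expression and produces the heavy-tailed ratio dispersion seen in
real case series; ratios of log-normals stay log-normal, which keeps every
downstream statistic analytically checkable.

Defaults (all configurable through `CohortConfig`):

| parameter | default | why |
|---|---|---|
| acrophases | NR1D1 06:00, BMAL1 18:00 | antiphase pair; puts the N/B peak at 06:00 and B/N at 18:00 |
| amplitude (both genes) | 2.0 | noiseless peak N/B = exp(4) ≈ 54.6, comfortably above the highest decision threshold (40); a calibration choice, not a fit |
| noise sd (log scale) | 0.5 per gene | visible case-to-case scatter (log-ratio sd ≈ 0.71) without drowning the rhythm |
| arrhythmic fraction | 0.15 | fraction of cases whose *personal* acrophase is uniform on [0, 24): shift workers and irregular lifestyles, the accepted explanation for low ratios at peak times; the offset is shared by both genes, preserving the 12-h antiphase relation |
| chronic-brain-injury attenuation | 0.0 | chronic brain injury (cerebral edema/hernia/hypoxia) abolishes the peripheral oscillation, so both amplitudes are multiplied by 0 for those cases |
| time of death | uniform on [0, 24) | the reference series reports no time-of-death distribution |
| sex | P(male) = 224/318 | reference cohort composition |
| causes of death | 10 categories at the reference-series proportions (245 extrinsic / 73 intrinsic over 318) | drives the intrinsic/extrinsic and brain-injury subgroup analyses; head-injury deaths split 35 acute : 15 chronic |
| age | mixture: ≤19 y (13/318, uniform 2 mo–19 y), 20–69 y (200/318, triangular(20, 57.61775, 69)), ≥70 y (105/318, uniform 70–97) | stratum weights match the reference age groups; the triangular mode is solved so the mixture mean is exactly 58.7 y |
| PMI | lognormal(μ=2.95058, σ=0.57283) truncated at 96 h | parameters solved so the truncated mean is exactly 22.3 h and P(PMI > 30 h) = 68/318, the reference group split |
| PMI degradation | off (rate 0) | when enabled, a common exp(-rate·PMI) decay on both genes — deliberately common so it cancels in the ratio, matching the observed PMI-independence of the method |

Randomness uses a single seed split into named `SeedSequence` child
streams, one per random component (time of death, sex, age stratum, age
value, PMI, cause, brain-injury course, arrhythmic flag, phase offset, two
noise vectors). The draw order within each stream is documented by the
column it fills, generation is fully vectorized, and identical
configurations produce byte-identical CSV output.

What the generator does **not** emulate: within-day structure of real
death times (diurnal peaks of cardiovascular death), correlation between
covariates (age × cause of death), gene-specific degradation, assay
failure, or any age/sex effect on the rhythm itself (the reference
analysis found none). Tests passing on synthetic cohorts therefore
validate the *machinery* — statistics, classifier, pipeline — and the
qualitative peak structure, not the real-world yield of the thresholds.

## Statistics

Per-domain summaries are mean ± SEM with the n−1 sample standard
deviation. The four time domains partition the clock as half-open
intervals: morning [3, 9), noon [9, 15), evening [15, 21), night
[21, 24) ∪ [0, 3); the "3:00–8:59"-style labels of the field are read as
half-open so every time maps to exactly one domain.

Multiple comparisons across domains use Scheffé's post-hoc procedure: with
k groups of total size N, MSW the pooled within-group variance on N−k
degrees of freedom,

    F_s = (mean_i − mean_j)² / (MSW (1/n_i + 1/n_j)),
    p   = P{F(k−1, N−k) > F_s/(k−1)}.

For k = 2 this reduces exactly to the one-way ANOVA omnibus test (used as
a numerical cross-check). Two-group contrasts use the pooled-variance
two-sided Student t-test. Significance is flagged at 0.05 and 0.01. No
multiplicity correction is applied *across* subgroup families — each
factor's family is Scheffé-controlled internally, mirroring how such case
series are conventionally analyzed; this is stated rather than hidden.

Degenerate inputs: zero within-group variance yields p = 1 for equal
means and p = 0 with a `RuntimeWarning` otherwise; domains with fewer
than two cases are dropped from comparisons with a logged warning, never
silently.

Subgroup levels: sex (male/female), age (≤19, 20–69, ≥70 y), PMI (<30 h
vs >30 h — PMI exactly 30 h goes to the high group; a measure-zero event
under the continuous generator), cause class (intrinsic/extrinsic), and
brain-injury course (acute vs chronic, restricted to head-injury deaths,
with additional per-domain acute-vs-chronic t-tests).

## The classifier

Thresholds are strict (">") and windows are closed clock intervals, per
the method's published phrasing. The highest-tier applicable rule wins;
the rule loader rejects sets where the high-tier window is not nested in
the low-tier window or where a single case could trigger both a morning
and an evening rule (possible iff the product of the smallest N/B and B/N
thresholds is ≤ 1; for the defaults 25 × 1.5 ≫ 1). A case below every
threshold receives tier `none`, which the evaluation reports as "no
statement" — it is never converted into an exclusion claim.

`tightest_window` reconstructs how such thresholds map to windows: the
minimal circular arc of the 24-h clock covering the death times of all
above-threshold cases is the complement of the largest gap between the
circularly sorted times. It handles wrap-around (the default windows
happen not to wrap) and degenerates to a zero-length arc for a single
case. Raising a threshold can only shrink the above-threshold set and
hence never lengthens the arc.

On synthetic cohorts the evaluation reports yield (predicted fraction)
and coverage (fraction of predicted cases whose true death time falls in
the window), overall and per tier. With the strongly rhythmic default
generator the yield (~65% at n = 318) is far above real-casework yield
(~25%), and coverage sits well below 100% because arrhythmic cases can
present a high ratio at any hour — both are properties of the simulated
conditions, reported honestly rather than calibrated away.

## Problem sizes and numerical choices

The test suite uses a 10,000-case cohort for qualitative peak structure
and composition checks, 2,000 replicate flat-oscillator (amplitude 0)
cohorts of 80 cases for the type-I-error property (drawn as slices of one
large cohort — cases are iid, so this is equivalent and fast), 100,000
random cases for ratio reciprocity, and 50,000 cases for calibration
means; the whole suite runs in a few seconds. Reciprocity is asserted to
1e-12 relative tolerance; Monte-Carlo checks use 3-standard-error bands.
Clock times in outputs are decimal hours rounded to 2 decimals to avoid
HH:MM ambiguity.

## Known limitations

- The dispersion parameters (noise sd, arrhythmic fraction) are
  calibration choices; no public per-case data exist to estimate them.
- No cosinor *fitting* is provided — the method never fits a rhythm model
  to data, it only reads ratios through thresholds.
- The classifier is deliberately discrete; no probabilistic or continuous
  phase-inversion estimate is attempted.
- Infants, the very old and long-PMI cases are rare in the reference
  composition and correspondingly rare in synthetic cohorts; subgroup
  results for them are noisy by construction.
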