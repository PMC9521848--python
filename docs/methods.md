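# Methods

## The estimator

Cross approximate entropy (C-ApEn) measures the asynchrony of two
simultaneously recorded signals `u`, `v`. Both are standardized to
zero mean and unit SD. With embedding dimension `m`, delay `lag` and
tolerance `r` (in SD units), the delay-embedded templates of `u` are
matched against those of `v` under the Chebyshev norm:

    C_i^m(r)  = #{ j : max_k |u_{i+k·lag} − v_{j+k·lag}| ≤ r } / n_m
    Φ^m(r)    = (1/n_m) Σ_i ln C_i^m(r),       n_m = N − (m−1)·lag
    C-ApEn    = Φ^m(r) − Φ^{m+1}(r)

i.e. the expected drop in log conditional match probability when the
template grows by one sample. Higher values mean the two series
predict each other less well (more asynchrony); with `u = v` the
definition reduces to ordinary ApEn, self-match included.

Design choices:

* **Direction symmetrization.** Cross-ApEn is asymmetric in its
  arguments. Electrode pairs are unordered, so we report
  `½·CApEn(u→v) + ½·CApEn(v→u)`. The two directions share one match
  matrix (one is the transpose of the other), so this costs nothing.
* **Zero-match floor.** Unlike ApEn, a cross template may match
  nothing and `ln 0` diverges. We substitute the minimal observable
  probability `1/n_targets` and flag the epoch (`floor_triggered`).
  Discarding unmatched templates instead would bias `Φ` asymmetrically
  between the `m` and `m+1` levels.
* **Constant epochs** return 0 (perfect predictability) with a
  degeneracy flag rather than erroring mid-pipeline.
* **Parameters.** `m = 2`, `lag = 1`, `r = 0.2` SD, 2 s epochs
  (1000 samples at 500 Hz) — the standard ApEn-family settings for
  EEG. All are configuration-exposed.

The optimized kernel counts matches exactly (binary-search candidate
windows on a sorted target series, numba-compiled when available) and
is verified against a pure-Python brute-force enumeration to 1e-10 in
the test suite; a numpy fallback path exists when numba is absent.

### Tolerance, epoch length, and the floor regime

The expected number of `(m+1)`-level matches scales like
`N · p(r)^{m+1}` with `p(r)` the single-coordinate match probability.
When that product falls below ~1 the floor term dominates `Φ^{m+1}`
and the estimator loses — and can even invert — its response to
genuine coupling. At `r = 0.2` this requires roughly `N ≥ 750`;
epochs of 1000 samples are safe. The reduced validation scale uses
250-sample epochs and therefore widens the tolerance to `r = 0.3`,
restoring an adequate match count. This coupling of `r` to epoch
length is a validity condition, not a tuning knob; `floor_triggered`
counts are carried through the pipeline so a user can see when an
analysis has entered the floor regime.

A related, measured limitation: at `r = 0.2` the estimator is nearly
insensitive to *weak* common-source coupling (shared variance below
~30%) even at `N = 1000`; its dynamic range concentrates where the
two signals share most of their variance, which is the regime of
neighbouring EEG electrodes. The coupling-monotonicity validation
therefore runs at `r = 0.5`, where sensitivity extends to weak
coupling, and treats the `r = 0.2` insensitivity as documented
behaviour rather than an error.

## Montage and analysis pipeline

Ten 10–20 electrodes cover five bilateral nodes of the speech
articulation network (DLPFC F3/F4, IFG F7/F8 — shifted onto the IFG,
M1 C3/C4, SPT T5/T6, IPL P3/P4). Twenty-one unordered pairs are
analyzed: 8 left-intrahemispheric, their 8 right mirrors, 5
homologous interhemispheric pairs. Recordings with extra channels
(e.g. 16-channel montages) load unchanged; unanalyzed channels are
dropped.

Preprocessing: 50 Hz mains notch (Q = 10; applied before the
band-pass so the notch's zero-phase edge transients stay out of the
passband), then 1–45 Hz 4th-order Butterworth, both zero-phase. The
recording bandwidth of the source hardware is 0.3–100 Hz; the
1–45 Hz analysis band and the 50 Hz mains frequency are this
package's choices (config-exposed).

Epoching: non-overlapping 2 s epochs; an epoch is dropped for all
channels when any channel's peak |amplitude| exceeds `reject_sd` (5)
whole-recording SDs — a deliberately simple stand-in for the
unpublished artifact-rejection procedure of the original lab. Per
pair, C-ApEn is averaged over retained epochs, separately per
condition (eyes-closed rest; eyes-closed syllable repetition) and
timepoint (baseline; post-treatment). Standardization is per epoch,
so the tolerance tracks local variance and slow drifts do not inflate
matches.

Derived quantities per pair and subject:

* **difference value** = C-ApEn(task) − C-ApEn(rest); positive when
  the task recording is the more asynchronous one;
* **change score** = difference value(post) − difference value(baseline).

A condition with fewer than `min_epochs` (10; 8 at the reduced scale)
retained epochs yields a missing cell which propagates as NaN — never
silently 0.

## Trial statistics

Matching the source trial's analysis plan: Shapiro–Wilk at α = 0.05
routes each comparison to the independent/paired t-test or to the
Mann–Whitney U / Wilcoxon signed-rank test (normality judged per
variable; on the differences for paired designs); all p-values
two-tailed; Pearson chi-square without continuity correction for
categorical baseline variables; univariate OLS screening at p < 0.2
followed by multivariate OLS always containing the treatment-arm
term; no correction across the 21 pairs (a Benjamini–Hochberg flag
exists, off by default).

The standardized mean difference pools SDs as the root-mean of the
two variances, `d = |m₁ − m₂| / √((s₁² + s₂²)/2)` — the only pooling
convention that reproduces the trial's printed effect sizes, verified
against 16 printed cells across its four report tables to ±0.001.

Paired-design power uses the noncentral t distribution
(df = n − 1, noncentrality dz·√n). The trial's printed planning value
(dz = 1.0, n = 11, α = 0.05 → 0.924) is the **one-sided** power;
the two-sided value is 0.847. Both alternatives are supported; the
worked example reports the one-sided figure to match the publication.

Known non-reproducibilities, excluded from validation: the baseline
table's continuous p-values (age 0.266, lesion size 0.378, onset
0.198) cannot be recovered from the printed summaries under either
routing branch, and the basal-ganglia row prints p = 0.572 where the
printed counts give 0.673.

## Synthetic data generator

No raw data accompany the source trial, so a seeded generator
produces the full study layout: 2 arms × 12 subjects × 2 timepoints
× 2 conditions, clinical covariates and five speech subtest scores,
and 10-channel recordings with controlled pairwise coupling.

**Recordings.** The requested pairwise couplings define a target
channel correlation matrix `R` (background 0.6 between all channel
pairs by default). `R` is split as `R = C + d·I` with
`d = λ_min(R)` — the largest white diagonal consistent with the
requested correlations — and `C` is realized through smooth AR(2)
latent sources (spectral peak ~6 Hz, pole radius 0.95) via its
eigendecomposition, `d` through white noise, plus a 2% white
sensor-noise floor; everything is band-limited to 1–45 Hz. This
*minimum-trace split* matters: C-ApEn discriminates a shared smooth
waveform against template-scale-independent (white) channel-private
activity, while smooth channel-private activity masks coupling.
Requests with a non-positive-semidefinite `R` raise an error naming
the most implicated channels. Because the band-pass removes
proportionally more white than smooth variance, realized broadband
correlations sit somewhat above the requested values; all effect
calibration is empirical, so this bias is absorbed.

**Treatment effects.** Within a subject the white/smooth split is
held constant across the four sessions, and an arm's programmed
pairs receive a *dedicated additive smooth source* (variance
`post_rest_delta`) shared by the pair's two channels in the
post-treatment rest recordings only; channels are renormalized to
unit variance. The shared rhythm lowers rest-phase asynchrony, so
the task-minus-rest difference value rises — the pattern the trial
reports. The default topology follows its findings: active arm
F3-F7, F7-C3, P3-F7, T5-P3, T5-F7; control arm F8-C4, T6-F8, F3-F4,
F7-F8. The ground-truth table records both the effective channel
correlation and the added shared variance per cell.

**Calibration.** No closed form links the added variance to a C-ApEn
effect size, so `calibrate_effect` measures it: pilot batches from
both arms at a probe delta give the per-pair between-arm change-score
effect sizes (including the leakage of the control arm's own effect
into the left-hemisphere pairs), and the delta is set by linear
scaling with one refinement stage. The default target is a
between-arm effect size of 1.0 on the programmed pairs. Pilot size
500 per arm and stage gives roughly ±4% calibration accuracy.

**Clinical scores.** Covariates are truncated normals / categorical
frequencies with the trial's printed arm-specific parameters (ages
truncated to the 18–80 inclusion range, etc.); the five subtest
scores are truncated bivariate normals with the printed
baseline/post means and SDs and a within-subject correlation
ρ = 0.5 (unstated in the source; config-exposed). Because
truncation shifts means, generator checks compare against the
truncated-normal expectation, not the raw printed mean.

**What the generator does not emulate:** volume-conduction geometry,
1/f spectra, eye-blink/EMG artifacts beyond optional amplitude
spikes, non-stationarity within sessions, or any relation between
clinical scores and EEG coupling. Passing pipeline tests on this
generator demonstrates statistical correctness of the machinery, not
physiological realism.

## Validation scales and problem sizes

Two named scales (`capen.presets`):

* **study**: 500 Hz, 300 s rest / 60 s task, 1000-sample epochs,
  r = 0.2 — the source trial's geometry, the package default.
* **reduced**: 125 Hz, 20 s per condition (ten 2 s epochs of 250
  samples), r = 0.3, `min_epochs` 8 — the package's Monte-Carlo
  validation scale.

The standing experiments (`capen.validation`, also run by
`scripts/acceptance.py`) use the reduced scale: effect recovery with
200 simulated trials at 12 subjects/arm against the 95% binomial band
around the theoretical two-sample t power at d = 1.0 (≈0.65); null
calibration over ≥1000 pair comparisons with the type-I band
[0.03, 0.07]; screening-rule retention over 1000 pure-noise
replicates; brute-force oracle agreement over 50 random signal pairs;
and common-source monotonicity over 100 seeded replicates with common
random numbers across the coupling grid.

## Numerical notes and edge cases

* Exact equality (not tolerance) is asserted between the jitted
  kernel, the numpy fallback and single- vs batched-epoch paths; the
  brute-force comparison uses 1e-10.
* Scale invariance of C-ApEn holds to 1e-10 (standardization makes
  `r` relative); symmetry in the two inputs is exact by construction.
* Flat (zero-variance) channels cannot trip the amplitude-rejection
  rule (their SD is treated as infinite) and reach the estimator as
  degenerate epochs, returning 0 with a flag.
* Constant regression candidates are never retained by the screen
  (p ≡ 1); an empty retained set yields an intercept-only model; a
  collinear retained set raises, naming the columns.
* All randomness flows from `numpy.random.SeedSequence`; a dataset,
  a calibration and every validation experiment are bit-reproducible
  for a fixed seed.
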