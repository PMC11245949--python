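# Methods

This note records the models, the synthetic-data design, and the numerical
choices behind `nirferm`, in the spirit of a package's statistical
documentation: what is computed, under which assumptions, and where the
design was genuinely open.

## Spectral model and preprocessing

Spectra are flat tables over a strictly increasing wavelength axis
(default 1100–2100 nm at 2 nm, 501 points). Reflectance R ∈ (0, 1] is
converted to absorbance A = log₁₀(1/R); absorbance is the modeled
quantity. Savitzky–Golay smoothing fits a local least-squares polynomial
in a (2m+1)-point window; edges are mirror-padded so the output keeps the
full axis and wavelength indices stay stable across the pipeline.

Two readings exist of a "second-order, three-step" smoothing convention:
polynomial order 2 with a 3-point window, or order 2 with half-window
m = 3 (7 points). The first is mathematically the identity map — a
quadratic interpolates three points exactly — so as literally configured
it has no effect. Both are runnable (`SGFilterSpec(poly_order, half_window)`);
the default is the 3-point reading, and any analysis wanting actual
smoothing should set `half_window=3`. No other corrections (SNV, MSC,
derivatives) are implemented: they are out of scope.

## PLSR

Single-response PLS1 via NIPALS. For centered X, y, each component takes
w ∝ Xᵀy (unit norm), scores t = Xw, loadings p = Xᵀt/tᵀt, inner
coefficient q = yᵀt/tᵀt, then deflates both blocks. Because the weight
step for a single response is closed-form, the decomposition is
deterministic and bit-reproducible — no random initialisation exists. The
response sum of squares explained per component is SSₐ = qₐ²·tₐᵀtₐ.
Coefficients β = W(PᵀW)⁻¹q are mapped back to the original predictor
scale, so ŷ = Xβ + b₀ without external centering.

Choices:

- **Scaling** — mean-centering only by default. Absorbance spectra share
  units; autoscaling would inflate noise-only bands. Unit-variance scaling
  is available (`scale=True`).
- **Component count A** — nothing forces one value. The pipeline default
  is a fixed A = 8 for speed and comparability; `plsr_recipe(None)`
  instead picks A per training fold by inner 5-fold cross-validation over
  1..15, so held-out data never inform the choice. At full rank A the
  solution provably coincides with ordinary least squares (tested).
- **Rank exhaustion** — when the residual X block has no covariance left
  with y (e.g. noise-free synthetic data, whose spectra have rank 2 with
  respect to the chemistry), `fit_plsr` raises by default;
  cross-validation recipes pass `allow_truncation=True` and keep the
  components found, mirroring common chemometrics practice.

VIP scores are vⱼ = √(p Σₐ SSₐ(wₐⱼ/‖wₐ‖)² / Σₐ SSₐ); Σⱼvⱼ² = p is an
algebraic identity and is enforced to 1e-8 in tests.

## Covering arrays and CAFS

A covering array CA(N; t, k, v) over symbols {0..v−1} has every vᵗ tuple
present in every set of t columns. The builder is one-row-at-a-time
greedy: each row is the best, by newly covered tuples, of (i) a
deterministic candidate taking per column the symbol occurring in most
uncovered tuples, (ii) a seeded pool of 30 random candidates, and (iii) a
fallback forcing the first uncovered tuple, which guarantees progress.
Tuple bookkeeping is explicit, so strengths are limited to t ≤ 3 —
all the selector needs — and verification is exhaustive, returning a
concrete (columns, tuple) witness on failure.

CAFS (covering-array feature selection) screens wavelength *bands* rather
than single wavelengths, reflecting that NIR absorption features span
adjacent wavelengths:

1. partition the p wavelengths into k contiguous near-equal bands
   (default k = 50);
2. build CA(N; t, k, 2) (default strength t = 2; N ≈ 14–16 rows at
   k = 50), symbol 1 = "band included";
3. per row, cross-validate a PLSR on the included wavelengths (K = 5,
   fixed A); an all-exclude row is skipped and logged;
4. score each band as mean RMSE of excluding rows minus mean RMSE of
   including rows — a main-effects screening estimate, positive = useful;
5. retain positive-score bands, refit PLSR on them, rank their
   wavelengths by |β| and keep the top n_final (default 30).

The per-band contrast in step 4 averages over few rows, so at small k
individual noise bands can alias with signal bands; at the default k = 50
this dilution is negligible and planted bands dominate. Everything is
deterministic given (data, parameters, seed). β-coefficient selection
uses a fixed count (default 15) with ties broken to the lower wavelength
index; VIP selection uses the strict vⱼ > 1 rule and treats an empty
selection as a distinct error rather than silently keeping everything.

## Validation protocol and metrics

Models are assessed by repeated K-fold cross-validation: K = 5, 30
repetitions, reshuffling with seed = base_seed + rep (kept below 2³¹).
Every sample is held out exactly once per repetition; any data-driven
choice (selection, component count) must live inside the recipe so it is
refit per training fold. Aggregation is the mean over all rep × fold
cells (mean-of-folds, not pooled predictions — the other convention is
defensible but one had to be fixed).

Per fold: RMSE = √(Σ(ŷᵢ−yᵢ)²/n); R² = 1 − Σ(ŷᵢ−yᵢ)²/Σ(yᵢ−ȳ)²;
RPD = SD/RMSE with SD the population standard deviation of the *full*
response vector of the evaluated dataset, so RPD·RMSE = SD holds exactly
per fold. An alternative R² normalisation using Σ(ŷᵢ−ȳ)² in the
denominator is selectable for audit only — it is not bounded by 1 and is
inconsistent with RPD. A perfect fold (RMSE = 0) reports R² = 1 and an
infinite, flagged RPD. In the leave-one-out limit (K = n) the single-
sample fold has no defined R²; it is recorded as NaN with RMSE equal to
the absolute residual.

The Kolmogorov–Smirnov statistic uses the order-statistic form
D⁺ = maxᵢ(i/n − Zᵢ), D⁻ = maxᵢ(Zᵢ − (i−1)/n), D = max(D⁺, D⁻) with
Zᵢ = F(X₍ᵢ₎). F is the normal CDF at the maximum-likelihood fit (sample
mean, population SD) by default; fixed parameters can be supplied, which
the exact-quantile test cases use. D is affine-invariant under the fitted
default. p-values are deliberately not computed: with fitted parameters
they would need the Lilliefors correction, which is out of scope.

## Synthetic fermentation data

The generator emulates a monitoring study over three coffee varieties
(Typica, Caturra, Catimor), seven fermentation times (0–24 h in 4 h
steps), two sub-samples per time and 50 spectrometer profiles per
sub-sample — 2100 profiles in total.

**Chemistry.** Each variety follows a normalised exponential decay pinned
exactly at both endpoints,
y(t) = end + (start−end)·(e^{−rt} − e^{−rT})/(1 − e^{−rT}), T = 24 h,
which becomes a step to the end value as r → ∞. Defaults: pH
5.60→4.77, 5.43→4.60, 5.57→4.67 (r = 0.25/h, near-plateau after
16–20 h); TSS starts 15.87, 15.13, 16.53 °Brix. The 24 h TSS endpoints
(9.40, 8.80, 10.00 °Brix; r = 0.15/h) represent roughly 40 % sugar
depletion — a design value, since only starting Brix is anchored.
Sub-sample jitter (SD 0.02 pH, 0.15 °Brix) models within-batch
heterogeneity; the *reported* reference values additionally carry
analytical error (SD 0.05 pH, 0.40 °Brix), which bounds attainable
prediction accuracy because it never enters the spectra.

**Spectra.** Absorbance = linear baseline (0.35–0.45 AU) + Gaussian bands
at 1205, 1729 (C–H; amplitude coupled to TSS), 1451, 1927 (O–H water;
coupled to pH) and 1839 nm (inert), + per-profile baseline offset (SD
0.002 AU) + iid noise per point (SD 0.008 AU); reflectance = 10^(−A).
Band amplitudes are affine in the latent chemistry, e.g. 0.45 −
0.10·(pH − 5). The *planted informative wavelengths* for a response are
those within one Gaussian width of a coupled band's center (20 indices
per response under defaults), a strict subset of the bands' support.

**Calibration.** The noise scales were set so the full-spectrum PLSR
reaches R²_cv ≈ 0.95 on the default dataset — the regime the method
comparison is meaningful in. At much lower spectral noise the planted-
truth question degrades: β legitimately recruits off-band reference
wavelengths to cancel baseline drift, and essentially every wavelength
carries usable signal.

**What passing tests do and do not show.** The generator produces
additive, exactly-Gaussian bands, linear amplitude–chemistry coupling,
and iid noise. Real fermentation spectra have overlapping asymmetric
bands, nonlinear water-activity effects (the known nonlinearity of TSS
prediction), scatter effects and instrument drift structure none of which
are modeled. Recovery and accuracy results on this benchmark validate the
implementation and the selectors' mechanics — not field performance on
real coffee.

## Problem sizes and determinism

Default analyses run on the 2100 × 501 benchmark; tests use a 126-profile
variant (3 profiles per sub-sample, one sub-sample) and a 15-profile
shrunken grid where only plumbing is exercised. Planted-recovery checks
use 20 replicate benchmarks with recorded seeds. Every stochastic stage —
generator, covering-array construction, fold shuffling — takes an
explicit seed, derived seeds stay below 2³¹, and reruns are
bit-identical; the pipeline writes its resolved configuration and all
seeds next to its outputs.

## Known limitations

- CAFS here is a main-effects screening reconstruction; interaction-aware
  scoring (exploiting strength t > 2 structure) is not implemented.
- Covering-array construction is greedy, not minimal; N is typically
  within a small factor of the best known sizes at these parameters.
- Single-response PLSR only; no PLS2, no nonlinear (kernel) variant.
- The KS statistic is descriptive; no p-values (see above).
- No instrument-format readers (JCAMP-DX etc.); CSV only, by design.
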