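# Methods

`algaftir` models protein, lipid and carbohydrate content (% of biomass
dry weight, % DW) of green microalgae from ATR–FTIR absorbance spectra.
This note records the models, their assumptions, the numerical choices,
and what the synthetic validation data can and cannot show.

## The measurement model

An ATR–FTIR spectrum of freeze-dried biomass is treated as a
non-negative superposition of pure-component absorbance profiles —
protein (amide I/II near 1655 and 1545 cm⁻¹), lipid (ester C=O near
1742 cm⁻¹ plus acyl C–H), carbohydrate (a crowded ring/C–O–C manifold
over ~960–1150 cm⁻¹) and a broadband remainder (bound water, residual
cell-wall modes) — distorted by three instrumental effects:

* **ATR penetration weighting.** The evanescent-wave penetration depth
  grows with wavelength, so bands at low wavenumbers are proportionally
  stronger than in transmission spectra. Modelled as an intensity
  multiplier `(1000 / wavenumber)^gamma`, default `gamma = 1`.
* **Baseline drift.** A smooth additive background dominated by a
  positive offset with mild tilt and curvature.
* **Additive detector noise.**

## Preprocessing

Applied in this order, chosen so that baseline estimation and
normalisation see the full recorded range before cropping:

1. **AsLS baseline correction** (`lam = 1e6`, `p = 0.001`, up to 50
   reweighting iterations, stop when the asymmetric weight vector is
   essentially unchanged). The baseline minimises a weighted
   least-squares fit with a second-difference smoothness penalty;
   points above the baseline get weight `p`, points below `1 − p`.
2. **Total-area normalisation** to unit trapezoidal area over the full
   axis (the constant is immaterial downstream; trapezoidal vs plain
   sum differs only by a constant factor on a uniform grid).
3. **Savitzky–Golay smoothing**, polynomial order 1, frame 5 — in the
   interior exactly a 5-point moving average.
4. **Crop** to the fingerprint region, 800–1800 cm⁻¹ (closed interval;
   251 points at 4 cm⁻¹, 501 at the 2 cm⁻¹ working grid).

Resampling to the 2 cm⁻¹ working grid uses linear interpolation. (The
instrument-native route is interferogram zero-filling; without
interferogram access linear interpolation is an adequate stand-in
because no downstream model uses sub-resolution detail.)

Two known AsLS behaviours matter in practice and are verified by the
test suite rather than assumed away:

* With `p = 0.001` the effective stiffness in signal-free regions is
  `lam / p = 1e9` (smoothing length ≈ 180 grid points), and the natural
  boundary conditions of the second-difference penalty cannot follow
  baseline curvature near the ends of the recorded range — edge errors
  of 10–30 % of the baseline amplitude are normal. Inside the
  fingerprint region a representative cubic drift is recovered to
  better than 2 % of its amplitude, which is the region all models
  consume.
* AsLS is not idempotent: a second pass slowly erodes bands wider than
  the smoothing length (the O–H stretch, for instance). The pipeline
  therefore applies it exactly once; re-running the full chain changes
  the fingerprint shape by ≈ 6 % (up to a per-sample scale factor).

## Band integration and the univariate models (ULRA)

Diagnostic windows: protein 1580–1700, lipid 1710–1765, carbohydrate
960–1130 cm⁻¹. Areas are trapezoidal integrals above zero (spectra are
already baseline-corrected); edges falling between grid points are
included by linear interpolation. A wider carbohydrate assignment range
(980–1200 cm⁻¹) exists in the literature; it is treated as descriptive
and the 960–1130 window is used for features.

Each compound is calibrated by ordinary least squares of composition
(% DW) on its band area — composition on intensity, not inverse
calibration, so predictions come directly from the fitted line and are
not clipped at zero. Validation is leave-one-out CV; every
data-dependent step is refit per fold.

The **carbohydrate/protein ratio model** regresses the composition
ratio `carb% / protein%` on the band-area ratio. Ratios cancel the
per-sample total-area factor, which is exactly the term that
normalisation errors and ATR weighting corrupt, so the ratio model is
more robust than the direct carbohydrate model. The chained
carbohydrate estimate is `predicted ratio × predicted protein`; its
LOO-CV refits *both* stages in every fold.

Statistics follow the conventions of the calibration-transfer
literature: RMSEC and RMSEP divide by `n`; RMSECV divides by `n − 1`
(a `denominator="n"` switch exists); Q² uses cross-validation
predictions against the mean of the full calibration response (fold
means would be the other defensible choice; this one is flagged here);
RPD is the sample SD (ddof = 1) of the response over RMSECV.

Outlier handling defaults to explicit lists (mirroring judgment-based
removal of samples whose wet chemistry failed); an iterative
externally-studentized-residual rule (threshold 3.0) exists to make the
workflow reproducible on synthetic data.

## Orthogonal PLS (O2-PLS-style)

A single model relates the centred fingerprint matrix X to the three
unit-variance-scaled responses Y. X keeps its natural variance
weighting (centring only); Y is centred and UV-scaled.

The fit separates three kinds of variation:

1. **Orthogonal in X** (`n_ox` components): the dominant principal
   directions of the X-residual outside the singular basis of `X'Y`.
   Because those weight vectors are orthogonal to the column space of
   `X'Y`, their scores have exactly zero covariance with Y.
2. **Orthogonal in Y** (`n_oy` components): symmetric construction on
   the Y side.
3. **Predictive core** (`n_pred` components): NIPALS PLS2 on the
   filtered blocks, with deterministic initialisation from the first
   singular vector of `Y'X` and a deterministic sign convention — each
   component is oriented so that its Y-weight on the first response
   (protein, then lipid) with appreciable magnitude is positive. Under
   nitrogen starvation this orients component 1 as "protein-rich
   (day 0) high", component 2 as "lipid-storing high".

With `n_ox = n_oy = 0` the predictions coincide to machine precision
with standard PLS2 — the correctness anchor, tested against an
independently written NIPALS implementation. Predictive scores are
exactly orthogonal to orthogonal-in-X scores by construction of the
deflation.

Component selection is greedy forward by 5-fold cross-validation
(seeded shuffle, contiguous folds): predictive components first, then
orthogonal-in-X, then orthogonal-in-Y, each accepted while the pooled
Q² improves by more than 0.01 (a rule-of-thumb threshold). Note that an
orthogonal-in-Y component only exists when some Y variation is
genuinely unpredictable from X; on noiseless low-rank data selection
correctly returns predictive components only.

Per-response R²/RMSE values are per-column read-outs of the joint
model; fitting separate single-response models is available but the
joint model is the default. Loading correlations are Pearson
correlations of each predictive score with each centred X column
(zero-variance columns are flagged and set to 0).

## MCR–ALS

The preprocessed calibration matrix `D` (samples × wavenumbers) is
factorised as `D ≈ C S` under non-negativity on both factors, by
alternating exact NNLS solves (rows of C, then columns-wise for S).
Initial estimates are the preprocessed reference spectra (albumin for
protein, an algal lipid extract for lipid, microcrystalline cellulose
for carbohydrate), clipped at zero; an SVD-based initial guess is also
available, and on well-separated components reference initialisation
recovers profiles at least as pure.

Numerical conventions:

* Rows of S are renormalised to unit area each iteration with the
  factor absorbed into C — this pins the scale indeterminacy, so the
  result is invariant (to 1e-8) under positive rescaling of the
  initial spectra.
* Each half step is an exact constrained minimisation, so the lack of
  fit is non-increasing across iterations (asserted per-run in tests).
* Convergence: relative change of the lack of fit below 0.1 % between
  iterations (the toolbox convention for a "0.1 convergence limit"),
  cap 50 iterations.
* `lof_exp = 100·sqrt(Σe²/Σd²)` against the raw matrix;
  `lof_pca` uses the rank-k truncated-SVD reproduction of D (no
  centring) as the reference; explained variance
  `R² = 100·(1 − Σe²/ΣD²) = 100 − lof²/100`.

Concentration profiles are in arbitrary units; each column is
calibrated against the chemical reference values by OLS, with LOO-CV
over the regression stage only (the decomposition is held fixed —
refitting the factorisation per fold is available behind a flag but is
not the standard workflow). Rotational ambiguity of the bilinear model
is acknowledged and not quantified (no ambiguity-band computation);
this is one reason MCR concentrations are calibrated rather than read
off directly.

The decomposition uses all 52 calibration samples; the explicit outlier
lists apply only to the response-wise calibration regressions. MCR gets
no external-validation RMSEP by default; projection of new samples onto
fixed resolved spectra exists behind a flag.

## The synthetic study design

The generator emulates a nitrogen-starvation monitoring study: seven
species-like strains in duplicate reactors, sampled on days 0–8 after
nitrogen depletion — four strains at days (0, 2, 4, 6, 8) and two at
(0, 4, 8), giving 52 calibration samples, plus one held-out strain at
(0, 4, 8) × 2 = 6 external samples. Protein relaxes exponentially from
its replete level (~40–47 % DW) toward a starved floor (~10–16 % DW);
storage pools rise saturably with species-specific partitioning
(lipid-accumulating, carbohydrate-accumulating, or both). All
compositions stay inside the empirical ranges protein 9–48, lipid
0–13, carbohydrate 13–55 % DW. Reactor bias is a seeded multiplicative
jitter held constant over the time course (so protein stays monotone
within a reactor).

Pure-component profiles are sums of Gaussians truncated at ±5σ, with
band placements chosen so that no component contributes intensity
inside another component's diagnostic window and all references share
the same total area. With the noise model switched off and `gamma = 0`
this makes every stage provably exact: mixing weights sum to one, every
sample has identical total area (normalisation reduces to a constant),
and band areas are exactly linear in composition — the `noiseless`
preset, on which the models must achieve R² ≈ 1 and RMSE at the 1e-6
scale.

The `paper_like` preset adds, with one seed controlling everything:

* additive noise (σ = 0.004 absorbance), cubic baseline drift
  (scale 0.03), ATR weighting `gamma = 1`;
* a shared interferent band at 1075 cm⁻¹ with per-sample half-normal
  amplitude (σ = 0.05) — a stand-in for PO₂/Si–O overlap inside the
  carbohydrate window. Its amplitude is deliberately kept below the
  lipid signal scale: a stronger un-modelled rank-1 source makes
  3-component MCR–ALS repurpose its weakest (lipid) component, a known
  degeneracy of unconstrained ALS;
* a per-sample residual-moisture O–H band at 3400 cm⁻¹ (half-normal,
  σ = 0.2 before ATR weighting). It carries no intensity inside the
  fingerprint but inflates the total-area normalisation constant, so
  every band area acquires a shared per-sample multiplicative error —
  precisely the error that band *ratios* cancel. This is the main
  mechanism separating the ratio model from the direct carbohydrate
  model, and it degrades ULRA and MCR calibrations alike, as observed
  in practice;
* wet-chemistry error on the *reported* composition table (σ = 2.6,
  0.9, 4.0 % DW for protein, lipid, carbohydrate — carbohydrate
  extraction being the least reliable assay), independent of the
  spectral noise;
* six planted outlier samples whose reported lipid/carbohydrate values
  are corrupted the way failed extractions corrupt real tables (late
  starvation overestimates in one strain, a day-0 underestimate in
  another). The explicit exclusion lists (2 for lipids, 6 for
  carbohydrates, the lipid list a subset of the carbohydrate list)
  reduce the response-wise calibration sizes to 50 and 46.

The `stress_test` preset raises the drift scale to 0.30 to exercise
baseline correction.

What the generator does **not** emulate: refractive-index dispersion
and anomalous-dispersion band distortion of real ATR optics, Mie
scattering, water-vapour/CO₂ lines, nonlinear detector response, and
band-shape changes with composition (real carbohydrate pools change
*nature*, not just amount, under starvation). Passing tests on this
generator therefore demonstrate correctness of the statistical
machinery and the qualitative mechanism ranking, not instrument-level
accuracy on real biomass.

## Problem sizes and determinism

Default runs operate on 58 spectra × 501 fingerprint points (2 cm⁻¹
grid); the full pipeline (all three methods, including LOO and 5-fold
CV) completes in about a second, and the Monte-Carlo checks (200 slope
replicates; 50 generator seeds for the difficulty-ordering property)
in well under a minute. Everything stochastic — generator noise, fold
assignment — flows from explicit integer seeds; reruns with the same
configuration are byte-identical.
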