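# Methods

This note documents the models implemented in `actipet`, the defaults they
ship with, the numerical choices behind them, and what the synthetic-data
generators do and do not emulate.

## Beam transport and dose

**Stopping power.** Proton mass stopping powers for water, air and kapton
are bundled as CSV tables computed from the Bethe formula (first Born
approximation, no shell or Barkas corrections) with ICRU-49 mean excitation
energies — water 75.0 eV, air 85.7 eV, kapton 79.6 eV — and the standard
Z/A ratios, on a 120-point log grid from 0.3 to 12 MeV
(`scripts/make_stopping_tables.py` regenerates them). In this energy range
the formula tracks tabulated reference data for light media to ~1–2 %,
which is the accuracy class of every dose and range quantity the package
reports. Interpolation is log-log linear (exact at nodes, rejecting
out-of-grid queries); below the grid a power law S ∝ E^(−q) is assumed,
with q taken from the slope of the two lowest grid points.

**CSDA range.** R(E) = ∫₀ᴱ dE′/(ρS(E′)) is evaluated by trapezoid
quadrature on a log-spaced sub-grid whose density is doubled until the
result changes by less than a relative tolerance (default 10⁻⁴), plus the
closed-form power-law tail below the grid. The tail contributes ≲ 1 % of
the range at 7.5 MeV. Computed anchors: 0.726 mm at 7.50 MeV and 113 µm at
2.6 MeV in water, 1–2 % below the commonly tabulated 0.74 mm / 115 µm —
the expected signature of omitting shell corrections.

**Layer degradation.** `energy_after_layers` slows the proton through each
layer by midpoint (RK2) stepping in areal density with steps capped at
2 keV of energy loss. A proton whose energy falls to the bottom of a
layer's table raises an explicit "stopped in layer k" error carrying the
residual range. The default beamline (8 µm kapton at 1.42 g/cm³ plus
7.5 cm of air, read literally as 5 cm window-to-shell plus 2.5 cm
shell-to-tumour) degrades 8.00 MeV to 7.49 MeV, a loss of 0.506 MeV.

**Spots, fluence, dose.** A spot is a single 2-D Gaussian; its spreads
grow with distance according to degree-2 polynomials fitted per axis
(ordinary least squares; ≥ 3 distinct distances required). Spot images are
fitted by least squares with moment-based initialisation, free amplitude,
centre, spreads and constant baseline — moments alone would be biased by
the baseline and by truncation at the image edge. Plans convert beam
current to protons as N = I·t/e, treating the nominal current as exact.
Fluence maps use beam's-eye-view millimetre coordinates on cell centres
(default pitch 0.05 mm, half-extent 5 mm, origin at the plan centroid); a
map whose edge value exceeds 10⁻³ of its maximum triggers a warning or
error. Surface dose multiplies fluence by the *slab-mean* stopping power,
obtained by slowing the proton across the slab (default 100 µm) in 200
equal areal-density steps — at 7.5 MeV the proton loses ~0.6 MeV in
100 µm, so the slab mean (59.9 MeV·cm²/g) is 3 % above the entry value and
matters at the stated precision. No Bragg-curve reconstruction or lateral
straggling is attempted: all supported dose quantities are surface
quantities. Dose homogeneity over a region is deliberately *not* reduced
to a single hard-coded metric; the maps expose the values and the user
chooses the metric.

## Activation model

Yields follow the thick-target expressions A₁₈F = A₀·N_O·f₁₈O·I₁₈F,
A₁₃N = A₀·N_O·(1−f₁₈O)·I₁₃N, A₁₁C = A₀·N_N·I₁₁C, where N_O, N_N are atoms
per gram (nominal masses 16 and 14 — the composition is only quoted to
three digits), f₁₈O is the fraction of oxygen atoms replaced by ¹⁸O, and
I_X = ∫₀^Ep σ_X(E) dE are the packaged integrated cross sections, valid
only at Ep = 7.5 MeV (75.1, 53.3 and 1130.71 mb·MeV for ¹¹C, ¹³N, ¹⁸F).
Any other Ep requires user-supplied integrals, and Ep ≥ 16.79 MeV is
refused outright because ¹⁵O production would open and the three-isotope
model becomes incomplete. Whether these A_i denote produced nuclei or
activities is left as a convention: the package treats them as
*proportional to produced nuclei*, and every downstream use is a ratio of
like quantities at a common reference time, where the convention cancels.

**The two ¹³N/¹¹C conventions.** The transparent cross-section ratio gives
A₁₃N/A₁₁C ≈ 8.41·(1−f₁₈O) for the default carcinoma composition
(H 9.8 %, C 19.5 %, N 4.8 %, O 65.0 % by mass). The calibrated constant
used by the fitting constraint is 0.394·(1−f₁₈O) — a factor ≈ 21 smaller —
because it embeds a transport simulation's full σ(E) weighting along the
slowing-down path, which single energy-integrated cross sections cannot
carry. Both modes are exposed (`mc_constant`, the default for fitting
constraints, and `xs_integral`); the disagreement is a documented property
of the data, not a bug, and the same limitation explains why the
order-of-magnitude Bragg-peak activity estimator
(`predict_bp_activity`: fluence from dose via the activation-window mean
stopping power, nuclei per proton from ∫σdE/ρS̄, spread over the
activation path length) lands roughly an order of magnitude below
published transport-simulation values for comparable scenarios. It is
reliable for scaling arguments (it is exactly linear in dose and
enrichment), not for absolute detectability claims.

**Enrichment inference.** f₁₈O = (A₁₈F/A₁₁C)·(N_N/N_O)·(I₁₁C/I₁₈F) from
decay-corrected amplitudes; relative uncertainties combine in quadrature;
results outside [0, 1] are clipped and flagged. The inference is the exact
algebraic inverse of the yield model, so noiseless round-trips are exact.

## Decay-curve decomposition

Events are filtered to the 511-keV photopeak window, read as ±10 % of the
centre (459.9–562.1 keV); the alternative reading (10 % *total* width) is
selectable. Counts are histogrammed (default 10-s bins) on a common clock
whose origin is the end of irradiation — the irradiation lasts only 90 s,
so the end-versus-start distinction is sub-percent and the origin is
configurable. Bins overlapping declared acquisition gaps are masked; a
flat background rate (from a no-sample acquisition) is subtracted.

Because the decay constants are fixed at the Table values
(T½ = 109.77 / 20.364 / 9.965 min), the model is *linear* in the
amplitudes, and the fit is solved exactly as a bounded (A ≥ 0) weighted
linear least-squares problem (`scipy.optimize.lsq_linear`) rather than by
generic nonlinear iteration. Weights default to Neyman variances
max(raw counts, 1) + (σ_bg·Δt)² per bin; an iteratively reweighted
model-based (Pearson) alternative is available since the original
analysis's weighting convention is not knowable. The covariance is
(XᵀWX)⁻¹ with no reduced-χ² rescaling — the variances are counting
statistics, not a free scale. The ratio constraint replaces A₁₃N with
(1−f₁₈O)·0.394·A₁₁C through a linear reduction matrix, so the tie holds
exactly and the tied amplitude's covariance entries are fully correlated
with ¹¹C. Non-negativity comes from the bounded solver, never post-hoc
clipping; amplitudes ending below 10⁻⁸ of the largest are flagged
"at bound". In the ex-vivo pipeline the constraint's f₁₈O is unknown a
priori, so the pipeline iterates fit → infer f₁₈O → refit to a fixed
point (2–3 passes suffice; the ¹⁸F/¹¹C ratio barely feels the tied ¹³N
amplitude).

**Retention.** Retained fractions are ratios of decay-corrected amplitudes
at a common reference time (default end of irradiation), with first-order
error propagation. ¹¹C and ¹³N are pooled under the assumption that the
wash does not change their activity ratio — justified because the post-wash
measurement starts ≥ 5 ¹³N half-lives after irradiation, leaving the two
channels nearly degenerate. A known artefact at study-like timing: the
pooled short-lived channel's post-wash signal is a few cps under a
hundreds-of-cps ¹⁸F, so the bound-constrained estimator carries a small
positive truncation bias (~+0.02 on a truth of 0.14) while its CI covers
the truth at above-nominal rate; the ¹⁸F channel, with strong signal in
both windows, shows no measurable bias.

## Washout fitting

TACs are fitted to A(t) = A₀·e^(−(λ_phys+λ_bio)t) with λ_phys fixed at ¹⁸F
and λ_bio ≥ 0 free (`scipy.optimize.least_squares`, log-linear regression
start values). The model value for a frame is by default the decay
integral over the frame divided by its length — for 60-min frames the
midpoint approximation misstates the first frames by enough to bias T_comb
at the stated precision, so midpoint evaluation is an explicit option, not
the default. A fit pinned at λ_bio = 0 is reported as "no detectable
washout" with T_bio = ∞. Confidence intervals use the (A₀, λ_bio)
covariance with a normal quantile when per-frame uncertainties are
supplied (they are then known variances) and a Student-t quantile with
reduced-χ² scaling otherwise; intervals for T_bio and T_comb are mapped
monotonically from the λ_bio interval rather than linearised, so the
λ_bio ≥ 0 boundary maps cleanly to infinite half-life. Coverage measured
on 500 synthetic TACs at 3 % noise is ~96 % at 95 % nominal.

The algebra helpers enforce 1/T_comb = 1/T_phys + 1/T_bio exactly:
`combined_half_life` and `washout_half_life` are mutual inverses, the
latter refusing T_comb ≥ T_phys ("no positive washout"), and biological
retention at time t is 2^(−t/T_bio).

## Synthetic data

`ScenarioSpec` carries the full ground truth. Event streams are
inhomogeneous Poisson processes per isotope: the count over each live
interval is Poisson with mean equal to the integral of A·e^(−λt), and
times are drawn by inverse-CDF sampling of the truncated exponential
(exact, no thinning rejection loop). Energies are Gaussian photopeaks with
6 % FWHM at 662 keV scaled as 1/√E (13.7 % FWHM at 511 keV); background is
flat in time and uniform over 300–700 keV, normalised so the rate inside
the default analysis window matches the scenario spec (default 1 cps — the detector
has low internal activity, and no value is printed anywhere to calibrate
against). `simulate_count_series` produces the statistically equivalent
binned counts directly and is used for replicate studies. All generators
are pure functions of (spec, seed).

Presets: T1–T4 use a 29-min pre-wash window starting 10 min after
irradiation and a 22-min post-wash window starting at 55 min, enrichments
spanning 0.61 % (T1) to 3.0 % (T4), retention truth 0.59 (¹⁸F) and 0.14
(¹¹C/¹³N); T3 carries a 10-min mid-acquisition gap (its window is extended
to 39 min so the live time matches the others). E1/E2 are nine 60-min PET
frames starting 3.75 h after irradiation with T_bio = 14.7 h and 21 h and
3 % frame noise. Absolute count rates are not printed in any source, so
the presets use hundreds of cps pre-wash — a one-time calibration choice;
each preset's ¹⁸F amplitude follows from its ¹¹C rate through the
transparent yield ratio (so enrichment inference round-trips to the truth)
while its ¹³N amplitude follows the calibrated 0.394 constant (so the
fitting constraint is well-specified). Purely statistical uncertainties at
these rates are tighter than the published retention errors, which include
tumour-to-tumour systematics the generator does not model.

What passing tests on these data show: the inverse analyses are unbiased
and their intervals calibrated *under ideal counting statistics*. What
they do not show: robustness to dead time, pile-up, Compton continuum,
scatter/randoms, segmentation error or physiological variability — none of
which the generators emulate.

## Problem sizes and determinism

Replicate studies in the test suite use 300–500 seeded repetitions of the
study-scale scenarios (≈ 170 ten-second bins per window, nine frames per
TAC), enough to pin coverage rates to a few percent; the exact-linear
decay fit makes each replicate essentially free. Every stochastic routine
takes an explicit NumPy `Generator` or integer seed; identical seeds give
bit-identical outputs. `scripts/acceptance.py --seed N` derives all of its
randomness from the given seed.

## Known limitations

* Bethe-only stopping powers: 1–2 % low-energy bias, visible as ranges
  ~2 % below standard tabulations; adequate for surface-dose and
  energy-loss bookkeeping, not for sub-percent dosimetry.
* Packaged cross-section *integrals* only, valid at Ep = 7.5 MeV: no
  energy-dependent σ(E), hence the documented gap between the
  `xs_integral` and `mc_constant` ratio conventions and the
  order-of-magnitude-only Bragg-peak activity estimator.
* Surface-slab dose only; no Bragg-curve or straggling model.
* Detector response is one efficiency scalar plus flat background; no
  absolute-Bq calibration.
* The pooled short-lived retention estimator is truncation-biased upward
  at study-like timing (see above); shorter pre/post delays would remove
  the degeneracy that causes it.
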