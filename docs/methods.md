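# Methods

This note documents the models, numerical choices and limitations of the
`varvent` package. Nothing here states a result that the test suite or the
analysis drivers do not themselves compute.

## Spontaneous-breathing generator

Breath amplitudes (proportional to tidal volume) and periods are stationary
lognormal AR(1) processes: `z_i = φ z_{i−1} + √(1−φ²) ε_i` with `ε ~ N(0,1)`
and `x_i = exp(μ + σ z_i)`, where `σ = √ln(1+CV²)` and `μ = ln(mean) − σ²/2`,
so the requested mean and CV hold exactly in distribution. Lognormality
guarantees positivity; the mild autocorrelation (default φ = 0.3) mimics the
breath-to-breath memory of real breathing. Defaults are the awake-COPD-rabbit
calibration: VT 7.1 mL/kg (CV 12.6%), RR 22.9 /min (CV 12.9%). Each breath
contributes a raised-cosine pressure bump; movement artifacts are 8 Hz bursts
at six times the mean amplitude, uniformly placed at 0.5/min for 2 s, and
annotated. The artifact model is a stand-in — real plethysmographic artifacts
(grooming, posture shifts) are not characterized here — so artifact-detector
performance on real data is not implied by the tests. The trace carries no
baseline drift or box-compliance dynamics; breath detection on real
recordings will be harder than on these fixtures.

## Breath detection and pattern construction

Detection band-passes the trace (Butterworth order 2, 0.1–3 Hz, zero-phase
with generous padding so edge transients stay clear of the first and last
cycles), delimits cycles at linearly interpolated upward zero crossings, and
rejects cycles whose band-passed excursion falls below 25% of the median
(noise crossings). Amplitudes are read from the raw trace within each cycle;
the filtered copy is used only for segmentation. Breaths overlapping artifact
intervals or an excision boundary are excluded. The detection parameters are
arguments, not constants.

The pattern is the ratio pair `(a_i/ā, T_i/T̄)` renormalized so both means
are exactly 1 (to float precision; asserted at 1e−9). Rescaling to target
mean VT and RR is multiplication by constants, so every dimensionless shape
statistic — CV, min/mean, max/mean, successive ratios — is preserved
exactly, and building a pattern from a rescaled schedule returns the original
ratios. The 382-breath pattern length and the pooling of four 10-minute
recordings follow the modeled derivation protocol; when several animals'
recordings contribute, pooling them in temporal order is the convention
adopted here.

## Lung model and ventilation runs

The forward model is a single-compartment linear system
`P_aw(t) = R·V̇(t) + E_eff·V(t) + PEEP`. Time-domain fractional-order
(constant-phase) simulation is out of scope; instead the tissue compartment
folds into the Newtonian pair at the breathing frequency `f_b`:

- `E_eff = H / f_open` — only the recruited fraction `f_open` of units
  accepts volume;
- `R = R_aw + G/(2π f_b)^α` with `α = (2/π)·arctan(H/G)` — the real part of
  the constant-phase tissue impedance at `f_b`.

Pressure profiles are square with a 50 ms linear rise and fall (avoiding
flow impulses). Because each breath is piecewise constant in pressure, the
ODE has the exact charging/discharging solution
`VT = (ΔP/E_eff)(1 − e^{−T_insp·E_eff/R})` with end-expiratory volume carried
between breaths; the 6-h runs use this closed form per breath (≈8,600
breaths in well under a second), while the sampled solver `apply_to_lung`
(exponential-integrator update per sample) exists for waveform-level work and
agrees with the closed form within 0.5%.

Recruitment dynamics are a deliberately minimal two-parameter mechanism:
`f_open` decays as `exp(−c·dt)` (c = 5×10⁻⁴/min, losing ≈16% over 6 h of
monotonous 7 mL/kg breaths) and a breath above 9 mL/kg recruits 2% of the
closed units. These constants were set from the qualitative behavior the
model must emulate — double-digit percent derecruitment over a monotonous
6-h run, reopening by sporadic large breaths — not from any fitted data;
the mechanism has no claim to alveolar micromechanics.

Protocol mirrors: a recruitment maneuver (25 cmH₂O held twice for 10 s,
modeled as `f_open → 1`) precedes each run; driving pressure is calibrated
once at H0 to deliver the 7 mL/kg target and then held constant; a
proportional controller adjusts RR by ±1/min per 5-min epoch (bounds
10–60/min) to keep end-tidal CO₂ — taken as PaCO₂/(Pb − PH₂O) — inside
5.5–6%. Hourly rows H0–H6 report the lung state, loop-averaged delivered VT
(averaging over one full pattern loop avoids aliasing the 382-breath cycle),
and blood gases. Auto-PEEP is flagged when end-expiratory flow exceeds 5% of
peak expiratory flow; its magnitude is `E_eff·V(end-expiration)`.

## Forced oscillations

The default forcing uses 15 frequencies on a 0.1 Hz grid within 0.5–20.9 Hz
chosen to be pairwise non-integer multiples (validated programmatically), so
no component's harmonics, generated by any mild nonlinearity, land on
another component. Phases are picked by seeded random search (200 trials)
minimizing crest factor; the summed signal is scaled to 2 cmH₂O peak-to-peak
exactly.

Impedance estimation is the H1 cross-spectral estimator on Hann-windowed 4-s
segments advanced by 5% of the window (95% overlap). A deliberate numerical
choice: Fourier coefficients are evaluated by complex-exponential correlation
*at the exact design frequencies* rather than at FFT bin centres — a 4-s
window has 0.25 Hz bins, which miss most design frequencies, and bin
snapping alone costs more reactance error at low frequency than the
estimator's own noise floor. Per-frequency magnitude-squared coherence is
reported; frequencies with negligible flow power are excluded, and the
estimate fails if more than a third are.

The model `Z(f) = R_aw + i·2πf·I_aw + (G − iH)/(2πf)^α` uses the standard
derived exponent `α = (2/π)·arctan(H/G)`, so α is always consistent with
G and H. Fitting minimizes `Σ|Z_meas − Z_model|²` (optional 1/|Z| weighting)
with bounded trust-region least squares from 20 seeded log-uniform starts
(bounds: R_aw ∈ [1, 200], I_aw ∈ [0, 1], G ∈ [1, 500], H ∈ [10, 2000] in
cmH₂O-based units). Solutions pinned at a bound are flagged, never silently
returned. Noise-free recovery is exact to optimizer tolerance; under 5%
instrument noise on pressure and flow with the three-epoch protocol, median
parameter errors are a few percent. Identifiability caveat: a very small
inertance (I_aw ≈ 0.01 cmH₂O·s²/L) contributes ≲1.3 cmH₂O·s/L of reactance
below 21 Hz and cannot be recovered to a few percent from noisy spectra by
any estimator — its Cramér–Rao bound exceeds that — so the Monte-Carlo
characterization uses I_aw = 0.05, where the parameter is identifiable.

## Gas exchange

CO₂ obeys the clearance law `PaCO₂ = 0.863·V̇CO₂/V̇A` (V̇CO₂ = 5.1 mL/min/kg,
dead space 2.2 mL/kg — chosen so normocapnia sits at VT 7 mL/kg, RR ≈ 23).
Oxygen saturation is a Hill curve (P50 = 30 mmHg, n = 2.7,
rabbit-plausible); content is `1.34·Hb·SO₂ + 0.003·PO₂`. The forward model
mixes end-capillary and fixed venous (PvO₂ = 40 mmHg) contents by
`shunt = baseline + 0.8·(1 − f_open)` and inverts the content curve
(Brent root-finding, tolerance 1e−10) for PaO₂. The estimator recomputes
CcO₂ via the alveolar gas equation `PAO₂ = FiO₂(Pb − PH₂O) − PaCO₂/RQ`
(Pb 760, PH₂O 47, RQ 0.8, all configurable) and applies the Berggren ratio.
Because generator and estimator share one dissociation curve, the round trip
is exact to root-finder tolerance — which validates the plumbing, not the
curve: no temperature, pH or 2,3-DPG effects are modeled, and CO₂ content
bookkeeping is deliberately absent. Contents violating cc ≥ ca ≥ cv produce
a warning and an out-of-range shunt, never silent clipping.

## Imaging

The fluoroscopy generator renders exactly `round(f_aer·area)` radiolucent
pixels inside a two-ellipse lung region, selected through a smoothed random
field with a gravity bias so aeration loss is spatially coherent; intensity
modes (58 vs 172 on an 8-bit scale, σ = 6 speckle) stay separable, which is
what makes the Otsu threshold recover counts within 1%. Real fluoroscopy has
overlapping mediastinal shadows and no such bimodality — which is why such
segmentation is done manually by radiologists in practice — so the tests
validate the counting and percent-change arithmetic, not radiographic
segmentation difficulty.
The aerated fraction shown to the imaging pipeline is proportional to the
lung model's open fraction (base 0.55 at full recruitment).

MLI lays horizontal/vertical test lines every 20 px (7 px for disc
phantoms, which need denser sampling), measures air chords bounded by
tissue on both sides within non-excluded stretches, and reports total air
length over the number of complete air chords. Chords touching the image
edge or an exclusion boundary are dropped (truncation bias); lines meeting
no tissue are skipped as degenerate. The alternative total-line-length
denominator is available by flag since the literature uses both. Stripe
phantoms validate the chord measurement exactly; disc phantoms check the
integral-geometry relation (mean chord of a disc across parallel lines =
π/4 of its diameter) within pixelization error. Field averaging follows the
18-fields-per-subject protocol.

## Study planning

Sample size uses the exact noncentral-*t* power of the two-sided two-sample
*t* test, iterating n upward — at d = 20/15, α = 0.05, power 0.8 this gives
10 per group (achieved power 0.805), where the normal approximation gives 9;
the exact route is the one that matches the modeled enrolment plan. Dropout
inflation is `round-half-up(n·(1+rate))`: 20 at 10% → 22 (the alternative
`n/(1−rate)` convention would round to 23). Pearson correlation delegates to
the standard product-moment implementation. Routine inferential machinery
(RM-ANOVA, post hoc tests, rank tests) is deliberately thin delegation.

## What the synthetic conditions do and do not show

Passing tests demonstrate internal consistency — estimators recover what
generators encode, closed forms match simulations, protocol arithmetic is
right — under idealized signals: no sensor drift, no cardiogenic
oscillations, no spontaneous effort, single-compartment homogeneity, a
one-parameter recruitment law. Directional findings (variable ventilation
preserving recruitment, compliance, oxygenation) reproduce the qualitative
physiology by construction of the recruitment mechanism and should not be
read as quantitative predictions for any animal. Problem sizes used
throughout (10-min recordings at 250 Hz, four synthetic animals, five
pattern seeds, 50 Monte-Carlo fit replicates) were chosen as the smallest
that leave the statistics stable.
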