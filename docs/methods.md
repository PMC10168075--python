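# Methods

This note documents the models implemented in `innerbark`, the choices made
where the procedure was genuinely open, what the synthetic-data generator
does and does not emulate, and the known limits of the method.

## The measurement and its derived series

A two-point dendrometer records the trunk-surface radius (on the living
inner bark) and the xylem-surface radius at the same stem location every
10 min; their difference is the inner bark thickness Th_IB (µm, relative to
an arbitrary offset). Because both sensors share one frame, thermal
expansion of the frame cancels in the difference and no temperature
correction is applied. A stem psychrometer next to the dendrometers gives
the local xylem water potential Ψ_X (MPa, ≤ 0).

Raw series are snapped to an exact 600-s grid. Gaps of at most 1800 s
(three steps) are filled by linear interpolation and flagged; longer gaps
are flagged missing and excluded from every downstream statistic — there is
no imputation of multi-hour or multi-week dropouts. Operator-declared
intervals (resin-blocked sensors, psychrometer malfunction) are flagged
discarded; the pipeline manifest records every discard.

Seasonal growth is removed by loess-based seasonal-trend decomposition
(STL) with a period of one day (144 samples). Window choices, all
configurable:

- trend window: 7 days (1009 samples). Growth drifts by a few µm/day while
  the diurnal cycle turns over daily; 7 days separates the two cleanly.
- seasonal window: 2001 (effectively "periodic" — the diurnal template is
  allowed to evolve only very slowly).
- robust fitting on, with the robustness sweeps capped at 3 outer
  iterations; on multi-week dendrometer series more sweeps change nothing
  visible and cost fivefold runtime.

The detrended series is defined as raw − trend, so the decomposition is
exact by construction at every valid sample.

## Diurnal metrics

For each calendar day, the thickness maximum is searched in [00:00, 24:00)
and the minimum in the 24 h following the maximum, because on some days the
bark keeps shrinking past midnight; amplitude = max − min. Ties break to
the earliest time. Days with fewer than 80% valid samples are marked
invalid.

The lag of thickness behind Ψ_X is the argmax over lags (multiples of
10 min, |lag| ≤ 12 h) of the normalized cross-correlation of the
mean-centred day series; the signed correlation is maximized, not its
absolute value, and a negative lag means thickness lags behind Ψ_X. The
expected physiological sign (positive peak correlation) is recorded as a QC
flag rather than enforced.

Seasonal climate responses of the daily amplitude follow the field's
conventional forms: linear in daily global radiation, quadratic in maximal
VPD (the vertex of the parabola estimates the saturation point beyond which
amplitude no longer responds), and exponential in mean air temperature,
fitted by log-linearization with non-positive amplitudes dropped. The
apparent Q10 is exp(10k) for the fitted rate k (per °C). Tree-level
structure is approximated by per-tree fits plus a pooled fit with fixed
per-tree intercept offsets; full random-effects machinery is intentionally
out of scope since only per-tree and pooled summaries are reported.

VPD is computed as e_s(T)·(1 − RH/100) with the Buck-type saturation curve
e_s(T) = 0.61365·exp(17.502·T/(240.97 + T)) kPa; the constants are fixed in
code so results are bit-reproducible.

## The radial water-exchange model

The inner bark is an elastic water reservoir coupled to the xylem through a
finite radial hydraulic conductance. Per calendar day, with ΔΨ_X and ΔTh_IB
anchored at the first measurement at midnight:

    dTh_IB/dt = α (β ΔΨ_X − ΔTh_IB) + γ        [µm per 10-min step]

- α (step⁻¹): relaxation rate; 1/α is the exchange time constant.
- β (µm MPa⁻¹): equilibrium thickness change per unit potential.
- γ (µm step⁻¹): within-day drift (residual growth, slow osmotic trend).
- αβ (µm MPa⁻¹ step⁻¹): the radial hydraulic conductance; ×10⁻⁶/600
  converts to m MPa⁻¹ s⁻¹.

The equation is fitted as the linear regression dTh = c₁ΔΨ + c₂ΔTh + c₀
with α = −c₂, β = c₁/α. This parenthesization is chosen deliberately so
that c₁ = αβ is the conductance, and the forward-difference regression is
exactly consistent with the prediction recursion

    ΔTh(t+1) = ΔTh(t) + α(β ΔΨ_X(t) − ΔTh(t)) + γ,   ΔTh(0) = 0,

whose step response is a geometric series (for a step ΔΨ: β·ΔΨ·(1−(1−α)^t)),
and which is a contraction for 0 < α < 1.

Ten-minute regression residuals are strongly autocorrelated, so estimation
is generalized least squares with AR(1) errors. The AR coefficient φ is
profiled on a fixed grid (step 0.01, |φ| ≤ 0.98) with exact whitening at
each φ (first row scaled by √(1−φ²), later rows quasi-differenced) and the
Gaussian likelihood maximized over the grid. This is deterministic — no
iterative-convergence ambiguity — and matches `statsmodels` GLSAR to within
a fraction of a percent on test problems, which the suite checks as an
independent oracle.

Per-day fits are screened before use ("unrealistic adjustments"):
rejected when α ≤ 0, β ≤ 0, |φ| ≥ 0.99, the relative SE of c₁ exceeds
100%, or the prediction R² against the observed ΔTh is negative. Days with
rainfall > 1 mm and days with any missing/discarded sample are excluded
before fitting. All thresholds are configuration knobs.

The **turgor-related signal** is the observed-minus-predicted ΔTh series of
an accepted fit: the part of the thickness trajectory the constant-osmoticum
capacitor cannot explain, attributed to varying solute content of the
phloem. Its daily amplitude (max − min) can be converted to a pressure
amplitude via Hooke's law, ΔP = ε·ΔTh/Th, given a bulk elastic modulus ε
(15–20 MPa is the plausible range for inner bark) and the absolute bark
thickness.

## Osmotics

Phloem hydrostatic pressure is estimated by van 't Hoff:

    P_H = Ψ_X + C_S · R · T,   R = 0.008314 L MPa mol⁻¹ K⁻¹,

with the sap osmolality (mol/kg) standing in for the molar concentration
(mol/L) without density correction. T defaults to 298.15 K, the osmometer's
operating temperature; this is also the only choice under which dawn
pressures computed with Ψ_X ≈ 0 reproduce tabulated dawn values, because
overnight rehydration brings the stem close to zero tension by dawn.
Replicate osmolalities are averaged per tree, the pressure is computed per
tree with that tree's Ψ_X at sampling time, and cell statistics (date ×
time-of-day × position) are means and SDs over trees. Axial gradients are
upper − lower, so a positive pressure gradient drives Münch flow downward.
The early-afternoon P_H–Ψ_X regression is ordinary least squares, and its
zero crossing −intercept/slope estimates the xylem potential at which
phloem turgor is lost.

## Synthetic campaigns

The generator produces complete campaigns — climate, ψ, dendrometer pairs,
osmotic sampling tables — from a single seed fanned out into named
substreams (adding a stream never perturbs others). Everything is a pure
function of (parameters, seed).

- **Climate**: diurnal solar arch with a per-day clear-sky fraction
  (Beta-distributed), multiplied by an AR(1) log-attenuation modelling
  within-day cloud passage; temperature lags radiation (peak 14:30) and RH
  moves in anti-phase; occasional rain days. Field radiation is broadband,
  and this structure is also what identifies the exchange dynamics (below).
- **ψ forcing**: a weighted radiation/VPD drawdown toward a per-day random
  depth, tracked quickly while drying (rate 0.5/step — tension propagates
  fast along the transpiration stream) and slowly while rewetting
  (0.08/step — nocturnal refill through finite conductances), clipped to
  [−1, 0] MPa. Daily maxima sit near zero before dawn and sunny-day minima
  near −0.6..−0.8 MPa; daily ψ-minima correlate with daily VPD-maxima as in
  the field.
- **Thickness**: the capacitor recursion driven by latent ψ, with the
  osmotic (turgor) waveform injected *inside* the dynamics as an
  equilibrium offset — osmotically drawn water crosses the same radial
  conductance, so the realized turgor component is the waveform filtered by
  the first-order dynamics (gain ≈ α/√(α²+ω²) at the daily frequency). The
  generator returns this realized component as ground truth. A linear
  growth ramp (30% of trunk growth in the bark, 70% in the xylem radius)
  and AR(1) observation noise complete the series.
- **Defaults**: αβ = 4.8 / 1.8 µm MPa⁻¹ step⁻¹ at the upper/lower
  positions (the field conductance medians, 8×10⁻⁹ / 3×10⁻⁹ m MPa⁻¹ s⁻¹),
  α = 0.1 step⁻¹ (~100-min time constant, consistent with the ~2-h
  thickness–ψ lag), growth 1–8 µm/day by tree and height, thickness noise
  σ = 0.01 µm at the sensor resolution floor (φ = 0.6), ψ noise 0.001 MPa
  (instrument repeatability at 10-min cadence; slow accuracy offsets cancel
  in the midnight-anchored differences), and a night-rising osmotic forcing
  of 6 / 3 µm equilibrium amplitude.

### What the generator does *not* emulate, and why

The osmotic forcing amplitude deliberately stays a minor within-day
perturbation (~15–20% of the ψ-driven amplitude). This is an identifiability
boundary of the residual method itself, found and mapped during design:
when the within-day osmotic forcing is of the same order as the ψ-driven
signal, the regression state ΔTh is dominated by the filtered forcing, the
estimated α flips sign on essentially every day, and all fits fail the
realism screen — the conductance c₁ = αβ alone remains estimable (to
~15–25%) because Δψ is exogenous. AR(1) whitening cannot rescue α: it
suppresses the low-frequency confound only in proportion to ω². Field
reports of turgor-residual amplitudes comparable to the thickness amplitude
should therefore be read with care: such residuals necessarily contain
model error, and the procedure cannot certify them as pure osmotic signal.
Passing recovery tests here demonstrate that the machinery is correct and
calibrated in the regime where the method is identified — not that
arbitrarily large real-world residuals are unbiased osmotic estimates.

Also out of emulation scope: cross-correlated sensor noises, mechanistic
Münch flow coupling along the trunk, weather reanalysis realism, and
diurnally varying radial conductance (aquaporin activity).

## Numerical choices and degenerate inputs

- φ grid step 0.01, |φ| ≤ 0.98; fits at the grid edge are screened by the
  |φ| ≥ 0.99 rejection rule anyway.
- Constant ΔΨ days raise a collinearity error rather than returning noise.
- Ties (extrema, lags, profile-likelihood maxima) resolve to the earliest
  time / smallest |lag| / first grid point, for determinism.
- Empty cells, single-tree cells, and unpaired positions in the osmotic
  summary are flagged or raise pairing errors; SDs over one tree are NaN.
- The tiny fixture spans 3 days — the minimum for the daily STL
  decomposition (≥ 3 full periods).
- Recovery studies run 100 campaigns of 9 days × 3 trees × 2 positions;
  the problem size keeps a full study within a few minutes on one core
  while giving ~5 000 day-fits.

## Known limitations

- Per-day fits assume the osmotic content constant within the fit and
  attribute all misfit to the residual; see the identifiability discussion
  above.
- The thickness regression contains the observed ΔTh with its measurement
  noise (an errors-in-variables term); at instrument-scale noise this bias
  is below a few percent, but noisy installations will attenuate α.
- mol/kg ≈ mol/L in the van 't Hoff step ignores sap density; the error is
  at the percent level for the osmolalities involved.
- Afternoon hydrostatic pressures require the concurrent Ψ_X; with the
  dawn approximation Ψ_X ≈ 0 only dawn cells are exactly reproducible.
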