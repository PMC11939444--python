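# Methods

This note documents the models behind each `rfdosim` module, the
parameter choices that matter, what the synthetic-data generators do
and do not emulate, and the numerical conventions.

## Dosimetry chain

The chain converts a spectrum-analyzer reading into the incident
plane-wave power flux at the sample plane:
`P_ELEC = P_MES/A_CABLE`, `U_ELEC = √(P_ELEC·Z0)`, `E = AF·U_ELEC`,
`P_EMG = E²/η0`. The default calibration constants are the physical
chain's values at 1.77 GHz: cable attenuation −3.896 dB (linear
coefficient 0.40776), antenna factor 179.89 m⁻¹, 50 Ω port, 377 Ω air
wave impedance, −75 dBm analyzer floor. Unit discipline is enforced by
naming and types: absolute powers are dBm or watts, gains/attenuations
are dB; a reading at or below the floor propagates as a typed
below-floor flag through tables and reports and is never imputed.

Two reproduction caveats on the published ladder, both treated as
print-precision artifacts rather than chain errors:

* the E cell at +20 dBm prints 2.05 V/m where the chain's own constants
  give 2.038 (0.6 % off); the matching flux cell (1.1×10⁻² W/m²) agrees
  at printed precision, so checks pin the flux, not that E cell;
* four flux cells print mantissa 2.9 where the chain gives 2.966
  (which rounds to 3.0); the published values appear truncated, and
  comparisons there use a 2.5 % band instead of exact 2-figure
  rounding. All other cells agree exactly after rounding to the
  printed figures.

Wavelength from frequency uses a propagation speed of 2.998×10⁸ m/s;
the far-field check of the 5.5 cm patch antenna uses the published
wavelength 0.165 m as input, giving the 3.67 cm bound (the sample sits
at 16.8 cm). The ICNIRP reference-level formulas are valid for
400–2000 MHz only and raise outside that band rather than
extrapolating.

## Field-map statistics

Maps are 1 mm-pitch grids; the Petri mask is the set of pixel centers
*strictly* inside a 52 mm circle centered on the grid center (the
boundary convention is fixed for reproducibility; whether the published
"~52 mm" is inner or outer diameter is not stated). Inhomogeneity is
`100·σ/mean` with the population standard deviation — the masked pixels
are the entire population of interest, not a sample — and is
scale-invariant. Polarization ratios are means of component magnitudes
over the mask. The plane-wave ratio divides the mask-mean of `|E|²/2η`
by the mask-mean magnitude of `Re(E×H*/2)`; it equals 1 exactly only
for `H = ẑ×E/η`, which is why the statistic refuses to run without H
rather than silently assuming a plane wave. Field components use the
peak-amplitude convention (`flux = |E|²/2η`); the probe chain's scalar
`E` is RMS (`flux = E²/η`). With cross-polarized components present the
Poynting direction tilts slightly, so the ratio on a constructed
(0.053, 0.015)-ratio map exceeds its x-polarized value by ~0.14 %; the
1.01-anchor map is therefore built x-polarized with H scaled by 1/1.01.

## Thermal budget

`ΔT = P_EMG·Surf_petri·Δt/(C·V)` with the duration in hours and the
volumetric heat capacity in Wh/(m³·K) — the unit contract is part of
the type, nothing converts silently. Shipped capacities: water
1160 Wh/(m³·K) and kidney tissue 1012 Wh/(m³·K). At the peak flux
(1.1×10⁻² W/m², 15 min, 53 mm dish, 4.5 mL) the water budget is
1.16×10⁻³ K. Note the published kidney-tissue figure of 1.37×10⁻³ °C
does not follow from its own printed inputs, which give 1.33×10⁻³;
the package reports the computed value and does not guess at the
discrepancy's cause.

## Regulation simulator

The plant is first-order-plus-dead-time:
`dT/dt = (ambient + K·u(t−θ) − T)/τ` with duty `u ∈ [0, 1]`. No plant
constants were published for the physical box, so the fixture plant is
synthetic — K = 30 °C/duty, τ = 600 s, θ = 20 s, ambient 22 °C — chosen
as a plausible slow thermal loop whose closed-loop behavior matches the
described regulation qualitatively (initial heating phase, <1 °C hood
dips, ±0.2 °C steady regulation).

Controller: PI by default (derivative available but zero — the usual
IMC practice for slow thermal plants), tuned by the IMC rules for an
FOPDT plant, `kp = τ/(K·(λc+θ))`, `Ti = τ`, with closed-loop time
constant λc = 120 s by default. The integrator is held while the output
saturates (anti-windup), and the derivative term acts on the
measurement. The controller updates once per 5 s PWM period; the PWM is
modeled as its mean duty within each period (τ ≫ period, so sub-period
switching dynamics are negligible). The plant integrates with a fixed
explicit step of 0.5 s (must stay ≤ period/10); runs are bit-for-bit
reproducible given the seed.

Hood openings add the plant's disturbance offset (−0.9 °C by default)
to the *sensed* air temperature while open, modeling the fast air
exchange at the sensor; routing the disturbance through the 600 s plant
pole instead would produce ~0.04 °C dips, inconsistent with the
sub-degree transients the regulation is known to show. A simulation
launched exactly at the setpoint preloads the integrator with the
equilibrium duty (bumpless start), so the hood-event scenarios model
the regulation phase after warm-up.

Step-response identification fits
`T(t) = T0 + K·Δu·(1−exp(−(t−θ)/τ))` by least squares with T0 free (the
first sample is noisy) and heuristic initial guesses (63.2 % rise time,
onset threshold). A trace is rejected as unsettled when its last two
10 %-windows differ by more than 1 % of the total rise. Noiseless
recovery of the fixture plant is within 0.05 % (gain), 0.05 % (τ) and
10⁻⁹ s (θ); with 0.05 °C sensor noise all three stay within ~5 %.

## Expression pipeline

Standard single-reference Livak quantification, computed per replicate:
`ΔCt = Ct_target − Ct_ref`, `ΔΔCt = ΔCt − mean(ΔCt_control)`,
`RQ = 2^(−ΔΔCt)`. The reported fold change is `2^(−mean ΔΔCt)` — the
mean on the cycle (log2) scale, equivalently the geometric mean of the
replicate RQs — so the control condition is exactly 1 by construction;
SEM is the replicate-RQ standard deviation over √n. ANOVA (one-way,
across all conditions) and Tukey HSD run on the replicate-level RQs,
linear scale by default with a log2 option (the original analysis does
not state its scale); only comparisons against the control group are
reported. Shapiro–Wilk is advisory: a failed normality check warns but
does not switch tests, mirroring the original workflow. Stars use
strict thresholds <0.0001/<0.001/<0.01/<0.05 (four levels; boundary
values take the weaker label).

The dose–response classifier is an operationalization of the verbal
"U-shaped/biphasic" description, not a published rule. Over the
increasing-amplitude ladder (control excluded) with significance at
`p_adj < α` (α = 0.05): no significant rung → `flat`; a contiguous
significant run at *each* ladder end, same response direction, with a
fully non-significant interior → `biphasic-U` (up) or
`biphasic-inverted` (down); otherwise ≥2 significant rungs with
Spearman |ρ| ≥ 0.8 between amplitude and fold → `monotonic-up/-down`;
anything else → `mixed`. Terminal *runs* (not single extreme rungs) are
used because a biphasic gene can respond at the two lowest amplitudes
and the highest one simultaneously. A single-peak responder (e.g. the
KRT79-like profile) is deliberately `mixed` under this rule. Both
thresholds are exposed as configuration.

## Synthetic-data generators

`gen_ct_table` draws `Ct_ref ~ N(baseline_ref, sd)` and
`Ct_target = baseline_target − log2(fold) + N(0, sd)` per
condition × replicate, with sd = 0.15 cycles by default (typical qPCR
replicate scatter) and n = 3 replicates over the seven-condition ladder
(sham, +10, 0, −10, −20, −30, −40 dBm). Shipped profiles encode the
study's verbal effect sizes as parameters — `kiaa_biphasic` (2.5-fold
at +10 dBm, 5-fold at −30 and −40 dBm, 1 elsewhere), `krt79_peak`
(10-fold at −10 dBm, 0.5-fold at 0 dBm) and `null_flat` — they are
paper-derived parameters, not measured data, and every unmentioned
condition sits at fold 1. The generator emulates replicate noise on
the cycle scale only: no primer-efficiency deviation from 2, no
technical-replicate structure, no batch drift, no outliers. Passing
recovery tests therefore shows the pipeline's correctness and noise
behavior under the stated model, not robustness to real-world qPCR
pathologies.

`gen_probe_ladder` inverts the dosimetry chain exactly and applies
optional Gaussian noise in dB (multiplicative in power, matching
instrument behavior) before the floor check. `gen_field_map` rescales a
lognormal texture affinely so the masked coefficient of variation hits
the target *exactly* (valid for small targets; it raises if the rescale
would go negative), builds x-dominant E components with exact pixelwise
cross-component ratios, and constructs `H = ẑ×E/(η·h_scale)`.
`gen_hood_schedule` is deterministic. Every generator is reproducible
per seed and exposes its embedded truth for scoring.

## Problem sizes and defaults

Default analyses use the 10-rung ladder, 60×60 mm field maps
(≈2100 masked pixels), 3600 s regulation runs at 0.5 s steps, 6000 s
identification traces, and 500 synthetic tables for the bias estimate —
sizes at which every stage's behavior is already asymptotic while the
full suite and the acceptance script run in seconds.

## Known limitations

* The chain uses a single calibrated antenna factor; no
  frequency-dependent interpolation.
* The regulation plant is a lumped FOPDT abstraction: no hydraulic
  modeling of the water loop, no spatial gradients, no firmware-level
  PWM switching.
* The expression pipeline starts at Ct values (no amplification-curve
  processing), assumes biological-replicate-level input, one reference
  gene, and efficiency-2 amplification.
* The field-validity figures of the physical box (7 %, 1.01,
  0.053/0.015) are reachable here only through constructed maps; they
  anchor the statistics' definitions and cannot substitute for a
  full-wave field computation.
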