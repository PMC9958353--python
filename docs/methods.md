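# Methods

## Scope and model

`dts4d` plans x-ray acquisition techniques for four-dimensional digital
tomosynthesis (4D-DTS) of the breathing lung. The input is a surrogate
breathing signal — an external chest-marker displacement standing in for
internal tissue motion — and the output is the time series of acquisition
parameters (projection-arc duration, frame rate, pulse duration, normalized
tube current) that bounds tissue travel to a capture distance D during each
sweep, plus a comparison of the residual motion a 4DCT gantry rotation would
incur. The package does not model image reconstruction, detector physics,
dose beyond mAs bookkeeping, or the surrogate-to-diaphragm correlation that a
clinical deployment would need: all its motion quantities are surrogate
motion, and users must map them to internal anatomy separately.

## Breathing models

**Lujan trajectory.** `z(t) = z0 − b·cos^{2n}(πt/τ − φ0)` with exhale
position z0 (default 0 mm), displacement b (mm), period τ (s), steepness
n (default 1) and starting phase φ0 (default 0). The range is exactly
[z0 − b, z0]; larger n flattens the exhale plateau and sharpens inhales.
Breathing rates in breaths/minute convert as τ = 60/bpm.

**Velocity conventions.** The literal derivative is
`(2nπb/τ)·cos^{2n−1}(x)·sin(x)`; for n = 1 its maximum is πb/τ at t = τ/4.
The package also ships a *replication* convention with exponent 2n+1,
`(2nπb/τ)·cos^{2n+1}(x)·sin(x)`, whose n = 1 maximum is (2πb/τ)·(3√3/16) at
t = τ/6. Published simulated velocity tables in this problem area are
consistent with the replication convention, not the literal derivative (for
b = 10 mm, τ = 5 s the literal maximum is 6.283 mm/s while the tabulated
value is 4.081 = (2πb/τ)·3√3/16); whether that reflects an unstated exponent
convention or a computational artifact cannot be settled from the text, so
both are first-class and `literal` is the default. The replication velocity
is the exact derivative of `A_rep(t) = z0 − (b·n/(n+1))·cos^{2n+2}(x)`
(equal to z0 − (b/2)cos⁴ at n = 1); sampling `A_rep` is the right input when
a windowed-average analysis should be consistent with replication-mode peak
speeds. Velocity maxima for n = 1 with zero phase use the closed forms above;
any other case falls back to a dense scan (step 10⁻⁴·τ) refined by bounded
scalar minimization, which agrees with the closed forms to 10⁻⁹ relative.

**Irregular generator.** Real free breathing is quasi-periodic. The
synthetic generator concatenates cos^{2n} arches whose per-cycle amplitude
and period are `mean·(1 + CV·ξ)` with ξ standard normal truncated at ±2
(truncation keeps pathological cycles out while leaving the mean amplitude
within sampling error of the target), then adds a linear baseline drift and
i.i.d. Gaussian noise, all from one seeded `numpy` generator so traces are
bit-reproducible. Defaults (10 mm amplitude, 15% amplitude CV, 4 s period,
10% period CV, 0.05 mm/s drift, 0.15 mm noise SD) describe a calm adult
free-breather. What the generator does *not* emulate: hysteresis between
inhale and exhale paths, apnea or cough events, slow amplitude trends beyond
a linear drift, and multi-dimensional marker motion — so passing tests bound
the pipeline's behavior on well-behaved quasi-periodic signals, not on every
clinical trace.

## Velocity estimation

The windowed average velocity sums N consecutive sample-to-sample slopes and
divides by N. On a uniform grid this telescopes to the endpoint slope
|A(t+N·dt) − A(t)|/(N·dt), which is what the implementation computes; a
direct-summation oracle in the tests confirms the identity to 10⁻¹² relative.
Defaults: N = 15, dt = 0.033 s, window 0.495 s. Choices made where the
design was open:

* **Rectification.** The windowed value is returned as a magnitude by
  default (configurable off): arc duration depends on speed, and inhalation
  and exhalation constrain imaging equally.
* **Alignment.** Window values are stamped at the window center. Extremes
  are alignment-invariant, so this only affects where flat/clamped segments
  appear on the time axis.
* **Edges.** Windows never extend past the data; the profile simply has N
  fewer points than the waveform.

### Sampling-grid sensitivity

The windowed maximum of a smooth trajectory is sensitive at the ~0.25% level
to where the sample grid happens to fall relative to the velocity peak.
Published average-velocity tables for the replication trajectory are
reproduced to their last printed digit on a 0.0333 s grid (a ~30 Hz surrogate
camera; window 0.4995 s), while the nominal 0.033 s grid lands ~0.25% high on
the fast-breathing corners. The package default stays at 0.033 s; the
table-reproduction tests sample at 0.0333 s and say so. One tabulated cell
(29.522 mm/s at 4 cm / 25 bpm) still reconstructs as 29.520 — the exact grid
behind the published digit is not recoverable — and is asserted with a
0.0025 mm/s band; every technique value chained from it matches to the
printed digit regardless.

## Technique chain

With capture distance D (default 1 mm), NP projections per arc (61), noise
scaling f (5; 2.5 as the low-dose option, 10 the clinical chest-DTS
reference), frame gap 0.01 ms and baseline mAs_AEC:

    mAs/projection = mAs_AEC · f / NP
    arc            = min(D / V, clamp)
    frame rate     = NP / arc
    pulse          = 1/frame rate − frame gap
    tube current   = (f / NP) / pulse        [per mAs_AEC]

No intermediate rounding anywhere; printed-table comparisons in the tests
round only at the final assert, half-away-from-zero, with ±1 unit in the
last printed digit of slack (published tables mix rounding and truncation,
e.g. a computed 2074.5 Hz printed as 2074).

* **Clamp.** The overlap limit that keeps successive phase arcs from
  colliding when breathing is slow is not published; the default clamp is
  0.495 s, one velocity-averaging window, so an arc never outlasts the
  velocity estimate that justified it. It is configurable. v = 0 maps to
  the clamp with the flag set.
* **Infeasibility.** A frame rate at or above 1/frame gap (100 kHz) leaves
  no pulse time. The single-point chain raises
  `InfeasibleTechniqueError`; plan derivation flags such points (NaN pulse
  and current) rather than aborting, and the CLI reports them.
* **Tube current normalization.** The published current quantity is mA per
  mAs_AEC; the chain computes f/(NP·pulse), which is independent of
  mAs_AEC. Absolute mA is that ratio times the configured mAs_AEC.
* **Extremes.** The chain is strictly monotone in speed while unclamped, so
  the four extremes (min arc, max frame, min pulse, max current) coincide at
  one instant; `technique_extremes` verifies this through the chain
  identities and refuses plans where it fails.

## Intraphase motion

For a CT gantry rotation δ (defaults 0.5 s and 0.28 s, both treated as full
rotations — no partial-scan geometry is modeled) the surrogate excursion is
estimated two ways: linearly, ΔS = V_max·δ, with V_max either the windowed
peak (measured traces) or the analytic instantaneous peak (models); and as
the displacement difference |z(t_max + δ/2) − z(t_max − δ/2)| on the literal
cos^{2n} trajectory, centered at the analytic t_max rather than a sampled
argmax (grid placement would otherwise perturb the result by ~1%). The
displacement difference is sub-linear in δ and is bounded by the path length
over the window; both bounds are property-tested. δ must be shorter than one
cycle. For measured waveforms only the linear method applies — a
displacement-difference variant for arbitrary traces would need a
peak-picking convention the model case does not define. Each report compares
the excursion against the DTS capture distance D and flags any δ whose
excursion exceeds it.

## Numerical and interface choices

* Canonical units are seconds and millimetres everywhere inside the package;
  cm (RPM convention) and ms are converted at the I/O boundary, once.
* Trace ingestion tolerates comma or whitespace delimiters, header lines and
  an ignored third (phase) column; non-uniform timestamps — real RPM exports
  drop frames — are linearly resampled onto the median interval and flagged
  in the provenance label rather than rejected. Strict non-monotonicity is
  an error.
* Waveform export carries 9 decimals so a write→read round trip is identical
  to < 10⁻⁶ mm in either unit.
* Simulated traces default to 60 s (a dozen breathing cycles, enough for the
  sliding window to see every grid alignment); CLI figures display the first
  20 s. Figures are inspection artifacts only — nothing reads pixels back.
* Tests use derandomized hypothesis profiles and fixed seeds throughout; the
  whole suite runs in a few seconds on one CPU.

## Known limitations

* Surrogate motion is treated as tissue motion; no diaphragm correlation.
* One published tube-current cell (10.0 s⁻¹ in the 1 cm / 12 bpm
  average-velocity row) is inconsistent with its own row's pulse duration
  (the chain gives 19.8 s⁻¹); the package reports the chain value and the
  tests exclude that cell from exact comparison. Two published 0.28 s
  displacement-difference cells (1.52, 6.07 mm) are reproduced to ~1% rather
  than the last digit, consistent with sampled-grid placement in the source
  computation.
* The velocity-window clamp value and the irregular-generator defaults are
  package choices where no published value exists; both are configurable.
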