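# dts4d — respiration-adapted technique planning for 4D lung tomosynthesis

Four-dimensional digital tomosynthesis (4D-DTS) images the breathing lung by
acquiring a sweep of NP projections per respiratory phase. The faster the
tissue moves, the shorter the sweep must be for each phase to stay sharp.
`dts4d` turns a surrogate breathing signal (a chest-marker trace such as a
Varian RPM export, or a simulated waveform) into the time-resolved x-ray
acquisition parameters that bound tissue travel per projection arc to a chosen
capture distance **D**, and quantifies the residual motion a conventional 4DCT
gantry rotation would incur over the same breathing. It is aimed at medical
physicists evaluating motion-adapted chest imaging protocols.

## The model

Breathing is either read from a trace or simulated with the Lujan model

    z(t) = z0 − b · cos^{2n}(πt/τ − φ0)

with displacement *b* (mm), period *τ* (s) and steepness *n*. The surrogate
speed is estimated with a sliding window that averages N = 15 consecutive
sample-to-sample slopes (for a uniform grid this telescopes to
|A(t+N·dt) − A(t)| / (N·dt)); with dt = 0.033 s the window spans 0.495 s.
The technique chain then reads, at each instant:

    arc duration    = min(D / V_average, clamp)        [s]
    frame rate      = NP / arc duration                [Hz]
    pulse duration  = 1/frame rate − frame gap         [s]
    tube current    = (f / NP) / pulse duration        [mA per mAs_AEC]

where f is the noise scaling factor (sweep mAs as a multiple of the
AEC-selected single-chest-exposure mAs) and the frame gap is the detector
dead time (0.01 ms, a 100 000 fps readout bound). The per-projection exposure
is mAs_AEC · f / NP. For the CT comparison, the intraphase excursion during a
gantry rotation δ is either ΔS = V_max · δ (linear) or the displacement
difference |z(t_max + δ/2) − z(t_max − δ/2)| centered at the velocity peak.

Two instantaneous-velocity conventions are provided (`VelocityMode`): the
`literal` derivative of z(t), whose n = 1 maximum is πb/τ at t = τ/4, and a
`replication` convention with exponent 2n+1, whose n = 1 maximum is
(2πb/τ)·(3√3/16) at t = τ/6 — the convention behind the published simulated
velocity tables in this problem area. `docs/methods.md` discusses the
difference and every other numerical choice.

## Worked example

The most demanding condition of the default sweep grid — 4 cm breathing
displacement at 25 breaths/min (τ = 2.4 s):

```python
from dts4d import (LujanParams, VelocityMode, TechniqueConfig,
                   max_instantaneous_velocity, technique_from_velocity,
                   intraphase_range_displacement)

params = LujanParams(b=40.0, tau=2.4)          # 4 cm breathing at 25 bpm
v, t = max_instantaneous_velocity(params, VelocityMode.REPLICATION)
print(f"peak surrogate speed : {v:.3f} mm/s at t = {t:.3f} s")
pt = technique_from_velocity(v, TechniqueConfig())
print(f"arc duration         : {pt.arc_duration_s*1e3:.1f} ms")
print(f"frame rate           : {pt.frame_rate_hz:.1f} Hz")
print(f"pulse duration       : {pt.pulse_duration_s*1e3:.3f} ms")
print(f"tube current         : {pt.tube_current_ratio:.1f} mA per mAs_AEC")
ds = intraphase_range_displacement(params, 0.5, VelocityMode.REPLICATION)
print(f"CT 0.5 s excursion   : {ds:.2f} mm (vs 1 mm DTS capture limit)")
```

prints

```
peak surrogate speed : 34.009 mm/s at t = 0.400 s
arc duration         : 29.4 ms
frame rate           : 2074.5 Hz
pulse duration       : 0.472 ms
tube current         : 173.6 mA per mAs_AEC
CT 0.5 s excursion   : 21.09 mm (vs 1 mm DTS capture limit)
```

Reading: to keep tissue travel under 1 mm during a 61-projection sweep at the
fastest point of this breathing cycle, the system must sweep in 29.4 ms at
2075 frames per second with 0.47 ms pulses, at roughly 174 times the tube
current of a single AEC chest exposure (for f = 5). Meanwhile a 0.5 s CT
gantry rotation at the same point in the cycle lets the surrogate travel
21 mm — twenty times the DTS capture limit.

## Command line

```sh
dts4d simulate --b-mm 40 --bpm 25 --mode replication --duration-s 20 --out run/sim
dts4d derive   --trace run/sim/trace.csv --out run/derive      # plan.csv, extremes.json, 5-panel figure
dts4d sweep    --mode replication --velocity-method instantaneous --out run/sweep
dts4d compare-ct --mode replication --out run/ct               # per-δ CT-vs-D verdicts
```

Every command writes a `run.json` with the effective configuration, its hash
and library versions; `--config file.yaml` supplies flag defaults.

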