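"""Time-resolved 4D-DTS acquisition technique derivation.

Given a surrogate speed v(t), the technique chain bounds tissue travel per
projection arc to a capture distance D and budgets the x-ray exposure:

    arc duration   = min(D / v, clamp)           [s]
    frame rate     = NP / arc duration           [Hz]
    pulse duration = 1/frame rate - frame gap    [s]
    tube current   = (f / NP) / pulse duration   [per mAs_AEC, 1/s]

where NP is the number of projections per arc, f the noise scaling factor
(tomosynthesis mAs as a multiple of the AEC chest-radiograph mAs), and the
frame gap the detector dead time between consecutive frames.  The clamp on
arc duration prevents successive phase-sampling arcs from overlapping when
the surrogate is nearly still; clamped stretches appear as flat segments
in the technique plots.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import InfeasibleTechniqueError, InputError
from .lujan import LujanParams, VelocityMode, generate_lujan_waveform, max_instantaneous_velocity
from .velocity import VelocityEstimatorConfig, max_average_velocity, sliding_average_velocity
from .waveform import DEFAULT_SAMPLING_INTERVAL, RespiratoryWaveform


@dataclass(frozen=True)
class TechniqueConfig:
    """Acquisition technique knobs.

    Attributes
    ----------
    capture_distance_mm : float
        D, maximum tissue travel captured during one arc (default 1 mm).
    projections_per_arc : int
        NP, projections per tomosynthesis sweep (default 61).
    noise_scaling : float
        f, total sweep mAs as a multiple of mAs_AEC (default 5; 2.5 is the
        low-dose alternative, 10 the clinical chest-DTS reference).
    mAs_aec : float
        Baseline AEC-selected mAs of a single chest exposure. Default 1 so
        tube current is reported normalized (mA per mAs_AEC); set the real
        value to obtain absolute mA.
    frame_gap_s : float
        Detector dead time between frames (default 1e-5 s = 0.01 ms, the
        100 000 fps readout bound).
    max_arc_duration_s : float
        Arc-duration clamp preventing overlap of successive phase arcs
        (default 0.495 s, one velocity-averaging window).
    """

    capture_distance_mm: float = 1.0
    projections_per_arc: int = 61
    noise_scaling: float = 5.0
    mAs_aec: float = 1.0
    frame_gap_s: float = 1e-5
    max_arc_duration_s: float = 0.495

    def __post_init__(self) -> None:
        if self.capture_distance_mm <= 0:
            raise InputError("capture distance D must be positive")
        if self.projections_per_arc < 1:
            raise InputError("projections per arc must be >= 1")
        if self.noise_scaling <= 0:
            raise InputError("noise scaling factor f must be positive")
        if self.mAs_aec <= 0:
            raise InputError("mAs_AEC must be positive")
        if self.frame_gap_s < 0:
            raise InputError("frame gap must be >= 0")
        if self.max_arc_duration_s <= 0:
            raise InputError("max arc duration must be positive")


class TechniquePoint(NamedTuple):
    """Technique chain evaluated at one velocity sample."""

    arc_duration_s: float
    frame_rate_hz: float
    pulse_duration_s: float
    tube_current_ratio: float
    clamped: bool


@dataclass(frozen=True)
class TechniquePlan:
    """Technique chain evaluated along a velocity profile.

    ``infeasible`` marks points whose frame rate meets or exceeds
    1/frame_gap (no time left for the pulse); pulse and tube current are
    NaN there.
    """

    times: np.ndarray
    arc_duration_s: np.ndarray
    frame_rate_hz: np.ndarray
    pulse_duration_s: np.ndarray
    tube_current_ratio: np.ndarray
    clamped: np.ndarray
    infeasible: np.ndarray
    config: TechniqueConfig

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; pulse duration in ms for readability."""
        return pd.DataFrame(
            {
                "time_s": self.times,
                "arc_s": self.arc_duration_s,
                "frame_hz": self.frame_rate_hz,
                "pulse_ms": self.pulse_duration_s * 1e3,
                "tube_current_per_mAsAEC": self.tube_current_ratio,
                "clamped": self.clamped,
                "infeasible": self.infeasible,
            }
        )


@dataclass(frozen=True)
class TechniqueExtremes:
    """The most demanding operating point of a plan."""

    min_arc_duration_s: float
    max_frame_rate_hz: float
    min_pulse_duration_s: float
    max_tube_current_ratio: float

    def as_dict(self) -> dict:
        return {
            "min_arc_duration_s": self.min_arc_duration_s,
            "max_frame_rate_hz": self.max_frame_rate_hz,
            "min_pulse_duration_ms": self.min_pulse_duration_s * 1e3,
            "max_tube_current_per_mAsAEC": self.max_tube_current_ratio,
        }


def mAs_per_projection(config: TechniqueConfig) -> float:
    """Per-projection exposure: mAs_AEC * f / NP."""
    return config.mAs_aec * config.noise_scaling / config.projections_per_arc


def arc_duration_at(v: float, config: TechniqueConfig) -> tuple[float, bool]:
    """Arc duration min(D/v, clamp) for surrogate speed ``v`` (mm/s) with a clamped flag."""
    if v < 0:
        raise InputError("speed must be >= 0 (rectify signed velocities first)")
    clamp = config.max_arc_duration_s
    if v == 0:
        return clamp, True
    arc = config.capture_distance_mm / v
    if arc >= clamp:
        return clamp, True
    return arc, False


def technique_from_velocity(v: float, config: TechniqueConfig | None = None) -> TechniquePoint:
    """Full technique chain at a single surrogate speed, no intermediate rounding.

    Raises
    ------
    InfeasibleTechniqueError
        If the frame rate reaches 1/frame_gap, i.e. the pulse duration
        would be <= 0 (hardware readout limit exceeded).
    """
    config = config or TechniqueConfig()
    arc, clamped = arc_duration_at(v, config)
    frame = config.projections_per_arc / arc
    if config.frame_gap_s > 0 and frame >= 1.0 / config.frame_gap_s:
        raise InfeasibleTechniqueError(
            f"frame rate {frame:.0f} Hz >= readout limit {1.0 / config.frame_gap_s:.0f} Hz"
        )
    pulse = 1.0 / frame - config.frame_gap_s
    ratio = config.noise_scaling / (config.projections_per_arc * pulse)
    return TechniquePoint(arc, frame, pulse, ratio, clamped)


def derive_technique_plan(
    waveform: RespiratoryWaveform,
    est_config: VelocityEstimatorConfig | None = None,
    tech_config: TechniqueConfig | None = None,
) -> TechniquePlan:
    """Sliding-window velocity followed by the per-point technique chain.

    Infeasible points (frame rate at/over the readout limit) are flagged
    rather than fatal; their pulse and tube current are NaN.
    """
    est_config = est_config or VelocityEstimatorConfig()
    tech_config = tech_config or TechniqueConfig()
    profile = sliding_average_velocity(waveform, est_config)
    v = profile.values
    if not est_config.use_absolute:
        v = np.abs(v)

    D = tech_config.capture_distance_mm
    clamp = tech_config.max_arc_duration_s
    NP = tech_config.projections_per_arc
    gap = tech_config.frame_gap_s

    with np.errstate(divide="ignore"):
        raw_arc = np.where(v > 0, D / np.where(v > 0, v, 1.0), np.inf)
    clamped = raw_arc >= clamp
    arc = np.where(clamped, clamp, raw_arc)
    frame = NP / arc
    infeasible = (gap > 0) & (frame >= 1.0 / gap) if gap > 0 else np.zeros_like(clamped)
    pulse = 1.0 / frame - gap
    pulse = np.where(infeasible, np.nan, pulse)
    ratio = tech_config.noise_scaling / (NP * pulse)
    return TechniquePlan(
        times=profile.times,
        arc_duration_s=arc,
        frame_rate_hz=frame,
        pulse_duration_s=pulse,
        tube_current_ratio=ratio,
        clamped=clamped,
        infeasible=np.asarray(infeasible, dtype=bool),
        config=tech_config,
    )


def technique_extremes(plan: TechniquePlan) -> TechniqueExtremes:
    """Most demanding operating point: (min arc, max frame, min pulse, max current).

    The chain is monotone in velocity, so all four extremes occur at the
    same instant; this is verified through the chain identities and a
    mismatch raises ``InputError``.  Infeasible points are excluded.
    """
    ok = ~plan.infeasible
    if plan.times.size == 0 or not np.any(ok):
        raise InputError("plan has no feasible points")
    cfg = plan.config
    min_arc = float(np.min(plan.arc_duration_s[ok]))
    max_frame = float(np.max(plan.frame_rate_hz[ok]))
    min_pulse = float(np.min(plan.pulse_duration_s[ok]))
    max_ratio = float(np.max(plan.tube_current_ratio[ok]))
    NP = cfg.projections_per_arc
    checks = (
        abs(max_frame * min_arc - NP) <= 1e-9 * NP,
        abs(min_pulse - (1.0 / max_frame - cfg.frame_gap_s)) <= 1e-9 * max(min_pulse, 1e-12),
        abs(max_ratio * min_pulse - cfg.noise_scaling / NP) <= 1e-9 * cfg.noise_scaling / NP,
    )
    if not all(checks):
        raise InputError("plan extremes do not coincide at a single time point")
    return TechniqueExtremes(min_arc, max_frame, min_pulse, max_ratio)


def sweep_sinusoidal_extremes(
    displacements_mm: Sequence[float],
    rates_bpm: Sequence[float],
    mode: VelocityMode = VelocityMode.LITERAL,
    tech_config: TechniqueConfig | None = None,
    velocity_method: str = "average",
    est_config: VelocityEstimatorConfig | None = None,
    duration_s: float = 60.0,
    dt_s: float = DEFAULT_SAMPLING_INTERVAL,
) -> pd.DataFrame:
    """Technique extremes over a grid of simulated breathing conditions.

    One row per (displacement b, rate bpm) pair with tau = 60/bpm.  The
    peak surrogate speed is found either analytically
    (``velocity_method="instantaneous"``) or by sampling the model
    trajectory and applying the sliding-window estimator
    (``velocity_method="average"``); the technique chain is then evaluated
    at that peak.
    """
    if velocity_method not in ("average", "instantaneous"):
        raise InputError(f"unknown velocity method {velocity_method!r}")
    if len(displacements_mm) == 0 or len(rates_bpm) == 0:
        raise InputError("empty sweep grid")
    tech_config = tech_config or TechniqueConfig()
    est_config = est_config or VelocityEstimatorConfig()
    rows = []
    for b in displacements_mm:
        for bpm in rates_bpm:
            params = LujanParams(b=b, tau=60.0 / bpm)
            if velocity_method == "instantaneous":
                v_max, _ = max_instantaneous_velocity(params, mode)
            else:
                wf = generate_lujan_waveform(params, duration_s, dt=dt_s, mode=mode)
                v_max, _ = max_average_velocity(sliding_average_velocity(wf, est_config))
            pt = technique_from_velocity(v_max, tech_config)
            rows.append(
                {
                    "displacement_mm": b,
                    "rate_bpm": bpm,
                    "tau_s": params.tau,
                    "velocity_method": velocity_method,
                    "mode": VelocityMode(mode).value,
                    "v_max_mm_s": v_max,
                    "min_arc_s": pt.arc_duration_s,
                    "max_frame_hz": pt.frame_rate_hz,
                    "min_pulse_ms": pt.pulse_duration_s * 1e3,
                    "max_tube_current_per_mAsAEC": pt.tube_current_ratio,
                    "clamped": pt.clamped,
                }
            )
    return pd.DataFrame(rows)
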