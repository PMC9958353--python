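"""Intraphase residual motion: surrogate excursion during a CT gantry rotation.

A single-phase 4DCT reconstruction uses data acquired over one gantry
rotation (delta = 0.5 s for a full 360-degree rotation; 0.28 s for a fast
rotation), during which the surrogate keeps moving.  Two estimates of that
excursion are provided:

* linear:  Delta_S = v_max * delta, with v_max either the windowed average
  peak (measured waveforms) or the analytic instantaneous peak (models);
* displacement difference: |z(t_max + delta/2) - z(t_max - delta/2)| on the
  literal cos^2n trajectory, the window centered at the instantaneous
  velocity peak — sub-linear in delta because the speed falls off away
  from the peak.

Comparing these excursions with the 4D-DTS capture distance D (1 mm by
default) shows how much residual blur a CT phase carries that the
velocity-adapted DTS arc would not.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InputError
from .lujan import (
    LujanParams,
    VelocityMode,
    generate_lujan_waveform,
    lujan_displacement,
    max_instantaneous_velocity,
)
from .velocity import VelocityEstimatorConfig, max_average_velocity, sliding_average_velocity
from .waveform import DEFAULT_SAMPLING_INTERVAL, RespiratoryWaveform


@dataclass(frozen=True)
class GantryConfig:
    """CT gantry rotation periods to evaluate, seconds."""

    rotation_periods_s: tuple = (0.5, 0.28)

    def __post_init__(self) -> None:
        if len(self.rotation_periods_s) == 0 or any(p <= 0 for p in self.rotation_periods_s):
            raise InputError("gantry rotation periods must be positive")


@dataclass(frozen=True)
class IntraphaseMotionReport:
    """Excursion ranges for one velocity method.

    ``ranges`` maps each gantry period delta (s) to the excursion Delta_S
    (mm); ``exceeds_capture`` flags deltas whose excursion exceeds the DTS
    capture distance it was compared against (None when no comparison was
    requested).
    """

    method: str  # linear_average | linear_instantaneous | displacement_difference
    v_max_mm_s: float
    t_max_s: float
    ranges_mm: Mapping[float, float]
    capture_distance_mm: float | None = None
    exceeds_capture: Mapping[float, bool] | None = None
    label: str = ""


def intraphase_range_linear(v_max: float, delta: float) -> float:
    """Linear excursion Delta_S = v_max * delta (mm)."""
    if v_max < 0:
        raise InputError("v_max must be >= 0")
    if delta <= 0:
        raise InputError("gantry period delta must be positive")
    return v_max * delta


def intraphase_range_displacement(
    params: LujanParams, delta: float, mode: VelocityMode = VelocityMode.REPLICATION
) -> float:
    """Displacement-difference excursion over ``delta`` around the velocity peak.

    The trajectory is always the literal cos^2n displacement (full
    amplitude b); only the center time t_max depends on the velocity
    convention (tau/6 for replication with n = 1, tau/4 literal).
    """
    if delta <= 0:
        raise InputError("gantry period delta must be positive")
    if delta >= params.tau:
        raise InputError("gantry period exceeds a breathing cycle")
    _, t_max = max_instantaneous_velocity(params, mode)
    lo = lujan_displacement(params, t_max - delta / 2.0)
    hi = lujan_displacement(params, t_max + delta / 2.0)
    return float(abs(hi - lo))


def compare_ct_intraphase(
    source: RespiratoryWaveform | LujanParams,
    est_config: VelocityEstimatorConfig | None = None,
    gantry: GantryConfig | None = None,
    capture_distance_mm: float = 1.0,
    mode: VelocityMode = VelocityMode.REPLICATION,
    duration_s: float = 60.0,
    dt_s: float = DEFAULT_SAMPLING_INTERVAL,
) -> list[IntraphaseMotionReport]:
    """CT-rotation excursion report(s) with a verdict against the DTS capture limit.

    For a measured :class:`RespiratoryWaveform` only the linear method on
    the windowed average velocity applies.  For model
    :class:`LujanParams` three reports are produced: linear on the sampled
    average velocity, linear on the analytic instantaneous peak, and the
    displacement difference.  Each delta whose excursion exceeds
    ``capture_distance_mm`` is flagged.
    """
    est_config = est_config or VelocityEstimatorConfig()
    gantry = gantry or GantryConfig()
    if capture_distance_mm <= 0:
        raise InputError("capture distance must be positive")
    deltas = tuple(gantry.rotation_periods_s)
    reports: list[IntraphaseMotionReport] = []

    def finish(method, v_max, t_max, ranges, label):
        return IntraphaseMotionReport(
            method=method,
            v_max_mm_s=v_max,
            t_max_s=t_max,
            ranges_mm=dict(ranges),
            capture_distance_mm=capture_distance_mm,
            exceeds_capture={d: r > capture_distance_mm for d, r in ranges.items()},
            label=label,
        )

    if isinstance(source, RespiratoryWaveform):
        v_max, t_max = max_average_velocity(sliding_average_velocity(source, est_config))
        ranges = {d: intraphase_range_linear(v_max, d) for d in deltas}
        reports.append(finish("linear_average", v_max, t_max, ranges, source.source_label))
        return reports

    if not isinstance(source, LujanParams):
        raise InputError("source must be a RespiratoryWaveform or LujanParams")

    label = f"lujan(b={source.b}, tau={source.tau})"
    wf = generate_lujan_waveform(source, duration_s, dt=dt_s, mode=mode)
    v_avg, t_avg = max_average_velocity(sliding_average_velocity(wf, est_config))
    reports.append(
        finish(
            "linear_average",
            v_avg,
            t_avg,
            {d: intraphase_range_linear(v_avg, d) for d in deltas},
            label,
        )
    )
    v_inst, t_inst = max_instantaneous_velocity(source, mode)
    reports.append(
        finish(
            "linear_instantaneous",
            v_inst,
            t_inst,
            {d: intraphase_range_linear(v_inst, d) for d in deltas},
            label,
        )
    )
    reports.append(
        finish(
            "displacement_difference",
            v_inst,
            t_inst,
            {d: intraphase_range_displacement(source, d, mode) for d in deltas},
            label,
        )
    )
    return reports
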