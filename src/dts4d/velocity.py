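"""Sliding-window average surrogate velocity.

The estimator averages N consecutive sample-to-sample slopes,

    V_average = (1/N) * sum_i [A(t_i) - A(t_{i-1})] / (t_i - t_{i-1}),

which for a uniform grid telescopes to the endpoint slope
|A(t_N) - A(t_0)| / (N*dt).  With the defaults (N = 15, dt = 0.033 s) the
averaging window spans 0.495 s — about one tenth of a breathing cycle —
long enough to suppress marker jitter, short enough to track the
inhale/exhale speed swing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .waveform import DEFAULT_SAMPLING_INTERVAL, RespiratoryWaveform


@dataclass(frozen=True)
class VelocityEstimatorConfig:
    """Sliding-window configuration.

    Attributes
    ----------
    window_intervals : int
        N, the number of sampling intervals averaged per window (default 15).
    expected_sampling_interval : float
        Nominal dt in seconds used for documentation/sanity checks
        (default 0.033); the estimator always uses the waveform's actual grid.
    use_absolute : bool
        Rectify the windowed velocity (default True): inhalation and
        exhalation both constrain the imaging technique, so downstream
        consumers need a speed, not a signed velocity.
    """

    window_intervals: int = 15
    expected_sampling_interval: float = DEFAULT_SAMPLING_INTERVAL
    use_absolute: bool = True

    def __post_init__(self) -> None:
        if self.window_intervals < 1:
            raise InputError("window_intervals must be >= 1")
        if self.expected_sampling_interval <= 0:
            raise InputError("expected_sampling_interval must be positive")


@dataclass(frozen=True)
class VelocityProfile:
    """Windowed average velocity time series.

    ``times`` are window centers (s); ``values`` are mm/s;
    ``window_span`` is N*dt (s).  The profile has N fewer points than the
    waveform it came from: windows never extend past the data.
    """

    times: np.ndarray
    values: np.ndarray
    window_span: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size or t.size == 0:
            raise InputError("profile times/values must be non-empty and equal length")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def sliding_average_velocity(
    waveform: RespiratoryWaveform,
    config: VelocityEstimatorConfig | None = None,
) -> VelocityProfile:
    """Windowed average velocity of a waveform.

    For a uniform grid the N-slope mean telescopes, so each window value is
    ``(A[k+N] - A[k]) / (N*dt)`` (rectified if configured), stamped at the
    window center ``(t[k] + t[k+N]) / 2``.
    """
    config = config or VelocityEstimatorConfig()
    N = config.window_intervals
    if waveform.n_samples <= N:
        raise InputError(
            f"waveform has {waveform.n_samples} samples; needs more than {N} for the window"
        )
    dt = waveform.sampling_interval
    if abs(dt - config.expected_sampling_interval) > 0.01 * config.expected_sampling_interval:
        warnings.warn(
            f"waveform sampling interval {dt:.4g} s differs from the expected "
            f"{config.expected_sampling_interval:.4g} s",
            stacklevel=2,
        )
    d = waveform.displacements
    t = waveform.times
    span = N * dt
    values = (d[N:] - d[:-N]) / span
    if config.use_absolute:
        values = np.abs(values)
    centers = (t[N:] + t[:-N]) / 2.0
    return VelocityProfile(times=centers, values=values, window_span=span)


def max_average_velocity(profile: VelocityProfile) -> tuple[float, float]:
    """Largest windowed velocity and the earliest window center attaining it."""
    if profile.values.size == 0:
        raise InputError("empty velocity profile")
    k = int(np.argmax(profile.values))  # argmax returns the first maximum
    return float(profile.values[k]), float(profile.times[k])


def write_velocity_profile(profile: VelocityProfile, path) -> None:
    """Export as CSV with header ``time_s,velocity_mm_per_s``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time_s,velocity_mm_per_s\n")
        for t, v in zip(profile.times, profile.values):
            fh.write(f"{t:.9f},{v:.9f}\n")
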