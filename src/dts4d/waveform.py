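"""Surrogate respiratory waveforms: container, text I/O, synthetic generation.

A surrogate waveform is an externally measured breathing signal (e.g. the
displacement of a chest marker tracked by the Varian RPM camera) standing in
for internal tissue motion.  All waveforms are held in canonical units —
seconds and millimetres — on a strictly uniform time grid, because the
downstream velocity estimator telescopes over a fixed number of equal
sampling intervals.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

#: Default surrogate sampling interval in seconds (~30 Hz camera).
DEFAULT_SAMPLING_INTERVAL = 0.033

#: Maximum permitted deviation from uniform time spacing, in seconds.
UNIFORM_SPACING_TOL = 1e-9


@dataclass(frozen=True)
class RespiratoryWaveform:
    """A uniformly sampled surrogate displacement time series.

    Parameters
    ----------
    times : ndarray
        Sample times in seconds, strictly increasing, uniformly spaced to
        within ``UNIFORM_SPACING_TOL``.
    displacements : ndarray
        Surrogate displacement in millimetres, same length as ``times``.
    source_label : str
        Free-text provenance tag (e.g. ``"lujan"``, ``"volunteer-sim"``).
    """

    times: np.ndarray
    displacements: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.displacements, dtype=float)
        if t.ndim != 1 or d.ndim != 1 or t.size != d.size:
            raise InputError("times and displacements must be 1-D and equal length")
        if t.size < 2:
            raise InputError("waveform needs at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise InputError("times must be strictly increasing")
        if np.max(dt) - np.min(dt) > UNIFORM_SPACING_TOL:
            raise InputError(
                "non-uniform time spacing (spread "
                f"{np.max(dt) - np.min(dt):.3g} s); resample first"
            )
        if not np.all(np.isfinite(d)):
            raise InputError("displacements must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "displacements", d)

    @property
    def sampling_interval(self) -> float:
        """Time between consecutive samples, seconds."""
        return float((self.times[-1] - self.times[0]) / (self.times.size - 1))

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Span from first to last sample, seconds."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class IrregularWaveformSpec:
    """Parameters of the quasi-periodic synthetic breathing generator.

    Emulates a free-breathing RPM trace: a train of cos^2n arches whose
    per-cycle amplitude and period are drawn from truncated normal
    distributions, with a slow linear baseline drift and additive
    measurement noise.

    Parameters
    ----------
    mean_displacement : float
        Mean peak-to-trough cycle amplitude, mm.
    displacement_cv : float
        Cycle-to-cycle amplitude coefficient of variation (fraction).
    mean_period : float
        Mean breathing period, s.
    period_cv : float
        Cycle-to-cycle period coefficient of variation (fraction).
    baseline_drift_rate : float
        Linear baseline drift, mm/s.
    noise_sd : float
        Standard deviation of additive i.i.d. Gaussian noise, mm.
    steepness_n : int
        Lujan steepness exponent of each arch (cos^{2n}).
    duration : float
        Total trace duration, s.
    seed : int
        PRNG seed; same seed reproduces the trace bit-for-bit.
    """

    mean_displacement: float = 10.0
    displacement_cv: float = 0.15
    mean_period: float = 4.0
    period_cv: float = 0.10
    baseline_drift_rate: float = 0.05
    noise_sd: float = 0.15
    steepness_n: int = 1
    duration: float = 60.0
    seed: int = 0
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.mean_period <= 0:
            raise InputError("duration and mean_period must be positive")
        if min(self.displacement_cv, self.period_cv, self.noise_sd) < 0:
            raise InputError("dispersion parameters must be >= 0")
        if self.mean_displacement < 0:
            raise InputError("mean_displacement must be >= 0")
        if self.steepness_n < 1:
            raise InputError("steepness_n must be a positive integer")
        if self.sampling_interval <= 0:
            raise InputError("sampling_interval must be positive")


def _parse_two_columns(text: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract the first two numeric columns, skipping header/comment lines."""
    times, disps = [], []
    for line in text.splitlines():
        tokens = line.replace(",", " ").split()
        if len(tokens) < 2:
            continue
        try:
            t = float(tokens[0])
            d = float(tokens[1])
        except ValueError:
            continue  # header or annotation line
        times.append(t)
        disps.append(d)
    return np.asarray(times), np.asarray(disps)


def read_surrogate_trace(
    path,
    displacement_unit: str = "cm",
    time_unit: str = "s",
) -> RespiratoryWaveform:
    """Read a delimited two-column (time, displacement) trace.

    Comma- or whitespace-delimited; lines whose first two tokens are not
    numeric (headers, comments) are skipped.  A third phase/gating column,
    if present, is ignored.  Displacement is converted to mm and time to
    seconds.  Non-uniform time stamps (dropped frames) are linearly
    resampled onto a uniform grid at the median interval and the result is
    flagged in ``source_label``.

    Parameters
    ----------
    path : str or Path
        Trace file location.
    displacement_unit : {"cm", "mm"}
        Unit of the displacement column. RPM exports use cm.
    time_unit : {"s", "ms"}
        Unit of the time column.
    """
    if displacement_unit not in ("cm", "mm"):
        raise InputError(f"unknown displacement unit {displacement_unit!r}")
    if time_unit not in ("s", "ms"):
        raise InputError(f"unknown time unit {time_unit!r}")
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    except OSError as exc:
        raise InputError(f"cannot read trace file {path}: {exc}") from exc

    t, d = _parse_two_columns(text)
    if t.size < 2:
        raise InputError(f"trace {path} has fewer than 2 numeric samples")
    if np.any(np.diff(t) <= 0):
        raise InputError(f"trace {path} has non-monotone time stamps")

    if time_unit == "ms":
        t = t / 1000.0
    if displacement_unit == "cm":
        d = d * 10.0

    label = str(path)
    dt = np.diff(t)
    if np.max(dt) - np.min(dt) > UNIFORM_SPACING_TOL:
        step = float(np.median(dt))
        n = int(np.floor((t[-1] - t[0]) / step)) + 1
        grid = t[0] + np.arange(n) * step
        d = np.interp(grid, t, d)
        t = grid
        label += " (resampled)"
    return RespiratoryWaveform(times=t, displacements=d, source_label=label)


def write_waveform(waveform: RespiratoryWaveform, path, displacement_unit: str = "mm") -> None:
    """Write a waveform as CSV with header ``time_s,displacement_<unit>``.

    Values carry 9 decimal places so that a write/read round trip
    reproduces the waveform to well under 1e-6 mm.
    """
    if displacement_unit not in ("cm", "mm"):
        raise InputError(f"unknown displacement unit {displacement_unit!r}")
    scale = 0.1 if displacement_unit == "cm" else 1.0
    buf = io.StringIO()
    buf.write(f"time_s,displacement_{displacement_unit}\n")
    for t, d in zip(waveform.times, waveform.displacements):
        buf.write(f"{t:.9f},{d * scale:.9f}\n")
    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())
    except OSError as exc:
        raise IOError(f"cannot write trace file {path}: {exc}") from exc


def generate_irregular_waveform(spec: IrregularWaveformSpec) -> RespiratoryWaveform:
    """Generate a quasi-periodic breathing trace from an :class:`IrregularWaveformSpec`.

    Each breathing cycle is a ``-amp * cos^{2n}(pi*s/period)`` arch (inhale
    at the cycle boundaries, exhale plateau in the middle, matching the
    Lujan convention with zero starting phase).  Per-cycle amplitude and
    period are ``mean * (1 + cv * xi)`` with ``xi`` a standard normal draw
    truncated at +/-2; a linear baseline drift and white Gaussian noise are
    added on top.  Deterministic for a fixed seed.
    """
    if spec.duration < spec.mean_period:
        raise InputError("duration must cover at least one mean breathing period")
    rng = np.random.default_rng(spec.seed)

    # Draw cycles until they cover the trace; the last one may be truncated.
    starts = [0.0]
    amps, periods = [], []
    while starts[-1] < spec.duration:
        xi_a = float(np.clip(rng.standard_normal(), -2.0, 2.0))
        xi_p = float(np.clip(rng.standard_normal(), -2.0, 2.0))
        amp = max(spec.mean_displacement * (1.0 + spec.displacement_cv * xi_a), 0.0)
        # keep the period away from zero even for extreme CVs
        period = max(spec.mean_period * (1.0 + spec.period_cv * xi_p), 0.2 * spec.mean_period)
        amps.append(amp)
        periods.append(period)
        starts.append(starts[-1] + period)
    starts_arr = np.asarray(starts)
    amps_arr = np.asarray(amps)
    periods_arr = np.asarray(periods)

    dt = spec.sampling_interval
    n = int(np.floor(spec.duration / dt)) + 1
    t = np.arange(n) * dt
    idx = np.clip(np.searchsorted(starts_arr, t, side="right") - 1, 0, len(amps) - 1)
    s = t - starts_arr[idx]
    arch = -amps_arr[idx] * np.cos(np.pi * s / periods_arr[idx]) ** (2 * spec.steepness_n)
    d = arch + spec.baseline_drift_rate * t
    if spec.noise_sd > 0:
        d = d + rng.normal(0.0, spec.noise_sd, size=n)
    return RespiratoryWaveform(times=t, displacements=d, source_label=f"irregular(seed={spec.seed})")
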