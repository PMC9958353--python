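"""Figure generation for technique plans and parameter sweeps.

Figures are human-inspection artifacts; nothing downstream reads them.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .technique import TechniquePlan
from .waveform import RespiratoryWaveform

#: Default display window, seconds.
DISPLAY_WINDOW_S = 20.0


def plot_technique_plan(
    waveform: RespiratoryWaveform,
    plan: TechniquePlan,
    path,
    window_s: float = DISPLAY_WINDOW_S,
) -> None:
    """Five stacked panels: displacement (cm), arc (s), frame (Hz), pulse (ms), current."""
    fig, axes = plt.subplots(5, 1, figsize=(8, 10), sharex=True)
    tmax = min(window_s, waveform.duration)

    wmask = waveform.times <= tmax
    axes[0].plot(waveform.times[wmask], waveform.displacements[wmask] / 10.0, lw=0.8)
    axes[0].set_ylabel("displacement (cm)")

    pmask = plan.times <= tmax
    panels = [
        (plan.arc_duration_s, "arc duration (s)"),
        (plan.frame_rate_hz, "frame rate (Hz)"),
        (plan.pulse_duration_s * 1e3, "pulse duration (ms)"),
        (plan.tube_current_ratio, "tube current\n(mA / mAs$_{AEC}$)"),
    ]
    for ax, (series, label) in zip(axes[1:], panels):
        ax.plot(plan.times[pmask], np.asarray(series)[pmask], lw=0.8)
        ax.set_ylabel(label)
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sweep(table: pd.DataFrame, path) -> None:
    """Four panels of technique extremes vs displacement, one line per breathing rate."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    panels = [
        ("min_arc_s", "minimum arc duration (s)"),
        ("max_frame_hz", "maximum frame rate (Hz)"),
        ("min_pulse_ms", "minimum pulse duration (ms)"),
        ("max_tube_current_per_mAsAEC", "maximum tube current (mA / mAs$_{AEC}$)"),
    ]
    for ax, (col, label) in zip(axes.ravel(), panels):
        for bpm, grp in table.groupby("rate_bpm"):
            grp = grp.sort_values("displacement_mm")
            ax.plot(grp["displacement_mm"], grp[col], marker="o", label=f"{bpm:g} bpm")
        ax.set_xlabel("breathing displacement (mm)")
        ax.set_ylabel(label)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
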