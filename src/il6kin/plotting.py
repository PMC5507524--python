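"""Shape-level trajectory plots (oxygen-uptake and plasma IL-6 panels)."""

from __future__ import annotations

from pathlib import Path

from .estimate import ObservationSeries
from .simulate import Trajectory


def plot_trajectory(
    traj: Trajectory,
    path: str | Path,
    series: ObservationSeries | None = None,
) -> None:
    """Two stacked panels: PVO2max(t) and plasma IL-6(t), optional data dots."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_v, ax_c) = plt.subplots(2, 1, sharex=True, figsize=(7, 6))
    ax_v.plot(traj.times, traj.pvo2max, color="tab:blue")
    ax_v.set_ylabel("PVO2max (% VO2max)")
    ax_c.plot(traj.times, traj.il6_plasma, color="tab:red", label="model")
    if series is not None:
        ax_c.plot(series.times, series.il6_values, "ko", ms=4, label="observed")
        ax_c.legend()
    ax_c.set_ylabel("plasma IL-6 (pg/ml)")
    ax_c.set_xlabel("time (min)")
    for ax in (ax_v, ax_c):
        ax.axvspan(
            traj.protocol.t_ex_start, traj.protocol.t_ex_end,
            color="0.9", zorder=0,
        )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
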