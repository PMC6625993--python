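"""Matplotlib panels mirroring the realized-vs-theory and error comparisons."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .metrics import ErrorReport  # noqa: E402
from .simulate import SimulationResult  # noqa: E402

__all__ = ["plot_trajectory", "plot_comparison"]

_VARIANT_COLORS = {
    "uncorrected": "tab:red",
    "volume_only": "tab:blue",
    "full_correction": "black",
    "setup1_equal_rate": "magenta",
}


def plot_trajectory(result: SimulationResult, path: str | Path) -> Path:
    """Realized concentration and flask volume over time."""
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(6, 6))
    ax1.plot(result.times, result.concentrations, "k.-", label="realized")
    if result.theory is not None:
        ax1.plot(result.times, result.theory, "c--", label="theory")
    ax1.set_ylabel("concentration (M)")
    ax1.legend(frameon=False)
    ax2.plot(result.times, result.volumes, "b.-")
    ax2.set_ylabel("flask volume (mL)")
    ax2.set_xlabel("time (min)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_comparison(reports: dict[str, ErrorReport], path: str | Path) -> Path:
    """Percent error over time for each correction variant."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for variant, rep in reports.items():
        ax.plot(
            rep.times,
            rep.per_time_error,
            ".-",
            color=_VARIANT_COLORS.get(variant, None),
            label=variant,
        )
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("error (% of final target)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
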