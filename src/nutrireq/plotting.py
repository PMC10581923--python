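"""Dose-response figures with annotated breakpoints."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .dose_response import DoseResponseFit, eval_model

__all__ = ["plot_dose_response"]


def plot_dose_response(
    fit: DoseResponseFit,
    data: Sequence[tuple[float, float]],
    path: str | Path,
    response_name: str = "response",
    dose_name: str = "dose",
) -> Path:
    """Scatter the observations, draw the fitted curve, and mark the
    breakpoint with an annotated vertical line."""
    arr = np.asarray(data, dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    grid = np.linspace(x.min(), x.max(), 400)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, color="black", s=18, zorder=3, label="observed")
    if fit.params is not None:
        ax.plot(grid, eval_model(fit.params, grid), color="tab:green",
                label=f"{fit.family} (R²={fit.r2:.2f})")
    if fit.inflection_in_range:
        ax.axvline(fit.inflection, color="tab:green", linestyle="--", lw=1)
        ax.annotate(
            f"{fit.inflection:.1f}",
            xy=(fit.inflection, ax.get_ylim()[1]),
            xytext=(3, -12),
            textcoords="offset points",
            color="tab:green",
        )
    ax.set_xlabel(dose_name)
    ax.set_ylabel(response_name)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
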