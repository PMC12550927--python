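"""Optional diagnostic plots (Levey-Jennings chart, linearity scatter)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .validation import LinearityResult  # noqa: E402


def levey_jennings_plot(
    qc_values: Sequence[float], mean: float, sd: float, path: str | Path
) -> None:
    x = np.arange(1, len(qc_values) + 1)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(x, qc_values, "o-", ms=4)
    for k, style in ((0, "-"), (1, "--"), (2, ":"), (3, ":")):
        for sign in (1, -1) if k else (1,):
            ax.axhline(mean + sign * k * sd, color="grey", ls=style, lw=0.8)
    ax.set_xlabel("run")
    ax.set_ylabel("control value")
    ax.set_title("Levey-Jennings chart (mean ± 2SD acceptance)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def linearity_plot(
    expected: Sequence[float],
    measured: Sequence[float],
    fit: LinearityResult,
    path: str | Path,
) -> None:
    x = np.asarray(expected, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(x, measured, "o", ms=4, alpha=0.7)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, "-", color="crimson", lw=1)
    ax.set_xlabel("expected (copies/µL blood)")
    ax.set_ylabel("measured (copies/µL blood)")
    ax.set_title(f"linearity: R² = {fit.r_squared:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
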