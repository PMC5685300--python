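"""Diagnostic plots: calibration scatter and the depth x SNP accuracy grid."""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .evaluation import GridCell, grid_to_dataframe
from .model import CalibrationResults, TrainingSample


def plot_calibration(
    results: CalibrationResults,
    samples: Sequence[TrainingSample],
    ax=None,
):
    """Scatter of gold-standard F against X with the fitted line overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.array([s.x_pct for s in samples])
    f = np.array([s.f_actual_pct for s in samples])
    ax.scatter(x, f, s=18, color="tab:blue", label="samples")
    xs = np.linspace(0, max(x.max(), 1e-9), 50)
    ax.plot(
        xs,
        results.slope * xs + results.intercept,
        color="tab:red",
        label=f"F = {results.slope:.1f} X {results.intercept:+.1f}",
    )
    ax.set_xlabel("non-maternal allele fraction X (%)")
    ax.set_ylabel("actual fetal DNA fraction F (%)")
    ax.legend()
    return ax


def plot_grid_heatmap(cells: Iterable[GridCell], ax=None):
    """Heat map of 95%-CI half-widths over the read-count x SNP-count grid."""
    import matplotlib.pyplot as plt

    df = grid_to_dataframe(cells)
    pivot = df.pivot(index="n_reads", columns="n_snps", values="ci_half_width")
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis_r", origin="lower")
    ax.set_xticks(range(len(pivot.columns)), [f"{c/1000:g}K" for c in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{r/1e6:g}M" for r in pivot.index])
    ax.set_xlabel("number of SNPs")
    ax.set_ylabel("read pairs")
    for i in range(pivot.shape[0]):
        for j in range(pivot.shape[1]):
            v = pivot.iat[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center", color="white")
    ax.figure.colorbar(im, ax=ax, label="95% CI half-width (%)")
    return ax
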