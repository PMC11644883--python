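"""Correlation and Bland-Altman figures for paired device comparisons."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .agreement import PairedMeasurements, bland_altman, pearson_r2

__all__ = ["plot_correlation", "plot_bland_altman", "save_agreement_figures"]


def plot_correlation(pairs: PairedMeasurements, ax: plt.Axes | None = None) -> plt.Axes:
    """Scatter of watch vs reference values with the identity line and the
    Pearson R^2 / p annotation."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    a, b = pairs.value_a, pairs.value_b
    ax.scatter(a, b, s=18, alpha=0.8)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8, label="identity")
    try:
        r2, p = pearson_r2(pairs)
        ax.set_title(f"{pairs.parameter_name}  $R^2$={r2:.2f}, p={p:.2g}")
    except ValueError:
        ax.set_title(pairs.parameter_name)
    ax.set_xlabel(f"reference {pairs.units}".strip())
    ax.set_ylabel(f"watch {pairs.units}".strip())
    return ax


def plot_bland_altman(pairs: PairedMeasurements, ax: plt.Axes | None = None) -> plt.Axes:
    """Difference (watch - reference) against the pair mean, with the mean
    difference (solid) and 95% limits of agreement (dashed)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    mean_pair = (pairs.value_a + pairs.value_b) / 2.0
    d = pairs.differences
    md, lo, hi = bland_altman(pairs)
    ax.scatter(mean_pair, d, s=18, alpha=0.8)
    ax.axhline(md, color="k", lw=1.0)
    for y in (lo, hi):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_title(f"{pairs.parameter_name}  diff {md:.2f} [{lo:.2f}, {hi:.2f}]")
    ax.set_xlabel(f"mean of devices {pairs.units}".strip())
    ax.set_ylabel(f"watch - reference {pairs.units}".strip())
    return ax


def save_agreement_figures(pairs_list: list[PairedMeasurements], outdir, stem: str,
                           fmt: str = "png", dpi: int = 120) -> list[str]:
    """One correlation and one Bland-Altman panel grid; returns file paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for kind, fn in (("correlation", plot_correlation),
                     ("bland_altman", plot_bland_altman)):
        k = len(pairs_list)
        ncol = min(3, k)
        nrow = int(np.ceil(k / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.5 * nrow),
                                 squeeze=False)
        for ax in axes.flat[k:]:
            ax.set_visible(False)
        for pairs, ax in zip(pairs_list, axes.flat):
            fn(pairs, ax=ax)
        fig.tight_layout()
        path = outdir / f"{stem}_{kind}.{fmt}"
        fig.savefig(path, dpi=dpi)
        plt.close(fig)
        paths.append(str(path))
    return paths
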