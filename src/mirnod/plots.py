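"""Optional figure artifacts: NOD boxplots, ROC panels, enrichment bars."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .enrichment import EnrichmentResult  # noqa: E402
from .roc import ROCResult  # noqa: E402

__all__ = ["nod_comparison_boxplot", "roc_panels", "enrichment_bars"]


def nod_comparison_boxplot(
    group_nods: Sequence[float],
    population_nods: Sequence[float],
    path: str | Path,
) -> Path:
    """Boxplot comparing candidate/biomarker NODs with the population."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.boxplot([list(group_nods), list(population_nods)],
               tick_labels=["biomarkers", "all miRNAs"])
    ax.set_ylabel("NOD (exclusive targets)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def roc_panels(rocs: Sequence[ROCResult], path: str | Path) -> Path:
    """One ROC panel per miRNA (false positive rate vs true positive rate)."""
    n = len(rocs)
    ncol = min(5, max(n, 1))
    nrow = math.ceil(n / ncol) if n else 1
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.6 * ncol, 2.6 * nrow),
                             squeeze=False)
    for ax in axes.flat:
        ax.set_axis_off()
    for ax, roc in zip(axes.flat, rocs):
        ax.set_axis_on()
        xs = [p[0] for p in roc.curve_points]
        ys = [p[1] for p in roc.curve_points]
        ax.plot(xs, ys, drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", lw=0.6, color="grey")
        ax.set_title(f"{roc.mirna_id}\nAUC={roc.auc:.2f}", fontsize=8)
        ax.set_xlim(-0.02, 1.02)
        ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def enrichment_bars(results: Sequence[EnrichmentResult], path: str | Path) -> Path:
    """Horizontal −log10 P bars for the top enriched sets."""
    fig, ax = plt.subplots(figsize=(6, 0.4 * max(len(results), 1) + 1.2))
    names = [r.set_id for r in results][::-1]
    vals = [-math.log10(max(r.p_value, 1e-300)) for r in results][::-1]
    ax.barh(names, vals)
    ax.set_xlabel("-log10 P")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
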