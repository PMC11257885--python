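"""Figure rendering for verification and dose-matching outputs."""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dose_matching import ExposureDistribution, REFERENCE_BIN
from .verification import FoldRatioReport, VPCResult

__all__ = ["plot_vpc", "plot_fold_ratios", "plot_exposure_boxes"]


def plot_vpc(result: VPCResult, path: str | Path, title: str = "") -> Path:
    """Mean + 5th-95th percentile envelope with observed points and LLOQ."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(
        result.times_h,
        result.predicted_p5,
        result.predicted_p95,
        alpha=0.3,
        color="tab:blue",
        label="predicted 5th-95th pct",
    )
    ax.plot(result.times_h, result.predicted_mean, color="tab:blue", label="predicted mean")
    quant = result.observed[~result.observed["below_lloq"]]
    ax.plot(
        quant["time_h"], quant["conc_mg_L"], "o", mfc="none", color="k",
        label="observed",
    )
    if result.lloq_mg_L > 0:
        ax.axhline(result.lloq_mg_L, ls="--", color="gray", label="LLOQ")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma concentration (mg/L)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_fold_ratios(report: FoldRatioReport, path: str | Path) -> Path:
    """Predicted-to-observed ratios per metric with fold-range guides."""
    fig, ax = plt.subplots(figsize=(6, 4))
    table = report.table
    metrics = list(dict.fromkeys(table["metric"]))
    for i, m in enumerate(metrics):
        sub = table[table["metric"] == m]
        ax.plot([i] * len(sub), sub["ratio"], "o", mfc="none", color="k")
    ax.axhspan(1 / 1.25, 1.25, color="0.85", label="1.25-fold")
    for lim, style in ((1.5, "--"), (2.0, "-")):
        ax.axhline(lim, ls=style, color="k", lw=0.8)
        ax.axhline(1 / lim, ls=style, color="k", lw=0.8)
    ax.axhline(1.0, color="0.5", lw=0.8)
    ax.set_yscale("log")
    ax.set_xticks(range(len(metrics)), metrics, rotation=30)
    ax.set_ylabel("predicted / observed")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_exposure_boxes(
    exposures: Mapping[str, ExposureDistribution] | ExposureDistribution,
    path: str | Path,
    reference_bin: str = REFERENCE_BIN,
) -> Path:
    """AUC0-48 box summaries per age bin, one panel per scenario.

    The shaded band marks the reference bin's interquartile range, the
    target that the matched doses aim for.
    """
    if isinstance(exposures, ExposureDistribution):
        exposures = {exposures.scenario_ref: exposures}
    n = len(exposures)
    fig, axes = plt.subplots(1, n, figsize=(5 * n, 4), squeeze=False)
    for ax, (name, dist) in zip(axes[0], exposures.items()):
        labels = [b.name for b in dist.bins]
        data = [np.asarray(dist.aucs[lab]) for lab in labels]
        if reference_bin in dist.aucs:
            ref = np.asarray(dist.aucs[reference_bin])
            ax.axhspan(
                np.percentile(ref, 25), np.percentile(ref, 75),
                color="0.8", zorder=0,
            )
        ax.boxplot(data, whis=(0, 100), tick_labels=labels)
        ax.set_title(f"{name} ({dist.dose_mg_kg:g} mg/kg)")
        ax.set_ylabel("AUC0-48 (mg*h/L)")
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
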