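"""Matplotlib figures for maps, selection frequencies and validation."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .mapping import CurrentMap, FieldMap
from .model import SelectionResult, ValidationReport


def plot_field_map(fm: FieldMap, ax=None):
    """Heat map of the interpolated normal field (pT)."""
    if ax is None:
        _, ax = plt.subplots()
    im = ax.pcolormesh(fm.x, fm.y, fm.values, cmap="RdBu_r", shading="auto")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_aspect("equal")
    plt.colorbar(im, ax=ax, label="Bz (pT)")
    return ax


def plot_current_map(cm: CurrentMap, ax=None, step: int = 5):
    """Quiver plot of the pseudo-current vectors."""
    if ax is None:
        _, ax = plt.subplots()
    s = slice(None, None, step)
    ax.quiver(cm.x[s], cm.y[s], cm.cx[s, s], cm.cy[s, s], cm.magnitude[s, s],
              cmap="viridis")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_aspect("equal")
    return ax


def plot_selection_frequencies(sr: SelectionResult, top: int = 10, ax=None):
    """Horizontal bars of the most frequently selected features."""
    if ax is None:
        _, ax = plt.subplots()
    frame = sr.summary_frame().head(top).iloc[::-1]
    ax.barh(frame.index, frame["frequency"], color="steelblue")
    ax.axvline(0.7, color="firebrick", linestyle="--", label="70% threshold")
    ax.set_xlabel("selection frequency")
    ax.legend()
    return ax


def plot_roc(report: ValidationReport, ax=None):
    """Cross-validated ROC curve with bootstrap percentile band."""
    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(report.roc_fpr, report.roc_band_low, report.roc_band_high,
                    alpha=0.25, label="95% bootstrap band")
    ax.plot(report.roc_fpr, report.roc_tpr,
            label=f"AUC = {report.auc:.2f} "
                  f"({report.auc_ci[0]:.2f}-{report.auc_ci[1]:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax


def plot_calibration(report: ValidationReport, n_bins: int = 10, ax=None):
    """Decile calibration plot with the recalibration line."""
    from .model import calibration_bins

    if ax is None:
        _, ax = plt.subplots()
    bins = calibration_bins(report.labels, report.oof_probabilities, n_bins)
    ax.plot(bins["mean_predicted"], bins["observed_rate"], "o-",
            label="decile bins")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8, label="ideal")
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed rate")
    ax.set_title(f"intercept {report.calibration_intercept:+.3f}, "
                 f"slope {report.calibration_slope:.2f}")
    ax.legend()
    return ax


def plot_decision_curve(report: ValidationReport, ax=None):
    """Net benefit of the model vs treat-all / treat-none."""
    if ax is None:
        _, ax = plt.subplots()
    dca = report.dca
    ax.plot(dca["threshold"], dca["net_benefit"], label="model")
    ax.plot(dca["threshold"], dca["net_benefit_all"], label="treat all")
    ax.plot(dca["threshold"], dca["net_benefit_none"], label="treat none")
    ax.set_ylim(bottom=max(-0.05, float(dca["net_benefit_all"].min())))
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend()
    return ax


def plot_butterfly(beat, ax=None):
    """Butterfly diagram: all 36 channels of the averaged beat overlaid."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(beat.offsets_ms, beat.data.T, lw=0.6, alpha=0.7)
    ax.set_xlabel("time from R-peak (ms)")
    ax.set_ylabel("field (pT)")
    return ax


def save_all(figures: dict[str, plt.Axes], out_dir) -> None:
    """Save a name -> axes mapping as PNG files."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, ax in figures.items():
        ax.figure.savefig(out / f"{name}.png", dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
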