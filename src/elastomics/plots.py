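"""Minimal matplotlib renderings of the evaluation curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluation import CalibrationCurve, DecisionCurve, ROCCurve  # noqa: E402


def plot_roc(curves: dict[str, ROCCurve], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, c in curves.items():
        ax.plot(c.fpr, c.tpr, label=name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_calibration(curves: dict[str, CalibrationCurve], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, c in curves.items():
        ax.plot(c.mean_predicted, c.observed_fraction, "o-", label=name)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="ideal")
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed malignant fraction")
    ax.legend(loc="upper left")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_decision(curves: dict[str, DecisionCurve], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    first = next(iter(curves.values()))
    ax.plot(first.thresholds, first.treat_all, color="gray", lw=0.8,
            label="treat all")
    ax.plot(first.thresholds, first.treat_none, color="black", lw=0.8,
            label="treat none")
    for name, c in curves.items():
        ax.plot(c.thresholds, c.net_benefit, label=name)
    ax.set_ylim(bottom=-0.1)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.legend(loc="upper right")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
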