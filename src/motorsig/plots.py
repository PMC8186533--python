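"""Figure helpers: training curve, ROC, ablation curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ablation import AblationCurve  # noqa: E402
from .mlp import Metrics  # noqa: E402


def plot_training_trace(trace, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(range(1, len(trace) + 1), trace)
    ax.set_xlabel("epoch")
    ax.set_ylabel("mean test accuracy")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_roc(metrics: Metrics, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(metrics.roc_fpr, metrics.roc_tpr, marker=".")
    ax.plot([0, 1], [0, 1], ls="--", c="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {metrics.auc:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ablation_curve(curve: AblationCurve, path) -> None:
    df = curve.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4))
    for col in ("accuracy", "sensitivity", "specificity"):
        ax.plot(df["retained_count"], df[col], marker="o", label=col)
    ax.set_xlabel("kinematic features retained")
    ax.set_ylabel("metric")
    ax.invert_xaxis()
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
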