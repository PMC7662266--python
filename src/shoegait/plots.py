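"""Figure helpers: explained-variance, information-gain and sweep plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .reduction import PCAModel


def plot_explained_variance(model: PCAModel, path: str | Path,
                            threshold: float = 0.99) -> Path:
    """Individual and cumulative explained-variance curves with the
    component count chosen by the threshold rule marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    comps = np.arange(1, model.k_max + 1)
    ax.bar(comps, model.explained_variance_ratio_, alpha=0.5,
           label="individual")
    ax.step(comps, model.cumulative_explained_variance_, where="mid",
            color="C1", label="cumulative")
    k = model.n_components_for_variance(threshold)
    ax.axhline(threshold, color="grey", ls="--", lw=0.8)
    ax.axvline(k, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("principal component")
    ax.set_ylabel("explained variance ratio")
    ax.set_title(f"{k} components reach {100 * threshold:.0f}% variance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_information_gain(ranking: pd.DataFrame, path: str | Path,
                          highlight_last: int = 52) -> Path:
    """Descending information-gain profile; the discarded tail shaded."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ig = ranking["ig_bits"].to_numpy()
    ax.bar(np.arange(len(ig)), ig, width=1.0)
    if 0 < highlight_last < len(ig):
        ax.axvspan(len(ig) - highlight_last - 0.5, len(ig) - 0.5,
                   color="red", alpha=0.15, label=f"last {highlight_last}")
        ax.legend()
    ax.set_xlabel("feature rank")
    ax.set_ylabel("information gain (bits)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_condition_accuracies(grid: pd.DataFrame, path: str | Path) -> Path:
    """Mean ± SD accuracy per benchmark condition (scheme, combo or k)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(grid))
    ax.bar(x, grid["accuracy_pct"], yerr=grid["accuracy_sd"], capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels(grid["condition"], rotation=30, ha="right")
    ax.set_ylabel("LOOCV accuracy (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
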