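"""Optional figure outputs: score plots, weighting plots, PCA plots.

Numerical tables are the pipeline's contract; these plots are convenience
artifacts mirroring the standard presentation of fingerprinting results.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .plsda import PlsModel  # noqa: E402


def score_plot(model: PlsModel, labels, path: str | Path) -> Path:
    """LV1 (vs LV2 when present) scores, colored by class."""
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    evf = model.explained_variance_fraction
    if model.scores.shape[1] >= 2:
        for cls in np.unique(labels):
            m = labels == cls
            ax.scatter(model.scores[m, 0], model.scores[m, 1], label=str(cls))
        ax.set_xlabel(f"LV1 ({100 * evf[0]:.1f}%)")
        ax.set_ylabel(f"LV2 ({100 * evf[1]:.1f}%)")
        ax.axhline(0.0, ls="--", c="gray", lw=0.8)
        ax.axvline(0.0, ls="--", c="gray", lw=0.8)
    else:
        for cls in np.unique(labels):
            m = labels == cls
            ax.scatter(np.flatnonzero(m), model.scores[m, 0], label=str(cls))
        ax.set_xlabel("sample")
        ax.set_ylabel(f"LV1 score ({100 * evf[0]:.1f}%)")
        ax.axhline(0.0, ls="--", c="gray", lw=0.8)
    ax.legend(title="class", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def weighting_plot(model: PlsModel, path: str | Path, n_label: int = 10) -> Path:
    """LV1 weightings across the ppm axis, largest peaks labelled."""
    centers = (model.bin_centers if model.bin_centers is not None
               else np.arange(model.x_weights.shape[0], dtype=float))
    w = model.x_weights[:, 0]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(centers, w, lw=0.7)
    top = np.argsort(-np.abs(w))[:n_label]
    for j in top:
        ax.annotate(f"{centers[j]:.2f}", (centers[j], w[j]), fontsize=6)
    ax.set_xlabel("chemical shift (ppm)")
    evf = model.explained_variance_fraction
    ax.set_ylabel(f"LV1 weighting ({100 * evf[0]:.1f}%)")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def pca_plot(scores: np.ndarray, variance_fractions: np.ndarray, labels,
             path: str | Path) -> Path:
    """PC1 vs PC2 of the GA-selected bins, colored by class."""
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in np.unique(labels):
        m = labels == cls
        y = scores[m, 1] if scores.shape[1] > 1 else np.zeros(m.sum())
        ax.scatter(scores[m, 0], y, label=str(cls))
    ax.set_xlabel(f"PC1 ({100 * variance_fractions[0]:.1f}%)")
    if scores.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({100 * variance_fractions[1]:.1f}%)")
    ax.legend(title="class", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
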