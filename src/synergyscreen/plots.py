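"""Minimal figure helpers: Fa-CI and Fa-DRI profiles, clustered heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .median_effect import SynergyProfile
from .triage import ClusterResult, ordered_matrix


def fa_ci_plot(profile: SynergyProfile, ax=None):
    """CI versus Fa with the additivity line and high-effect region shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.plot(profile.fa_grid, profile.ci_values, "o-", color="tab:blue",
            label=f"{profile.drugs[0]} + {profile.drugs[1]}")
    ax.axhline(1.0, color="black", lw=0.8, ls="--")
    ax.axvspan(profile.fa_threshold, 1.0, color="gold", alpha=0.2)
    ax.set_xlabel("Fa (fraction affected)")
    ax.set_ylabel("Combination index (CI)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def fa_dri_plot(profile: SynergyProfile, ax=None):
    """Per-drug DRI versus Fa with the DRI = 1 reference line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    dri1 = [d[0] for d in profile.dri_values]
    dri2 = [d[1] for d in profile.dri_values]
    ax.plot(profile.fa_grid, dri1, "o-", label=profile.drugs[0])
    ax.plot(profile.fa_grid, dri2, "s-", label=profile.drugs[1])
    ax.axhline(1.0, color="black", lw=0.8, ls="--")
    ax.set_xlabel("Fa (fraction affected)")
    ax.set_ylabel("Dose-reduction index (DRI)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def heatmap(matrix: pd.DataFrame, cluster: ClusterResult | None = None, ax=None, cmap="RdBu"):
    """Basic heatmap of a (optionally cluster-ordered) labelled matrix."""
    if cluster is not None:
        matrix = ordered_matrix(matrix, cluster)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(matrix.shape[1]), labels=matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), labels=matrix.index, fontsize=6)
    plt.colorbar(im, ax=ax, shrink=0.7)
    return ax
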