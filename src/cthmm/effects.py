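"""Downstream analyses of a fitted progression model.

Two views of the fitted transition model:

* per-covariate-group 1-year transition matrices — evaluate the generator
  on a grid of covariate settings (e.g. CAG repeat lengths 40, 42, 43,
  45, 50 with other covariates at cohort means) and report
  ``A(1) = expm(Q)``, optionally display-truncating probabilities below
  0.005 to zero for heatmap legibility;
* effect-pattern clustering — arrange each covariate's coefficients over
  the allowed transitions into a matrix (intercept excluded), project it
  onto its first two principal components, and group covariates by
  average-linkage agglomerative clustering on those scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import average as _average_linkage, fcluster
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .model import (
    BetaParams,
    CovariateVector,
    ModelParams,
    TransitionStructure,
    ValidationError,
    build_generator,
    transition_matrix,
)

__all__ = [
    "GroupTransitionSummary",
    "BetaClusterResult",
    "group_transition_matrices",
    "cluster_beta_patterns",
    "cag_covariate_grid",
]


@dataclass
class GroupTransitionSummary:
    group: str
    covariates: CovariateVector
    delta: float
    matrix: np.ndarray            # full stochastic matrix
    truncated: np.ndarray         # display copy, entries < threshold zeroed
    display_threshold: float


@dataclass
class BetaClusterResult:
    effect_matrix: np.ndarray     # (n_covariates, n_edges)
    covariate_labels: tuple[str, ...]
    pc_scores: np.ndarray         # (n_covariates, n_components)
    explained_variance: np.ndarray
    linkage_tree: np.ndarray      # scipy linkage matrix
    labels: np.ndarray            # cluster label per covariate


def group_transition_matrices(
    params: ModelParams,
    covariate_grid: Sequence[CovariateVector],
    delta: float = 1.0,
    display_threshold: float = 0.005,
    group_labels: Sequence[str] | None = None,
) -> list[GroupTransitionSummary]:
    """Interval transition matrices for a grid of covariate settings.

    Deterministic given the parameters and grid; the truncation affects
    only the display copy, never the stored full matrix.
    """
    if group_labels is not None and len(group_labels) != len(covariate_grid):
        raise ValidationError("group_labels length must match grid")
    out = []
    for g, z in enumerate(covariate_grid):
        q = params.generator_for(z)
        a = transition_matrix(q, delta)
        trunc = np.where(np.abs(a) < display_threshold, 0.0, a)
        label = group_labels[g] if group_labels is not None else f"group{g}"
        out.append(GroupTransitionSummary(label, z, float(delta), a, trunc,
                                          float(display_threshold)))
    return out


def cag_covariate_grid(
    labels: Sequence[str],
    cag_label: str,
    cag_values: Sequence[float] = (40, 42, 43, 45, 50),
    cohort_covariates: np.ndarray | None = None,
    cag_offset: float = 40.0,
    cag_scale: float = 10.0,
) -> tuple[list[CovariateVector], list[str]]:
    """Covariate vectors sweeping raw CAG values through the fit-time
    scaling, all other covariates held at cohort means (or 0)."""
    labels = tuple(labels)
    if cag_label not in labels:
        raise ValidationError(f"covariate {cag_label!r} not among {labels}")
    base = (np.nanmean(cohort_covariates, axis=0)
            if cohort_covariates is not None else np.zeros(len(labels)))
    base = np.asarray(base, dtype=float).copy()
    base[-1] = 1.0
    idx = labels.index(cag_label)
    grid, names = [], []
    for cag in cag_values:
        z = base.copy()
        z[idx] = (cag - cag_offset) / cag_scale
        grid.append(CovariateVector(z, labels))
        names.append(f"CAG={cag:g}")
    return grid, names


def cluster_beta_patterns(
    beta: BetaParams,
    covariate_labels: Sequence[str],
    structure: TransitionStructure,
    n_components: int = 2,
    linkage: str = "average",
    n_clusters: int | None = 2,
    cut_height: float | None = None,
    standardize: bool = False,
    include_intercept: bool = False,
) -> BetaClusterResult:
    """PCA + agglomerative clustering of per-covariate effect patterns.

    Rows of the effect matrix are covariates (intercept excluded by
    default), columns the allowed transitions.  Columns are centered
    (optionally standardized), projected on the leading principal
    components, and the scores grouped by average-linkage hierarchical
    clustering cut either at ``n_clusters`` or at ``cut_height``.
    """
    if linkage != "average":
        raise ValidationError("only average linkage is supported")
    bmat = beta.matrix(structure)          # (n_edges, L)
    labels = tuple(covariate_labels)
    if len(labels) != bmat.shape[1]:
        raise ValidationError("covariate_labels length must equal L")
    if include_intercept:
        effect = bmat.T.copy()
        row_labels = labels
    else:
        effect = bmat[:, :-1].T.copy()     # drop trailing intercept column
        row_labels = labels[:-1]
    n_cov = effect.shape[0]
    if n_cov < 2:
        raise ValidationError("need >= 2 covariates to cluster")
    if n_clusters is not None and n_clusters > n_cov:
        raise ValidationError(f"n_clusters={n_clusters} exceeds {n_cov} covariates")
    n_comp = min(n_components, n_cov, effect.shape[1])

    centered = effect - effect.mean(axis=0, keepdims=True)
    if standardize:
        sd = centered.std(axis=0, ddof=0)
        centered = centered / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(centered)
    tree = _average_linkage(pdist(scores))
    if cut_height is not None:
        lab = fcluster(tree, t=cut_height, criterion="distance")
    else:
        lab = fcluster(tree, t=n_clusters, criterion="maxclust")
    return BetaClusterResult(
        effect_matrix=effect,
        covariate_labels=tuple(row_labels),
        pc_scores=scores,
        explained_variance=pca.explained_variance_ratio_,
        linkage_tree=tree,
        labels=np.asarray(lab),
    )


# ---------------------------------------------------------------------------
# Plotting layer (optional matplotlib)
# ---------------------------------------------------------------------------


def plot_transition_heatmaps(summaries: Sequence[GroupTransitionSummary], path) -> None:
    """Heatmap panel of display-truncated 1-year transition matrices."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(summaries)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), squeeze=False)
    for ax, s in zip(axes[0], summaries):
        im = ax.imshow(s.truncated, cmap="viridis", vmin=0, vmax=1)
        ax.set_title(s.group)
        ax.set_xlabel("to state")
        ax.set_ylabel("from state")
    fig.colorbar(im, ax=axes[0].tolist(), shrink=0.8)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_beta_heatmap(beta: BetaParams, covariate_labels: Sequence[str],
                      structure: TransitionStructure, path,
                      display_range: float = 2.0) -> None:
    """Effect-matrix heatmap; coefficients within [-display_range,
    display_range] are blanked for legibility (display only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bmat = beta.matrix(structure)[:, :-1].T
    shown = np.where(np.abs(bmat) > display_range, bmat, np.nan)
    fig, ax = plt.subplots(figsize=(0.6 * structure.n_edges + 2, 0.5 * bmat.shape[0] + 2))
    im = ax.imshow(shown, cmap="coolwarm", vmin=-np.nanmax(np.abs(bmat)) if bmat.size else -1,
                   vmax=np.nanmax(np.abs(bmat)) if bmat.size else 1)
    ax.set_xticks(range(structure.n_edges))
    ax.set_xticklabels([f"{i}->{j}" for i, j in structure.edges], rotation=90)
    ax.set_yticks(range(bmat.shape[0]))
    ax.set_yticklabels(covariate_labels[:-1])
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_clusters(result: BetaClusterResult, path) -> None:
    """Scatter of covariates on the first two principal components."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(result.pc_scores[:, 0],
                    result.pc_scores[:, 1] if result.pc_scores.shape[1] > 1
                    else np.zeros(len(result.labels)),
                    c=result.labels, cmap="tab10")
    for i, lab in enumerate(result.covariate_labels):
        ax.annotate(lab, result.pc_scores[i, :2] if result.pc_scores.shape[1] > 1
                    else (result.pc_scores[i, 0], 0.0), fontsize=8)
    ax.set_xlabel(f"PC1 ({result.explained_variance[0]:.0%})")
    if result.explained_variance.size > 1:
        ax.set_ylabel(f"PC2 ({result.explained_variance[1]:.0%})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
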