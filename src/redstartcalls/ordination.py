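"""Ordination of call distances: PCoA, NMDS, group ellipses and plots.

Principal coordinates analysis embeds a distance matrix metrically via the
eigendecomposition of the Gower-centered squared-distance matrix; axes with
negative eigenvalues (which arise for non-Euclidean dissimilarities such as
1 - random-forest proximity) are excluded from the coordinates and reported
separately.  Non-metric multidimensional scaling preserves distance ranks
by minimizing Kruskal stress-1 over monotone-regressed distances, taking
the best of several random restarts.

Group ellipses follow the convention of confidence ellipses on the group
centroid: the covariance of the axis scores divided by the group size
(i.e. the standard error of the mean), scaled by the chi-square quantile
with 2 degrees of freedom at the requested confidence level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .permanova import DistanceMatrix

__all__ = [
    "OrdinationResult",
    "GroupEllipse",
    "pcoa",
    "nmds",
    "group_ellipses",
    "plot_ordination",
    "plot_similarity_heatmap",
]


@dataclass
class OrdinationResult:
    """Low-dimensional embedding of calls with method diagnostics."""

    coordinates: np.ndarray  # (n, k)
    method: str  # 'pcoa' | 'nmds'
    eigenvalues: np.ndarray | None = None  # full spectrum, descending (PCoA)
    stress: float | None = None  # Kruskal stress-1 (NMDS)
    seed: int | None = None

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    @property
    def k(self) -> int:
        return self.coordinates.shape[1]


@dataclass
class GroupEllipse:
    """Confidence ellipse on a group's centroid in ordination space."""

    label: object
    center: np.ndarray
    semi_axes: np.ndarray | None  # lengths of the two semi-axes, descending
    angle: float | None  # radians, orientation of the major axis
    n: int
    degenerate: bool = False


def pcoa(dist: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Coordinates are eigenvectors of the Gower-centered matrix scaled by the
    square root of their (positive) eigenvalues.
    """
    n = dist.n
    if n < k + 1:
        raise ValueError(f"PCoA with k={k} needs at least {k + 1} points")
    A = -0.5 * dist.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = max(eigvals.max(), 1.0)
    n_pos = int(np.sum(eigvals > 1e-10 * scale))
    if k > n_pos:
        raise ValueError(
            f"requested k={k} axes but only {n_pos} positive eigenvalues are "
            "available"
        )
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    return OrdinationResult(coordinates=coords, method="pcoa", eigenvalues=eigvals)


def nmds(
    dist: DistanceMatrix, k: int = 2, restarts: int = 20, seed: int = 0
) -> OrdinationResult:
    """Non-metric MDS (Kruskal stress-1), best of `restarts` seeded starts."""
    from sklearn.manifold import MDS

    if dist.n < 4:
        raise ValueError("NMDS requires at least 4 points")
    best = None
    rng = np.random.default_rng(seed)
    states = rng.integers(0, 2**31 - 1, size=restarts)
    for state in states:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mds = MDS(
                n_components=k,
                metric=False,
                dissimilarity="precomputed",
                random_state=int(state),
                n_init=1,
                max_iter=500,
                eps=1e-9,
                normalized_stress=True,
            )
            coords = mds.fit_transform(dist.values)
        if not np.isfinite(mds.stress_):
            continue
        if best is None or mds.stress_ < best[0]:
            best = (float(mds.stress_), coords)
    if best is None:
        raise RuntimeError(
            f"NMDS failed to converge in any of {restarts} restarts "
            f"(n={dist.n}, k={k})"
        )
    return OrdinationResult(
        coordinates=best[1], method="nmds", stress=best[0], seed=seed
    )


def group_ellipses(
    ordination: OrdinationResult, labels, level: float = 0.99
) -> list[GroupEllipse]:
    """Centroid confidence ellipses per group at the given level."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    coords = ordination.coordinates[:, :2]
    labels = np.asarray(labels)
    q = chi2.ppf(level, df=2)
    out = []
    for g in pd.unique(labels):
        pts = coords[labels == g]
        center = pts.mean(axis=0)
        if len(pts) < 2:
            out.append(GroupEllipse(g, center, None, None, len(pts), degenerate=True))
            continue
        cov = np.cov(pts, rowvar=False) / len(pts)  # SE of the centroid
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        if evals[0] <= 0:
            out.append(GroupEllipse(g, center, None, None, len(pts), degenerate=True))
            continue
        semi = np.sqrt(np.clip(evals, 0.0, None) * q)
        angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
        out.append(
            GroupEllipse(g, center, semi, angle, len(pts), degenerate=semi[1] <= 0)
        )
    return out


# ---------------------------------------------------------------------------
# plotting


def plot_ordination(
    ordination: OrdinationResult, labels, path=None, level: float = 0.99, title=None
):
    """Scatter of the first two axes with group centroids and ellipses."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for g in pd.unique(labels):
        pts = ordination.coordinates[labels == g, :2]
        ax.scatter(pts[:, 0], pts[:, 1], s=14, alpha=0.7, label=str(g))
    for ell in group_ellipses(ordination, labels, level=level):
        if ell.semi_axes is None:
            continue
        ax.add_patch(
            Ellipse(
                ell.center,
                2 * ell.semi_axes[0],
                2 * ell.semi_axes[1],
                angle=np.degrees(ell.angle),
                fill=False,
                lw=1.2,
            )
        )
        ax.annotate(str(ell.label), ell.center, fontsize=10, weight="bold")
    ax.set_xlabel("Axis 1")
    ax.set_ylabel("Axis 2")
    if ordination.method == "nmds" and ordination.stress is not None:
        ax.set_title(title or f"NMDS (stress = {ordination.stress:.3f})")
    else:
        ax.set_title(title or "PCoA")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_similarity_heatmap(matrix, path=None, title="Call similarity"):
    """Similarity heatmap ordered by bird; darker = more similar.

    Grid lines separate the calls of different individuals.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    birds = np.asarray(matrix.bird_ids)
    order = np.argsort(birds, kind="stable")
    V = matrix.values[np.ix_(order, order)]
    sorted_birds = birds[order]
    fig, ax = plt.subplots(figsize=(6.5, 6))
    ax.imshow(1.0 - V, cmap="gray", interpolation="nearest")
    boundaries = np.flatnonzero(sorted_birds[1:] != sorted_birds[:-1]) + 0.5
    for b in boundaries:
        ax.axhline(b, color="black", lw=0.4)
        ax.axvline(b, color="black", lw=0.4)
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
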