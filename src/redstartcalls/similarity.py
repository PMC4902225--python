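"""Unsupervised random-forest call similarity and within/between statistics.

Call similarity follows the synthetic-contrast construction of unsupervised
random forests: a contrast class is built by sampling every feature
independently from its empirical marginal (destroying the joint structure),
a forest is trained to separate real calls from the contrast, and the
proximity of two real calls is the fraction of trees in which they land in
the same terminal node.  Proximities lie in [0, 1] with 1 on the diagonal
and behave as a similarity score that respects the joint feature structure
of real calls.

The within/between analysis averages, for each bird, the pairwise
proximities among its own calls (C(n,2) values per bird) and between its
calls and every other bird's calls (n^2 * (n_birds - 1) values), and
compares the two per-bird samples with a two-sample t-test (Welch by
default; the pooled variant is also reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .features import feature_columns

__all__ = [
    "SimilarityMatrix",
    "WithinBetweenResult",
    "ProximityForest",
    "ProximityResults",
    "unsupervised_proximity",
    "within_between_similarity",
    "supervised_importance",
    "similarity_to_distance",
]


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise call-similarity scores in [0, 1], diagonal 1."""

    values: np.ndarray
    call_ids: list
    bird_ids: list

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = v.shape[0]
        if v.shape != (n, n) or n != len(self.call_ids) or n != len(self.bird_ids):
            raise ValueError("similarity matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        self.values = v

    @property
    def n_calls(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.call_ids, columns=self.call_ids)


@dataclass
class WithinBetweenResult:
    """Per-bird mean similarities and the within-vs-between t-test."""

    within_means: pd.Series  # one mean per bird (C(n,2) pairs each)
    between_means: pd.Series  # one mean per bird (n^2 * (n_birds-1) entries each)
    t_statistic: float  # Welch
    df: float
    p_value: float
    t_pooled: float
    df_pooled: float
    p_pooled: float
    pair_counts: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Within- vs between-individual call similarity",
            f"  birds: {len(self.within_means)}",
            f"  mean within similarity:  {self.within_means.mean():.4f}",
            f"  mean between similarity: {self.between_means.mean():.4f}",
            f"  Welch t = {self.t_statistic:.2f}, df = {self.df:.1f}, "
            f"p = {self.p_value:.3g}",
            f"  pooled t = {self.t_pooled:.2f}, df = {self.df_pooled:.0f}, "
            f"p = {self.p_pooled:.3g}",
        ]
        return "\n".join(lines)


class ProximityForest:
    """Unsupervised random-forest proximity model over a feature table.

    Parameters
    ----------
    table : feature table (metadata columns + numeric features).
    n_trees : number of trees (the reference analysis used 4999).
    oob_only : if True, count each pair only over trees where both calls
        are out of bag, instead of over all trees (the default).
    """

    def __init__(self, table: pd.DataFrame, n_trees: int = 4999, oob_only: bool = False):
        feats = feature_columns(table)
        if len(table) < 10:
            raise ValueError("proximity analysis requires at least 10 calls")
        X = table[feats]
        non_numeric = [c for c in feats if not np.issubdtype(X[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"non-numeric feature column(s): {non_numeric}")
        self.table = table
        self.feature_names = feats
        self.n_trees = int(n_trees)
        self.oob_only = bool(oob_only)

    def fit(self, seed: int = 0) -> "ProximityResults":
        rng = np.random.default_rng(seed)
        X = self.table[self.feature_names].to_numpy(dtype=float)
        n, p = X.shape
        # synthetic contrast: independent draws from each empirical marginal
        contrast = np.column_stack(
            [rng.choice(X[:, j], size=n, replace=True) for j in range(p)]
        )
        Xy = np.vstack([X, contrast])
        y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(Xy, y)
        leaves = forest.apply(X)  # (n, n_trees)
        if self.oob_only:
            prox = self._oob_proximity(forest, Xy, leaves, n)
        else:
            prox = np.zeros((n, n))
            for lo in range(0, self.n_trees, 256):
                chunk = leaves[:, lo : lo + 256]
                prox += (chunk[:, None, :] == chunk[None, :, :]).sum(axis=2)
            prox /= self.n_trees
        np.fill_diagonal(prox, 1.0)
        matrix = SimilarityMatrix(
            values=prox,
            call_ids=list(self.table.get("file", pd.RangeIndex(n))),
            bird_ids=list(self.table["bird_id"]) if "bird_id" in self.table else [None] * n,
        )
        return ProximityResults(matrix=matrix, model=self, forest=forest, seed=seed)

    @staticmethod
    def _oob_proximity(forest, Xy, leaves, n):
        from sklearn.ensemble._forest import (
            _generate_unsampled_indices,
            _get_n_samples_bootstrap,
        )

        n_total = Xy.shape[0]
        n_boot = _get_n_samples_bootstrap(n_total, forest.max_samples)
        prox = np.zeros((n, n))
        counts = np.zeros((n, n))
        for t, tree in enumerate(forest.estimators_):
            oob = _generate_unsampled_indices(tree.random_state, n_total, n_boot)
            mask = np.zeros(n, dtype=bool)
            mask[oob[oob < n]] = True
            both = np.outer(mask, mask)
            same = leaves[:, t][:, None] == leaves[:, t][None, :]
            prox += both & same
            counts += both
        with np.errstate(invalid="ignore", divide="ignore"):
            prox = np.where(counts > 0, prox / counts, 0.0)
        return prox


@dataclass
class ProximityResults:
    """Fitted proximity model: the similarity matrix plus derived statistics."""

    matrix: SimilarityMatrix
    model: ProximityForest
    forest: RandomForestClassifier
    seed: int

    def within_between(self) -> WithinBetweenResult:
        return within_between_similarity(self.matrix)

    def to_distance(self) -> np.ndarray:
        return similarity_to_distance(self.matrix)


def unsupervised_proximity(
    table: pd.DataFrame, n_trees: int = 4999, seed: int = 0, oob_only: bool = False
) -> SimilarityMatrix:
    """Functional wrapper: fit a ProximityForest and return its matrix."""
    return ProximityForest(table, n_trees=n_trees, oob_only=oob_only).fit(seed).matrix


def within_between_similarity(matrix: SimilarityMatrix) -> WithinBetweenResult:
    """Per-bird within/between mean similarities and their t-test."""
    from scipy import stats as _stats

    birds = pd.Series(matrix.bird_ids)
    uniq = birds.unique()
    if len(uniq) < 2:
        raise ValueError("within/between analysis requires at least 2 birds")
    V = matrix.values
    within = {}
    between = {}
    counts = {}
    for b in uniq:
        idx = np.flatnonzero(birds.to_numpy() == b)
        other = np.flatnonzero(birds.to_numpy() != b)
        if idx.size < 2:
            warnings.warn(
                f"bird {b!r} has a single call; excluded from within-individual means"
            )
        else:
            sub = V[np.ix_(idx, idx)]
            iu = np.triu_indices(idx.size, k=1)
            within[b] = float(sub[iu].mean())
        between[b] = float(V[np.ix_(idx, other)].mean())
        counts[b] = {
            "within_pairs": int(idx.size * (idx.size - 1) // 2),
            "between_entries": int(idx.size * other.size),
        }
    w = pd.Series(within, name="within")
    btw = pd.Series(between, name="between")
    if np.allclose(w.std(ddof=1), 0.0) and np.allclose(btw.std(ddof=1), 0.0):
        t_w = t_p = 0.0
        df_w = len(w) + len(btw) - 2.0
        p_w = p_p = 1.0
    else:
        t_w, p_w = _stats.ttest_ind(w, btw, equal_var=False)
        res = _stats.ttest_ind(w, btw, equal_var=False)
        df_w = float(res.df)
        t_p, p_p = _stats.ttest_ind(w, btw, equal_var=True)
        t_w, p_w, t_p, p_p = float(t_w), float(p_w), float(t_p), float(p_p)
    return WithinBetweenResult(
        within_means=w,
        between_means=btw,
        t_statistic=t_w,
        df=df_w,
        p_value=p_w,
        t_pooled=t_p,
        df_pooled=float(len(w) + len(btw) - 2),
        p_pooled=p_p,
        pair_counts=counts,
    )


def supervised_importance(
    table: pd.DataFrame,
    labels,
    n_trees: int = 4999,
    seed: int = 0,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Feature importance from a forest supervised by a fixed factor.

    Returns a frame indexed by feature with ``mean_decrease_accuracy``
    (permutation importance) and ``mean_decrease_gini`` (impurity
    importance) plus the rank under each criterion.
    """
    feats = feature_columns(table)
    y = np.asarray(labels)
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("supervised importance requires at least 2 label classes")
    if class_counts.min() < 2:
        raise ValueError("every label class needs at least 2 rows")
    X = table[feats].to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    perm = permutation_importance(
        forest, X, y, n_repeats=n_repeats, random_state=seed, scoring="accuracy"
    )
    out = pd.DataFrame(
        {
            "mean_decrease_accuracy": perm.importances_mean,
            "mean_decrease_gini": forest.feature_importances_,
        },
        index=pd.Index(feats, name="feature"),
    )
    out["rank_accuracy"] = (
        out["mean_decrease_accuracy"].rank(ascending=False, method="first").astype(int)
    )
    out["rank_gini"] = (
        out["mean_decrease_gini"].rank(ascending=False, method="first").astype(int)
    )
    return out.sort_values("mean_decrease_accuracy", ascending=False)


def similarity_to_distance(matrix: SimilarityMatrix) -> np.ndarray:
    """d(i, j) = 1 - proximity(i, j), with a zero diagonal."""
    d = 1.0 - matrix.values
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)
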