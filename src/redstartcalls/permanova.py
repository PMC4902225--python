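"""Permutational multivariate analysis of variance on call distances.

PERMANOVA (Anderson's distance-based pseudo-F test) partitions the total
sum of squared inter-point distances among the levels of categorical
factors.  For a single factor with a groups on n points,

    SS_total  = (1/n) * sum_{i<j} d_ij^2
    SS_within = sum_groups (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F  = [ (SS_total - SS_within) / (a - 1) ] / [ SS_within / (n - a) ]

and significance comes from permuting the labels: the p-value is
(1 + #{F_perm >= F_obs}) / (1 + n_perm).  For univariate Euclidean input
the pseudo-F coincides with the classical one-way ANOVA F.

Multi-factor designs use the Gower-centered inner-product matrix
G = -1/2 * J A J (A the squared distances, J the centering projector) and
sequential (Type I) sums of squares via hat matrices of the growing design:
SS_term = tr((H_k - H_{k-1}) G).  When individual birds are the exchangeable
units ("individual identity nested" in the design), factors that are
constant within a bird (sex, age) are tested by permuting whole birds —
bird-level labels are reassigned across birds so that the within-bird
correlation structure is preserved under the null — while call-level
factors use free permutation of calls.

The `Permanova` model class wraps this: build it from a distance matrix (or
a feature table) plus factor labels; `fit()` returns a `PermanovaResults`
carrying the per-term table and a `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "distance_matrix",
    "permanova_single",
    "permanova_terms",
    "Permanova",
    "PermanovaResults",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    values: np.ndarray
    labels: list = field(default_factory=list)
    metric: str = "unknown"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12:
            raise ValueError("distances must be non-negative")
        self.values = v
        if not self.labels:
            self.labels = list(range(v.shape[0]))

    @property
    def n(self) -> int:
        return self.values.shape[0]


def distance_matrix(
    table: pd.DataFrame,
    metric: str = "euclidean",
    standardize: str = "zscore",
) -> DistanceMatrix:
    """Pairwise call distances from a feature table.

    metric: 'euclidean', 'manhattan' (cityblock) or 'bray-curtis';
    standardize: 'zscore' (per-feature, the default — acoustic measurements
    mix units of ms, Hz and bits) or 'none'.  Bray-Curtis requires
    non-negative values and is therefore incompatible with z-scoring.
    """
    from .features import feature_columns

    feats = feature_columns(table)
    X = table[feats].to_numpy(dtype=float)
    if standardize == "zscore":
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    elif standardize != "none":
        raise ValueError(f"unknown standardize option {standardize!r}")
    scipy_metric = {
        "euclidean": "euclidean",
        "manhattan": "cityblock",
        "bray-curtis": "braycurtis",
    }.get(metric)
    if scipy_metric is None:
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "bray-curtis" and (X < 0).any():
        raise ValueError(
            "bray-curtis distance requires non-negative values; use "
            "standardize='none' and non-negative features"
        )
    d = squareform(pdist(X, metric=scipy_metric))
    labels = list(table["file"]) if "file" in table.columns else list(range(len(table)))
    return DistanceMatrix(values=d, labels=labels, metric=metric)


# ---------------------------------------------------------------------------
# single factor


def _group_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """SS_within = sum over groups of mean pairwise squared distance sums."""
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * idx.size)
    return ss


def permanova_single(
    dist: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
) -> "PermanovaResults":
    """One-factor PERMANOVA with free label permutation."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    codes, uniq = pd.factorize(labels)
    a = len(uniq)
    n = dist.n
    if a < 2:
        raise ValueError("factor needs at least 2 levels")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every factor level needs at least 2 observations")
    d2 = dist.values**2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _group_ss(d2, codes, a)
    ss_factor = ss_total - ss_within
    df_factor, df_resid = a - 1, n - a
    f_obs = (ss_factor / df_factor) / (ss_within / df_resid)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ss_w = _group_ss(d2, codes[perm], a)
        f_perm = ((ss_total - ss_w) / df_factor) / (ss_w / df_resid)
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    name = getattr(labels, "name", None) or "factor"
    table = pd.DataFrame(
        {
            "df": [df_factor, df_resid, n - 1],
            "SumOfSqs": [ss_factor, ss_within, ss_total],
            "F": [f_obs, np.nan, np.nan],
            "R2": [ss_factor / ss_total, ss_within / ss_total, 1.0],
            "p": [p, np.nan, np.nan],
        },
        index=[name, "Residual", "Total"],
    )
    return PermanovaResults(
        table=table,
        n_perm=n_perm,
        seed=seed,
        metric=dist.metric,
        schemes={name: "free"},
    )


# ---------------------------------------------------------------------------
# multi-term sequential designs


def _dummies(values: np.ndarray) -> np.ndarray:
    codes, uniq = pd.factorize(values)
    if len(uniq) < 2:
        return np.empty((values.size, 0))
    d = np.zeros((values.size, len(uniq) - 1))
    for k in range(1, len(uniq)):
        d[codes == k, k - 1] = 1.0
    return d


def _hat(X: np.ndarray) -> np.ndarray:
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], X.shape[0]))
    return X @ np.linalg.pinv(X)


class Permanova:
    """PERMANOVA model: distance matrix + factor design.

    Parameters
    ----------
    dist : DistanceMatrix over n calls.
    factors : DataFrame (n rows) of categorical factor columns, in the
        order the sequential sums of squares should attribute them.
    interactions : iterable of (factor_a, factor_b) name pairs.
    nest : optional label vector naming the exchangeable unit of each call
        (the bird).  Factors that are constant within every unit are tested
        by permuting unit-level labels across units.
    """

    def __init__(self, dist: DistanceMatrix, factors: pd.DataFrame,
                 interactions=(), nest=None):
        if len(factors) != dist.n:
            raise ValueError("factor table length does not match distance matrix")
        self.dist = dist
        self.factors = factors.reset_index(drop=True)
        self.interactions = [tuple(t) for t in interactions]
        self.nest = None if nest is None else np.asarray(nest)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        factors: list[str],
        interactions=(),
        nest: str | None = None,
        metric: str = "euclidean",
        standardize: str = "zscore",
    ) -> "Permanova":
        dist = distance_matrix(table, metric=metric, standardize=standardize)
        nest_vals = table[nest].to_numpy() if nest else None
        return cls(dist, table[list(factors)], interactions=interactions, nest=nest_vals)

    # -- design handling ----------------------------------------------------

    def _term_columns(self, factor_values: dict[str, np.ndarray]):
        """Ordered (term_name, design_block) pairs for the sequential model."""
        terms = []
        for name in self.factors.columns:
            terms.append((name, _dummies(factor_values[name])))
        for a, b in self.interactions:
            da, db = _dummies(factor_values[a]), _dummies(factor_values[b])
            block = np.einsum("ni,nj->nij", da, db).reshape(len(da), -1)
            terms.append((f"{a}:{b}", block))
        return terms

    def _is_unit_level(self, name: str) -> bool:
        if self.nest is None:
            return False
        parts = name.split(":")
        for part in parts:
            vals = self.factors[part].to_numpy()
            for unit in np.unique(self.nest):
                if len(set(vals[self.nest == unit])) > 1:
                    return False
        return True

    def _sequential_ss(self, G: np.ndarray, terms) -> tuple[list, float, list]:
        n = G.shape[0]
        X = np.ones((n, 1))
        H_prev = _hat(X)
        rank_prev = 1
        rows = []
        for name, block in terms:
            X = np.column_stack([X, block])
            H = _hat(X)
            rank = int(np.round(np.trace(H)))
            df = rank - rank_prev
            if df == 0:
                raise ValueError(
                    f"term {name!r} is aliased with earlier terms (0 df); "
                    "check for confounded factors"
                )
            ss = float(np.trace((H - H_prev) @ G))
            rows.append({"term": name, "df": df, "SumOfSqs": ss})
            H_prev, rank_prev = H, rank
        ss_resid = float(np.trace((np.eye(n) - H_prev) @ G))
        return rows, ss_resid, [n - rank_prev]

    def fit(self, n_perm: int = 999, seed: int = 0,
            permute_blocks: bool = True) -> "PermanovaResults":
        """Fit the sequential PERMANOVA and permutation-test every term."""
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        n = self.dist.n
        A = -0.5 * self.dist.values**2
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ A @ J
        values = {c: self.factors[c].to_numpy() for c in self.factors.columns}
        terms = self._term_columns(values)
        rows, ss_resid, (df_resid,) = self._sequential_ss(G, terms)
        ss_total = float(np.trace(G))
        for r in rows:
            r["F"] = (r["SumOfSqs"] / r["df"]) / (ss_resid / df_resid)
            r["R2"] = r["SumOfSqs"] / ss_total

        schemes = {
            r["term"]: (
                "blocks"
                if permute_blocks and self.nest is not None
                and self._is_unit_level(r["term"])
                else "free"
            )
            for r in rows
        }
        rng = np.random.default_rng(seed)
        exceed = {r["term"]: 0 for r in rows}
        f_obs = {r["term"]: r["F"] for r in rows}
        need_free = any(s == "free" for s in schemes.values())
        need_block = any(s == "blocks" for s in schemes.values())
        for _ in range(n_perm):
            if need_free:
                perm = rng.permutation(n)
                Gp = G[np.ix_(perm, perm)]
                p_rows, p_resid, (p_dfres,) = self._sequential_ss(Gp, terms)
                for r in p_rows:
                    if schemes[r["term"]] == "free":
                        fp = (r["SumOfSqs"] / r["df"]) / (p_resid / p_dfres)
                        if fp >= f_obs[r["term"]] - 1e-12:
                            exceed[r["term"]] += 1
            if need_block:
                perm_values = self._permute_unit_labels(values, rng)
                p_terms = self._term_columns(perm_values)
                p_rows, p_resid, (p_dfres,) = self._sequential_ss(G, p_terms)
                for r in p_rows:
                    if schemes[r["term"]] == "blocks":
                        fp = (r["SumOfSqs"] / r["df"]) / (p_resid / p_dfres)
                        if fp >= f_obs[r["term"]] - 1e-12:
                            exceed[r["term"]] += 1
        for r in rows:
            r["p"] = (1.0 + exceed[r["term"]]) / (1.0 + n_perm)

        table = pd.DataFrame(rows).set_index("term")
        table.loc["Residual"] = {
            "df": df_resid, "SumOfSqs": ss_resid, "F": np.nan,
            "R2": ss_resid / ss_total, "p": np.nan,
        }
        table.loc["Total"] = {
            "df": n - 1, "SumOfSqs": ss_total, "F": np.nan, "R2": 1.0, "p": np.nan,
        }
        table["df"] = table["df"].astype(int)
        return PermanovaResults(
            table=table, n_perm=n_perm, seed=seed, metric=self.dist.metric,
            schemes=schemes,
        )

    def _permute_unit_labels(self, values: dict, rng) -> dict:
        """Reassign bird-level factor labels across birds (whole-bird blocks)."""
        units = np.unique(self.nest)
        perm_units = rng.permutation(len(units))
        out = {}
        for name, vals in values.items():
            if self._is_unit_level(name):
                per_unit = {u: vals[self.nest == u][0] for u in units}
                shuffled = {units[k]: per_unit[units[perm_units[k]]]
                            for k in range(len(units))}
                out[name] = np.array([shuffled[u] for u in self.nest])
            else:
                # call-level factors stay attached to their calls under
                # whole-bird relabelling
                out[name] = vals
        return out


@dataclass
class PermanovaResults:
    """Per-term df, sums of squares, pseudo-F, R^2 and permutation p-values."""

    table: pd.DataFrame
    n_perm: int
    seed: int
    metric: str
    schemes: dict = field(default_factory=dict)

    def __post_init__(self):
        ss = self.table["SumOfSqs"]
        terms = ss.drop(index=["Total"])
        total = ss.loc["Total"]
        if abs(terms.sum() - total) > 1e-9 * max(abs(total), 1.0):
            raise AssertionError("sum-of-squares decomposition not conserved")

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def min_p(self) -> float:
        return 1.0 / (self.n_perm + 1.0)

    def summary(self) -> str:
        lines = [
            "Permutational multivariate analysis of variance",
            f"  distance metric: {self.metric}; permutations: {self.n_perm}; "
            f"seed: {self.seed}",
            f"  sums of squares: sequential; permutation schemes: {self.schemes}",
            "",
            self.table.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def permanova_terms(
    dist: DistanceMatrix,
    factors: pd.DataFrame,
    interactions=(),
    nest=None,
    n_perm: int = 999,
    seed: int = 0,
    permute_blocks: bool = True,
) -> PermanovaResults:
    """Functional wrapper over the Permanova model class."""
    model = Permanova(dist, factors, interactions=interactions, nest=nest)
    return model.fit(n_perm=n_perm, seed=seed, permute_blocks=permute_blocks)
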