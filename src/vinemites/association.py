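"""Rank correlations and community ordination.

Spearman correlations relate the toxicity indices to each other and to
predatory-mite densities; non-metric multidimensional scaling (NMDS) on a
Bray-Curtis dissimilarity summarises pollen-community gradients, split
into spring (sampling dates 1-2) and summer (dates 3-5), with
environmental traits fitted onto the ordination envfit-style.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

logger = logging.getLogger(__name__)

SPRING_DATES = (1, 2)
SUMMER_DATES = (3, 4, 5)


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Ties receive average ranks; rho is the Pearson correlation of the
    ranks and p comes from the t distribution with n-2 degrees of freedom.
    Pairs with a missing value in either vector are dropped listwise. A
    constant vector leaves rho undefined: NaN is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("spearman requires at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def correlation_table(table: pd.DataFrame, pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Spearman rho and p for each named column pair of *table*."""
    rows = []
    for a, b in pairs:
        rho, p = spearman(table[a], table[b])
        rows.append({"x": a, "y": b, "rho": rho, "p_value": p, "n": int(
            (~(table[a].isna() | table[b].isna())).sum()
        )})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dissimilarity
# ---------------------------------------------------------------------------

def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarities between community rows.

    d(i,j) = Σ|x_ik − x_jk| / Σ(x_ik + x_jk), in [0, 1], diagonal 0. A pair
    of all-zero rows is defined as d = 0 (identical emptiness) with a
    warning.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("community abundances must be non-negative")
    zero_rows = np.where(~X.any(axis=1))[0]
    D = squareform(pdist(X, metric="braycurtis"))
    if len(zero_rows) > 1:
        warnings.warn(
            f"{len(zero_rows)} all-zero community rows; their mutual "
            "dissimilarity is defined as 0",
            stacklevel=2,
        )
        ix = np.ix_(zero_rows, zero_rows)
        D[ix] = 0.0
    if np.isnan(D).any():  # zero-vs-nonzero handled by scipy; guard anyway
        D = np.nan_to_num(D, nan=0.0)
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResults:
    """NMDS scores, Kruskal stress-1, and fitted environmental traits."""

    scores: pd.DataFrame
    stress: float
    k: int
    converged: bool
    traits: pd.DataFrame | None = None
    trait_centroids: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"NMDS ordination: {len(self.scores)} sites, k = {self.k}",
            f"  Kruskal stress-1 = {self.stress:.4f} "
            f"({'converged' if self.converged else 'best effort'})",
        ]
        if self.stress > 0.2:
            lines.append("  warning: stress > 0.2 — interpret the plot with care")
        if self.traits is not None and len(self.traits):
            lines.append("fitted traits (r², permutation p):")
            for row in self.traits.itertuples(index=False):
                lines.append(f"  {row.trait:28s} r2={row.r2:.3f}  p={row.p_value:.3f}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scores with fitted-trait arrows scaled by r."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(self.scores.iloc[:, 0], self.scores.iloc[:, 1], s=18, c="#333")
        if self.traits is not None:
            scale = np.abs(self.scores.to_numpy()).max()
            for row in self.traits.itertuples(index=False):
                if row.kind != "continuous":
                    continue
                dx, dy = row.axis1, row.axis2
                r = np.sqrt(max(row.r2, 0.0)) * scale
                ax.annotate(
                    row.trait, xy=(dx * r, dy * r), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="<-", color="#bb5566"),
                    color="#bb5566", fontsize=8,
                )
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel("NMDS1")
        ax.set_ylabel("NMDS2")
        ax.set_title(f"stress = {self.stress:.3f}")
        return ax


def _pcoa_init(D: np.ndarray, k: int) -> np.ndarray:
    """Classical-scaling start configuration (double-centred eigenvectors)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_k)


def nmds(
    dissimilarity: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_restarts: int = 8,
    seed: int | None = 0,
    max_iter: int = 500,
) -> OrdinationResults:
    """Non-metric MDS minimising Kruskal stress-1.

    Runs SMACOF with monotone regression from a classical-scaling start
    plus ``n_restarts - 1`` seeded random starts and keeps the lowest
    stress. Scores are centred; the result is deterministic given *seed*.
    Non-convergence returns the best-so-far solution flagged
    ``converged=False``.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("dissimilarity must have a zero diagonal")
    n = D.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, n-1], got {k} for n={n}")
    rng = np.random.default_rng(seed)
    best = None
    for i in range(max(1, n_restarts)):
        init = _pcoa_init(D, k) if i == 0 else None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, stress, n_iter = smacof(
                D,
                metric=False,
                n_components=k,
                init=init,
                n_init=1,
                max_iter=max_iter,
                eps=1e-9,
                random_state=rng.integers(0, 2**31 - 1),
                normalized_stress=True,
                return_n_iter=True,
            )
        converged = n_iter < max_iter
        if best is None or stress < best[1]:
            best = (coords, float(stress), converged)
    coords, stress, converged = best
    coords = coords - coords.mean(axis=0)
    index = (
        dissimilarity.index
        if isinstance(dissimilarity, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    scores = pd.DataFrame(
        coords, index=index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    if not converged:
        logger.warning("NMDS did not converge in %d iterations; stress=%.4f",
                       max_iter, stress)
    return OrdinationResults(scores=scores, stress=stress, k=k, converged=converged)


# ---------------------------------------------------------------------------
# envfit-style trait fitting
# ---------------------------------------------------------------------------

def _continuous_fit(scores: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, float]:
    """Direction cosines and r² of the least-squares fit of a trait onto
    the score space."""
    X = np.column_stack([np.ones(len(v)), scores])
    beta, _, _, _ = np.linalg.lstsq(X, v, rcond=None)
    fitted = X @ beta
    ss_tot = float(((v - v.mean()) ** 2).sum())
    ss_res = float(((v - fitted) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    direction = beta[1:]
    norm = np.linalg.norm(direction)
    if norm > 0:
        direction = direction / norm
    return direction, r2


def _categorical_fit(scores: np.ndarray, labels: np.ndarray) -> tuple[dict, float]:
    """Level centroids and the between-group r² (1 − SSwithin/SStotal)."""
    centroids = {}
    ss_within = 0.0
    grand = scores.mean(axis=0)
    ss_total = float(((scores - grand) ** 2).sum())
    for lev in np.unique(labels):
        sub = scores[labels == lev]
        c = sub.mean(axis=0)
        centroids[str(lev)] = c
        ss_within += float(((sub - c) ** 2).sum())
    r2 = 0.0 if ss_total == 0 else max(0.0, 1.0 - ss_within / ss_total)
    return centroids, r2


def fit_traits(
    ordination: OrdinationResults,
    traits: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> OrdinationResults:
    """Fit environmental traits onto an ordination (vegan envfit style).

    Continuous traits get a least-squares direction in score space with a
    squared correlation r²; categorical traits get level centroids with a
    between-group r². Significance comes from permuting trait rows
    (seeded) and recomputing r²; p = (1 + #{perm r² >= observed}) /
    (1 + n_permutations). Constant traits are skipped with a warning.
    Returns a new :class:`OrdinationResults` carrying the trait table.
    """
    scores = ordination.scores
    missing = set(scores.index) - set(traits.index)
    if missing:
        raise ValueError(f"traits missing for ordination rows: {sorted(missing)}")
    traits = traits.loc[scores.index]
    S = scores.to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    centroids_all = {}
    for name in traits.columns:
        col = traits[name]
        numeric = pd.api.types.is_numeric_dtype(col)
        vals = col.to_numpy()
        if (numeric and np.ptp(vals.astype(float)) == 0) or (
            not numeric and len(pd.unique(vals)) < 2
        ):
            warnings.warn(f"constant trait {name!r} skipped", stacklevel=2)
            continue
        if numeric:
            direction, r2 = _continuous_fit(S, vals.astype(float))
            kind = "continuous"
        else:
            centroids, r2 = _categorical_fit(S, vals.astype(str))
            centroids_all[name] = centroids
            direction = np.full(ordination.k, np.nan)
            kind = "categorical"
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(vals))
            if numeric:
                _, r2p = _continuous_fit(S, vals[perm].astype(float))
            else:
                _, r2p = _categorical_fit(S, vals[perm].astype(str))
            if r2p >= r2:
                exceed += 1
        p = (1.0 + exceed) / (1.0 + n_permutations)
        row = {"trait": name, "kind": kind, "r2": r2, "p_value": p}
        for i in range(ordination.k):
            row[f"axis{i + 1}"] = direction[i] if kind == "continuous" else np.nan
        rows.append(row)
    trait_table = pd.DataFrame(rows)
    return OrdinationResults(
        scores=ordination.scores,
        stress=ordination.stress,
        k=ordination.k,
        converged=ordination.converged,
        traits=trait_table,
        trait_centroids=centroids_all,
    )


# ---------------------------------------------------------------------------
# seasonal split
# ---------------------------------------------------------------------------

def split_season(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into spring (dates 1-2) and summer (dates 3-5).

    The split is exhaustive and disjoint; an unknown date index is an
    error.
    """
    dates = records["date_index"].astype(int)
    unknown = set(dates.unique()) - set(SPRING_DATES) - set(SUMMER_DATES)
    if unknown:
        raise ValueError(f"unknown date_index values: {sorted(unknown)}")
    spring = records.loc[dates.isin(SPRING_DATES)].copy()
    summer = records.loc[dates.isin(SUMMER_DATES)].copy()
    return spring, summer


class NMDSOrdination:
    """Model-style wrapper: community matrix in, fitted ordination out.

    ``NMDSOrdination(matrix).fit(seed=...)`` computes the Bray-Curtis
    dissimilarity (configurable to Euclidean or Jaccard), runs NMDS and,
    when a trait table is supplied, fits traits — returning an
    :class:`OrdinationResults`.
    """

    def __init__(
        self,
        community: pd.DataFrame,
        dissimilarity: str = "braycurtis",
        k: int = 2,
        traits: pd.DataFrame | None = None,
    ):
        if community.shape[0] < 2 or community.shape[1] < 2:
            raise ValueError("ordination requires at least a 2×2 community matrix")
        self.community = community
        self.dissimilarity = dissimilarity
        self.k = k
        self.traits = traits

    def _distance(self) -> pd.DataFrame:
        if self.dissimilarity == "braycurtis":
            return bray_curtis(self.community)
        if self.dissimilarity in ("euclidean", "jaccard"):
            D = squareform(pdist(self.community.to_numpy(float), self.dissimilarity))
            return pd.DataFrame(
                D, index=self.community.index, columns=self.community.index
            )
        raise ValueError(f"unknown dissimilarity {self.dissimilarity!r}")

    def fit(
        self, seed: int | None = 0, n_restarts: int = 8, n_permutations: int = 999
    ) -> OrdinationResults:
        result = nmds(self._distance(), k=self.k, n_restarts=n_restarts, seed=seed)
        if self.traits is not None:
            result = fit_traits(
                result, self.traits, n_permutations=n_permutations, seed=seed
            )
        return result
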