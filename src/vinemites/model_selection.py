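"""Multi-model AICc inference for vineyard density responses.

The analysis fits an additive Gaussian GLM (identity link, equivalent to
least squares on the log10(y+1)-transformed response) for every candidate
model in a pre-declared set, ranks them by the small-sample-corrected
Akaike Information Criterion

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1),

with k counting the intercept, slope coefficients and the residual
variance, and selects the parsimonious set {Δi <= 2} where
Δi = AICc_i - min AICc.

Candidate models are additive term sets (no interactions); predictors are
screened beforehand for pairwise collinearity (|Pearson r| >= 0.5 keeps a
pair out of the same model) and variance inflation (VIF > 5 flags a term
for removal).

The module is organised statsmodels-style: build a
:class:`DensityModelSelection` from the analysis table, call
:meth:`~DensityModelSelection.fit`, and read the ranked table, per-model
coefficients and ``summary()`` off the returned :class:`SelectionResults`.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: analysis-table categorical predictors and their closed level sets
CATEGORICAL_LEVELS = {
    "date": ("1", "2", "3", "4", "5"),
    "management": ("integrated", "organic"),
    "cover_crop": ("species_poor", "species_rich", "spontaneous"),
}

DELTA_THRESHOLD = 2.0
COLLINEARITY_THRESHOLD = 0.5
VIF_THRESHOLD = 5.0


# ---------------------------------------------------------------------------
# response transform
# ---------------------------------------------------------------------------

def transform_response(values):
    """log10(y + 1); densities are non-negative, zero maps to zero."""
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("densities must be non-negative before log10(y+1)")
    return np.log10(arr + 1.0)


def back_transform_response(values):
    """Inverse of :func:`transform_response`: 10**x - 1."""
    return np.power(10.0, np.asarray(values, dtype=float)) - 1.0


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _encode_term(table: pd.DataFrame, term: str) -> pd.DataFrame:
    """Columns for one additive term: treatment contrasts for categoricals
    (reference = first level, alphabetical unless configured), the column
    itself for numerics."""
    col = table[term]
    if term in CATEGORICAL_LEVELS or col.dtype == object or isinstance(
        col.dtype, pd.CategoricalDtype
    ):
        levels = CATEGORICAL_LEVELS.get(term)
        vals = col.astype(str)
        if levels is None:
            levels = tuple(sorted(vals.unique()))
        else:
            unknown = set(vals.unique()) - set(levels)
            if unknown:
                raise ValueError(f"unknown levels for {term!r}: {sorted(unknown)}")
        out = {}
        for lev in levels[1:]:
            out[f"{term}[{lev}]"] = (vals == lev).astype(float).to_numpy()
        return pd.DataFrame(out, index=table.index)
    return pd.DataFrame({term: col.astype(float).to_numpy()}, index=table.index)


def design_matrix(table: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    """Intercept + treatment-coded additive design for *terms*."""
    parts = [pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)]
    for term in terms:
        parts.append(_encode_term(table, term))
    return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------------
# predictor screening
# ---------------------------------------------------------------------------

def collinearity_screen(
    predictors: pd.DataFrame, threshold: float = COLLINEARITY_THRESHOLD
) -> tuple[list[tuple[str, str]], list[str]]:
    """Pairs of predictors too collinear to share a model.

    Returns ``(excluded_pairs, constant_columns)``: all unordered predictor
    pairs whose absolute Pearson correlation meets *threshold*, and any
    constant columns (flagged, not correlated). Categorical predictors are
    expanded to indicator contrasts; a pair is excluded when any contrast
    pair crosses the threshold.
    """
    if len(predictors) < 3:
        raise ValueError("collinearity screen requires at least 3 rows")
    encoded: dict[str, pd.DataFrame] = {
        term: _encode_term(predictors, term) for term in predictors.columns
    }
    constant = [
        term
        for term, block in encoded.items()
        if all(np.ptp(block[c].to_numpy()) == 0 for c in block.columns)
    ]
    pairs = []
    terms = [t for t in predictors.columns if t not in constant]
    for a, b in itertools.combinations(terms, 2):
        worst = 0.0
        for ca in encoded[a].columns:
            xa = encoded[a][ca].to_numpy()
            if np.ptp(xa) == 0:
                continue
            for cb in encoded[b].columns:
                xb = encoded[b][cb].to_numpy()
                if np.ptp(xb) == 0:
                    continue
                r = np.corrcoef(xa, xb)[0, 1]
                worst = max(worst, abs(r))
        if worst >= threshold:
            pairs.append((a, b))
            logger.info("collinearity: excluding pair (%s, %s), |r|max=%.3f", a, b, worst)
    return pairs, constant


def vif(predictors: pd.DataFrame, terms: tuple[str, ...] | None = None) -> pd.Series:
    """Variance inflation factors, VIF_j = 1/(1 - R²_j) from regressing each
    predictor column on the others (with intercept). Perfect collinearity
    reports ``inf``."""
    if terms is None:
        terms = tuple(predictors.columns)
    X = design_matrix(predictors, tuple(terms))
    cols = [c for c in X.columns if c != "Intercept"]
    out = {}
    for j in cols:
        y = X[j].to_numpy()
        others = X[[c for c in X.columns if c != j]].to_numpy()
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[j] = math.nan
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def vif_removals(predictors: pd.DataFrame, threshold: float = VIF_THRESHOLD) -> list[str]:
    """Design columns whose VIF exceeds *threshold* (reported for removal)."""
    v = vif(predictors)
    flagged = sorted(v.index[v > threshold])
    for name in flagged:
        logger.info("VIF: %s = %.2f > %.1f, flagged for removal", name, v[name], threshold)
    return flagged


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CandidateModel:
    """An additive model specification for one response."""

    response: str
    terms: tuple[str, ...]
    is_null: bool = False

    @property
    def label(self) -> str:
        return "null model" if self.is_null else " + ".join(self.terms)


def _violates(terms: tuple[str, ...], exclusions) -> bool:
    pairs = {frozenset(p) for p in exclusions}
    return any(
        frozenset((a, b)) in pairs for a, b in itertools.combinations(terms, 2)
    )


def enumerate_candidates(
    response: str,
    pool: tuple[str, ...],
    exclusions=(),
    max_extra_terms: int = 2,
    forced: tuple[str, ...] = ("date",),
    explicit: list[tuple[str, ...]] | None = None,
) -> list[CandidateModel]:
    """Build the candidate model set for one response.

    With an *explicit* list of term tuples (the reproduction surface for a
    published analysis) each model is validated against *exclusions* and
    used verbatim (the null model is added if absent). Otherwise the
    generator emits the null model, the forced terms alone (``date`` by
    default, which the published selections always retain), and the forced
    terms plus every combination of up to *max_extra_terms* further pool
    terms that respects the exclusion pairs.
    """
    if not pool and not explicit:
        raise ValueError("candidate pool is empty")
    models: list[CandidateModel] = [CandidateModel(response, (), is_null=True)]
    if explicit is not None:
        for terms in explicit:
            terms = tuple(terms)
            if _violates(terms, exclusions):
                raise ValueError(
                    f"explicit model {terms} violates a collinearity exclusion"
                )
            if terms:
                models.append(CandidateModel(response, terms))
        return models
    extras = tuple(t for t in pool if t not in forced)
    if forced:
        models.append(CandidateModel(response, tuple(forced)))
    seen = {m.terms for m in models}
    for size in range(1, max_extra_terms + 1):
        for combo in itertools.combinations(extras, size):
            terms = tuple(forced) + combo
            if _violates(terms, exclusions) or terms in seen:
                continue
            seen.add(terms)
            models.append(CandidateModel(response, terms))
    logger.info("enumerated %d candidate models for %s", len(models), response)
    return models


#: predictor pool for the study analysis (cross-response predictors are
#: appended per response by the pipeline)
STUDY_POOL = (
    "management",
    "cover_crop",
    "aaptlc",
    "n_applications_total",
    "vegetation_cover_spring",
    "vegetation_cover_summer",
    "pct_total_snh",
    "pct_vineyards",
    "min_dist_woody",
)

#: predictor pairs never allowed in the same model: the toxicity loading,
#: the application count and the summer ground cover all track management
#: (organic regimes are sulfur/copper-heavy and keep denser summer cover),
#: so these management-linked predictors stay out of each other's models
STUDY_EXCLUSIONS = (
    ("management", "aaptlc"),
    ("management", "n_applications_total"),
    ("aaptlc", "n_applications_total"),
    ("management", "vegetation_cover_summer"),
    ("n_applications_total", "vegetation_cover_summer"),
)


def load_model_config(path) -> dict:
    """Read a declared candidate-model configuration from YAML.

    The file maps each response name to a mapping with optional keys
    ``models`` (list of term lists, used verbatim), ``exclusions`` (list of
    term pairs), ``pool``, ``max_extra_terms`` and ``forced``. Returns a
    dict of per-response keyword arguments for :func:`enumerate_candidates`.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for response, spec in raw.items():
        spec = spec or {}
        out[response] = {
            "pool": tuple(spec.get("pool", STUDY_POOL)),
            "exclusions": [tuple(p) for p in spec.get("exclusions", STUDY_EXCLUSIONS)],
            "max_extra_terms": int(spec.get("max_extra_terms", 2)),
            "forced": tuple(spec.get("forced", ("date",))),
            "explicit": (
                [tuple(m) for m in spec["models"]] if "models" in spec else None
            ),
        }
    return out


def study_candidate_config() -> dict:
    """The package's documented 42-model configuration.

    Forced ``date``, the 9-term :data:`STUDY_POOL`, the 5
    :data:`STUDY_EXCLUSIONS` pairs and at most 2 non-date terms enumerate
    exactly 42 candidates: null + date + 9 single-extra models + 31
    exclusion-respecting pairs.
    """
    return {
        "pool": STUDY_POOL,
        "exclusions": STUDY_EXCLUSIONS,
        "max_extra_terms": 2,
        "forced": ("date",),
    }


# ---------------------------------------------------------------------------
# Gaussian GLM fit + AICc
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """One fitted candidate: Gaussian ML estimates and information criteria."""

    model: CandidateModel
    n: int
    k: int
    loglik: float
    aic: float
    aicc: float
    r2: float
    adj_r2: float
    params: pd.Series
    bse: pd.Series
    delta_i: float = math.nan

    @property
    def label(self) -> str:
        return self.model.label


def fit_gaussian_glm(
    model: CandidateModel, table: pd.DataFrame, response_col: str | None = None
) -> FitResult:
    """Fit one candidate by Gaussian maximum likelihood (identity link).

    The ML solution is the least-squares solve of the treatment-coded
    design; k counts the intercept, the slope coefficients and the residual
    variance. Requires n > k + 1 so the AICc correction is finite, and a
    full-rank design (aliased terms are named in the error).
    """
    response_col = response_col or model.response
    y = table[response_col].to_numpy(dtype=float)
    X = design_matrix(table, model.terms)
    n, p_full = X.shape
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < p_full:
        # identify aliased columns via QR pivoting on the gram matrix
        _, r = np.linalg.qr(Xv)
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in range(p_full) if diag[i] < 1e-10 * diag.max()]
        raise np.linalg.LinAlgError(
            f"rank-deficient design for model {model.label!r}; aliased terms: {aliased}"
        )
    k = p_full + 1  # + residual variance
    if n <= k + 1:
        raise ValueError(
            f"model {model.label!r}: n={n} too small for k={k} (need n > k + 1)"
        )
    beta, _, _, _ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ beta
    ss_res = float(resid @ resid)
    sigma2 = ss_res / n  # ML variance estimate
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    aic = -2.0 * loglik + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    p_slopes = p_full - 1
    adj_r2 = (
        1.0
        if ss_tot == 0
        else 1.0 - (1.0 - r2) * (n - 1.0) / (n - p_slopes - 1.0)
    )
    # classical OLS standard errors (unbiased variance) for reporting
    dof = n - p_full
    s2 = ss_res / dof if dof > 0 else math.nan
    cov = s2 * np.linalg.inv(Xv.T @ Xv)
    bse = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
    params = pd.Series(beta, index=X.columns)
    return FitResult(
        model=model, n=n, k=k, loglik=loglik, aic=aic, aicc=aicc,
        r2=r2, adj_r2=adj_r2, params=params, bse=bse,
    )


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def rank_models(
    fits: list[FitResult], delta_threshold: float = DELTA_THRESHOLD
) -> pd.DataFrame:
    """Rank fitted candidates by AICc and mark the parsimonious set.

    Δi = AICc_i − min AICc; the parsimonious set is {Δi <= threshold}.
    Exact AICc ties break by fewer parameters, then lexicographic term
    order (logged); the ranking is invariant to input order.
    """
    if not fits:
        raise ValueError("rank_models requires at least one fit")
    best = min(f.aicc for f in fits)
    for f in fits:
        f.delta_i = f.aicc - best
    ordered = sorted(fits, key=lambda f: (f.aicc, f.k, f.model.terms))
    for a, b in zip(ordered, ordered[1:]):
        if a.aicc == b.aicc:
            logger.info(
                "AICc tie between %r and %r broken by (k, term order)",
                a.label, b.label,
            )
    rows = [
        {
            "model": f.label,
            "terms": f.model.terms,
            "k": f.k,
            "loglik": f.loglik,
            "aicc": f.aicc,
            "delta_i": f.delta_i,
            "adj_r2": f.adj_r2,
            "selected": f.delta_i <= delta_threshold,
        }
        for f in ordered
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statsmodels-style model / results objects
# ---------------------------------------------------------------------------

class DensityModelSelection:
    """Multi-model AICc selection for one density response.

    Parameters
    ----------
    table : DataFrame
        Analysis table, one row per vineyard × sampling date, holding the
        raw (untransformed) response column and all predictor columns.
    response : str
        Name of the response column; it is log10(y+1)-transformed before
        fitting unless ``pre_transformed=True``.
    candidates : list[CandidateModel], optional
        Explicit candidate set; by default the study's 42-model
        configuration restricted to the columns present in *table*.
    delta_threshold : float
        Δi cut for the parsimonious set (2 by default).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        response: str,
        candidates: list[CandidateModel] | None = None,
        delta_threshold: float = DELTA_THRESHOLD,
        pre_transformed: bool = False,
    ):
        if response not in table.columns:
            raise KeyError(f"response column {response!r} not in table")
        self.response = response
        self.delta_threshold = float(delta_threshold)
        self.table = table.copy()
        self._ycol = f"__log10p1_{response}"
        if pre_transformed:
            self.table[self._ycol] = table[response].astype(float)
        else:
            self.table[self._ycol] = transform_response(table[response])
        if candidates is None:
            cfg = study_candidate_config()
            pool = tuple(t for t in cfg["pool"] if t in table.columns)
            candidates = enumerate_candidates(
                response,
                pool,
                exclusions=cfg["exclusions"],
                max_extra_terms=cfg["max_extra_terms"],
                forced=cfg["forced"],
            )
        self.candidates = candidates

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, response: str, **kwargs):
        """Alias constructor mirroring the statsmodels ``from_formula`` idiom."""
        return cls(table, response, **kwargs)

    def fit(self) -> "SelectionResults":
        fits = [
            fit_gaussian_glm(m, self.table, response_col=self._ycol)
            for m in self.candidates
        ]
        ranking = rank_models(fits, self.delta_threshold)
        return SelectionResults(self, fits, ranking)


class SelectionResults:
    """Ranked candidate fits for one response.

    Attributes
    ----------
    ranking : DataFrame
        Sorted selection table (model, k, loglik, AICc, Δi, adjusted R²,
        selected flag).
    fits : list[FitResult]
        All fits, in ranked order.
    """

    def __init__(self, model: DensityModelSelection, fits, ranking):
        self.model = model
        order = {tuple(t): i for i, t in enumerate(ranking["terms"])}
        self.fits = sorted(fits, key=lambda f: order[f.model.terms])
        self.ranking = ranking

    @property
    def best(self) -> FitResult:
        return self.fits[0]

    @property
    def parsimonious(self) -> list[FitResult]:
        """Fits with Δi within the threshold."""
        return [f for f in self.fits if f.delta_i <= self.model.delta_threshold]

    def selection_table(self) -> pd.DataFrame:
        """Publication-shaped table: model, AICc, Δi, adjusted R²."""
        return self.ranking[["model", "aicc", "delta_i", "adj_r2"]].rename(
            columns={"aicc": "AICc", "delta_i": "delta_i", "adj_r2": "adjusted_R2"}
        )

    def coefficients(self) -> pd.DataFrame:
        """Long table of estimates ± SE for every candidate."""
        rows = []
        for f in self.fits:
            for name in f.params.index:
                rows.append(
                    {
                        "model": f.label,
                        "term": name,
                        "estimate": f.params[name],
                        "se": f.bse[name],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable selection summary."""
        lines = [
            f"AICc model selection: response {self.model.response!r} "
            f"(log10(y+1) scale)",
            f"  candidates: {len(self.fits)}, n = {self.best.n}, "
            f"parsimonious set (Δi <= {self.model.delta_threshold:g}): "
            f"{len(self.parsimonious)}",
            "",
            self.ranking[["model", "k", "aicc", "delta_i", "adj_r2"]]
            .head(10)
            .to_string(
                index=False,
                formatters={
                    "aicc": "{:.2f}".format,
                    "delta_i": "{:.2f}".format,
                    "adj_r2": "{:.2f}".format,
                },
            ),
        ]
        best = self.best
        lines += ["", f"best model: {best.label}", "coefficients (estimate ± SE):"]
        for name in best.params.index:
            lines.append(f"  {name:30s} {best.params[name]:+.4f} ± {best.bse[name]:.4f}")
        return "\n".join(lines)

    def plot_effects(self, ax=None):
        """Bar plot of the best model's slope estimates with ±2 SE bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.5))
        best = self.best
        terms = [t for t in best.params.index if t != "Intercept"]
        est = best.params[terms]
        err = 2.0 * best.bse[terms]
        ax.barh(range(len(terms)), est, xerr=err, color="#4477aa")
        ax.set_yticks(range(len(terms)), terms)
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel("effect on log10(density + 1)")
        ax.set_title(f"{self.model.response}: {best.label}")
        return ax
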