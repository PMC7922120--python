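"""Area-related acute pesticide contact toxicity loading (aAPTLc) and the
categorical *Typhlodromus pyri* toxicity rating.

The aAPTLc is a per-vineyard hazard-quotient-times-persistence loading: for
every application of every active ingredient, the amount applied (g/ha,
product dose times ingredient concentration) is divided by the honeybee
contact LD50 (µg/bee) and weighted by the ingredient's soil half-life in
units of the mean residence time (half-life / ln 2), then summed and scaled
(default 1e-4, a display convention that must not change any rank-based
downstream result).

The categorical rating sums a fixed harm-class scale (harmless 0.4,
slightly harmful 0.8, harmful 1.0) over every applied active-ingredient
occurrence.

All functions operate on plain pandas tables matching the package's
interchange schemas (see :mod:`vinemites.io`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: numeric scale for the categorical T. pyri harm classes
HARM_CLASS_SCALE = {"harmless": 0.4, "slightly_harmful": 0.8, "harmful": 1.0}

#: closed set of application categories (spray-record `category` column)
APPLICATION_CATEGORIES = (
    "insecticide",
    "acaricide",
    "synthetic_fungicide",
    "sulfur",
    "copper",
    "potassium_bicarbonate",
    "other",
)

#: ingredient-specific fallback half-lives (days), table-driven and overridable
DEFAULT_HALF_LIVES = {"potassium_bicarbonate": 7.0}

DEFAULT_SCALING = 1e-4


class UnresolvableProductError(KeyError):
    """A spray record references a product absent from the product table."""


@dataclass
class ToxicityResult:
    """Per-vineyard toxicity summary."""

    vineyard_id: str
    aaptlc: float
    tpyri_rating: float
    excluded_ingredients: list[tuple[str, str]] = field(default_factory=list)
    n_applications_total: int = 0
    n_applications_by_category: dict[str, int] = field(default_factory=dict)


def _product_composition(products: pd.DataFrame) -> dict[str, list[tuple[str, float]]]:
    comp: dict[str, list[tuple[str, float]]] = {}
    for row in products.itertuples(index=False):
        pct = float(row.concentration_pct)
        if not (0.0 < pct <= 100.0):
            raise ValueError(
                f"concentration_pct for product {row.product!r} / ingredient "
                f"{row.ingredient!r} must be in (0, 100], got {pct}"
            )
        comp.setdefault(str(row.product), []).append((str(row.ingredient), pct))
    return comp


def active_ingredient_amounts(
    spray: pd.DataFrame, products: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Resolve spray records to applied active-ingredient amounts (g/ha).

    Parameters
    ----------
    spray : DataFrame
        Columns ``vineyard_id, date, product, dose_g_per_ha, category``
        (one vineyard's regime or several vineyards' records).
    products : DataFrame
        Long-format composition table, columns
        ``product, ingredient, concentration_pct``.

    Returns
    -------
    contributions : DataFrame
        One row per (application, ingredient) with columns
        ``vineyard_id, date, product, category, ingredient, amount_g_per_ha``.
        Individual per-application contributions are preserved because the
        toxicity loading sums over applications, not merely over ingredients.
    totals : Series
        Amount summed per ingredient (g/ha), indexed by ingredient name.

    Raises
    ------
    UnresolvableProductError
        If a spray row references a product absent from *products*.
    ValueError
        If any dose is negative.
    """
    comp = _product_composition(products)
    rows = []
    for rec in spray.itertuples(index=False):
        dose = float(rec.dose_g_per_ha)
        if dose < 0:
            raise ValueError(
                f"negative dose {dose} g/ha for product {rec.product!r} "
                f"in vineyard {rec.vineyard_id!r}"
            )
        name = str(rec.product)
        if name not in comp:
            raise UnresolvableProductError(
                f"product {name!r} not found in the product table"
            )
        for ingredient, pct in comp[name]:
            rows.append(
                {
                    "vineyard_id": rec.vineyard_id,
                    "date": rec.date,
                    "product": name,
                    "category": rec.category,
                    "ingredient": ingredient,
                    "amount_g_per_ha": dose * pct / 100.0,
                }
            )
    contributions = pd.DataFrame(
        rows,
        columns=[
            "vineyard_id", "date", "product", "category",
            "ingredient", "amount_g_per_ha",
        ],
    )
    totals = contributions.groupby("ingredient")["amount_g_per_ha"].sum() \
        if len(contributions) else pd.Series(dtype=float, name="amount_g_per_ha")
    return contributions, totals


def _ingredient_lookup(ingredients: pd.DataFrame) -> pd.DataFrame:
    tab = ingredients.set_index(ingredients["name"].astype(str))
    if tab.index.has_duplicates:
        dupes = sorted(tab.index[tab.index.duplicated()].unique())
        raise ValueError(f"duplicate ingredient entries: {dupes}")
    return tab


def aaptlc(
    spray: pd.DataFrame,
    ingredients: pd.DataFrame,
    products: pd.DataFrame,
    scaling: float = DEFAULT_SCALING,
    default_half_lives: dict[str, float] | None = None,
) -> tuple[float, list[tuple[str, str]]]:
    """Compute the area-related acute pesticide contact toxicity loading.

    score = scaling * sum over (application, ingredient) of
    (amount g/ha / LD50 µg/bee) * (half-life days / ln 2).

    Ingredients with a missing LD50 or half-life are excluded from the sum
    and reported; an ingredient listed in *default_half_lives* (by default
    potassium bicarbonate at 7 days) falls back to that half-life instead
    of being excluded.

    Returns ``(score, excluded)`` where *excluded* is a list of
    ``(ingredient, reason)`` tuples, one entry per distinct ingredient.
    """
    if scaling <= 0:
        raise ValueError(f"scaling must be positive, got {scaling}")
    if default_half_lives is None:
        default_half_lives = dict(DEFAULT_HALF_LIVES)
    contributions, _ = active_ingredient_amounts(spray, products)
    if contributions.empty:
        return 0.0, []
    tab = _ingredient_lookup(ingredients)
    ln2 = math.log(2.0)

    score = 0.0
    excluded: dict[str, str] = {}
    n_terms = 0
    for rec in contributions.itertuples(index=False):
        name = rec.ingredient
        if name not in tab.index:
            raise UnresolvableProductError(
                f"ingredient {name!r} not found in the ingredient table"
            )
        ld50 = tab.at[name, "ld50_contact_ug_per_bee"]
        half_life = tab.at[name, "half_life_days"]
        if pd.isna(half_life) and name in default_half_lives:
            half_life = default_half_lives[name]
            logger.info("aaptlc: using default half-life %.3g d for %s", half_life, name)
        if pd.isna(ld50):
            excluded[name] = "missing ld50_contact"
            continue
        if pd.isna(half_life):
            excluded[name] = "missing half_life"
            continue
        score += (rec.amount_g_per_ha / float(ld50)) * (float(half_life) / ln2)
        n_terms += 1
    if n_terms == 0 and len(excluded):
        logger.warning(
            "aaptlc: all ingredients excluded (%s); score is 0", sorted(excluded)
        )
    return scaling * score, sorted(excluded.items())


def tpyri_rating(
    spray: pd.DataFrame,
    ingredients: pd.DataFrame,
    products: pd.DataFrame,
) -> tuple[float, list[tuple[str, str]]]:
    """Categorical toxicity rating for *T. pyri*.

    Every (application, ingredient) occurrence contributes the scale value
    of the ingredient's harm class (harmless 0.4, slightly harmful 0.8,
    harmful 1.0); occurrences with an unknown harm class are excluded and
    reported per distinct ingredient.
    """
    contributions, _ = active_ingredient_amounts(spray, products)
    if contributions.empty:
        return 0.0, []
    tab = _ingredient_lookup(ingredients)
    score = 0.0
    excluded: dict[str, str] = {}
    for rec in contributions.itertuples(index=False):
        name = rec.ingredient
        if name not in tab.index:
            raise UnresolvableProductError(
                f"ingredient {name!r} not found in the ingredient table"
            )
        harm = tab.at[name, "harm_class"]
        if pd.isna(harm) or str(harm) == "unknown":
            excluded[name] = "unknown harm_class"
            continue
        harm = str(harm)
        if harm not in HARM_CLASS_SCALE:
            raise ValueError(
                f"ingredient {name!r} has harm_class {harm!r}; expected one of "
                f"{sorted(HARM_CLASS_SCALE)} or 'unknown'"
            )
        score += HARM_CLASS_SCALE[harm]
    return score, sorted(excluded.items())


def application_counts(spray: pd.DataFrame) -> tuple[int, dict[str, int]]:
    """Count applications in a spray regime.

    The total counts distinct application dates — several products applied
    on the same date form a single application. Per-category counts count
    product applications within each category.
    """
    by_category = {c: 0 for c in APPLICATION_CATEGORIES}
    if spray.empty:
        return 0, by_category
    unknown = set(spray["category"].astype(str)) - set(APPLICATION_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown application categories: {sorted(unknown)}")
    total = int(spray["date"].nunique())
    counts = spray["category"].value_counts()
    for cat, n in counts.items():
        by_category[str(cat)] = int(n)
    return total, by_category


def compute_toxicity(
    spray: pd.DataFrame,
    ingredients: pd.DataFrame,
    products: pd.DataFrame,
    scaling: float = DEFAULT_SCALING,
    default_half_lives: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-vineyard toxicity summary over a multi-vineyard spray table.

    Returns a DataFrame with one row per vineyard: ``aaptlc``,
    ``tpyri_rating``, ``n_applications_total``, one
    ``n_applications_<category>`` column per category, and semicolon-joined
    ``excluded_ingredients``. Vineyards are every unique ``vineyard_id`` in
    *spray*; a vineyard with an empty regime would simply be absent, so
    callers wanting explicit zero rows should reindex.
    """
    rows = []
    for vid, regime in spray.groupby("vineyard_id", sort=True):
        score, excl_a = aaptlc(regime, ingredients, products, scaling, default_half_lives)
        rating, excl_r = tpyri_rating(regime, ingredients, products)
        total, by_cat = application_counts(regime)
        excluded = sorted(set(excl_a) | set(excl_r))
        row = {
            "vineyard_id": vid,
            "aaptlc": score,
            "tpyri_rating": rating,
            "n_applications_total": total,
            "excluded_ingredients": ";".join(f"{n}:{r}" for n, r in excluded),
        }
        for cat in APPLICATION_CATEGORIES:
            row[f"n_applications_{cat}"] = by_cat[cat]
        rows.append(row)
    return pd.DataFrame(rows)
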