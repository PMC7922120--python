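"""Leaf-wash mite counts and sticky-tape pollen counts to per-area densities.

Mite counts from a leaf wash of 25 vine leaves are normalised by the
measured total leaf area to individuals per 100 cm² leaf area. Pollen
grains counted on transects of a 19 × 19 mm sticky-tape square are
extrapolated to grains per cm² using the counted fraction of the square.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

MITE_TAXA = (
    "phytoseiid",
    "tydeoid",
    "eriophyoid_colomerus",
    "eriophyoid_calepitrimerus",
    "spider_mite",
)

ERIOPHYOID_SOURCES = ("eriophyoid_colomerus", "eriophyoid_calepitrimerus")

#: morphologically indistinguishable pollen families merged before analysis
DEFAULT_POLLEN_MERGE_RULES = {
    "Amaranthaceae": "Amaranthaceae/Caryophyllaceae",
    "Caryophyllaceae": "Amaranthaceae/Caryophyllaceae",
    "Moraceae": "Moraceae/Urticaceae",
    "Urticaceae": "Moraceae/Urticaceae",
}

#: unidentifiable / coarse pollen categories that pass through merges
POLLEN_PASSTHROUGH = ("AP", "NAP", "NA")


def mite_density(samples: pd.DataFrame) -> pd.DataFrame:
    """Convert leaf-wash counts to densities per 100 cm² leaf area.

    Parameters
    ----------
    samples : DataFrame
        Long format: ``vineyard_id, date_index, taxon, count, leaf_area_cm2``.
        ``leaf_area_cm2`` is the total measured area of the washed leaves and
        must be constant within a vineyard-date.

    Returns
    -------
    DataFrame in the same long layout with a ``density_per_100cm2`` column
    (count / leaf_area × 100) replacing ``count``.
    """
    if (samples["count"] < 0).any():
        raise ValueError("mite counts must be non-negative")
    if (samples["leaf_area_cm2"] <= 0).any():
        bad = samples.loc[samples["leaf_area_cm2"] <= 0]
        raise ValueError(
            f"leaf_area_cm2 must be positive; offending rows: {bad.index.tolist()}"
        )
    out = samples.copy()
    out["density_per_100cm2"] = out["count"] / out["leaf_area_cm2"] * 100.0
    return out.drop(columns=["count"])


def merge_eriophyoid(densities: pd.DataFrame) -> pd.DataFrame:
    """Merge the two eriophyoid species into a single ``eriophyoid`` taxon.

    Operates on the long density table; the merged density is the sum of
    the species densities for each vineyard-date. Idempotent: records
    already carrying only the merged taxon pass through unchanged.
    """
    is_source = densities["taxon"].isin(ERIOPHYOID_SOURCES)
    if not is_source.any():
        return densities.copy()
    merged = (
        densities.loc[is_source]
        .groupby(["vineyard_id", "date_index"], as_index=False)
        .agg(
            density_per_100cm2=("density_per_100cm2", "sum"),
            leaf_area_cm2=("leaf_area_cm2", "first"),
        )
    )
    merged["taxon"] = "eriophyoid"
    rest = densities.loc[~is_source]
    out = pd.concat([rest, merged], ignore_index=True)
    return out.sort_values(["vineyard_id", "date_index", "taxon"]).reset_index(drop=True)


def relative_abundance(tally: dict[str, int] | pd.Series) -> pd.Series:
    """Percent share of each species in a family tally.

    Percentages sum to 100 (to numerical precision); internal values stay
    at full precision — round only for reporting.
    """
    counts = pd.Series(tally, dtype=float)
    if counts.empty or counts.sum() <= 0:
        raise ValueError("relative_abundance requires a non-empty tally with total > 0")
    if (counts < 0).any():
        raise ValueError("species counts must be non-negative")
    return 100.0 * counts / counts.sum()


def pollen_density(samples: pd.DataFrame) -> pd.DataFrame:
    """Extrapolate transect pollen counts to grains per cm².

    grains_per_cm2 = grains / (counted_fraction × square_area_cm²), with
    square_area_cm² = (square_side_mm / 10)² — 3.61 cm² for the protocol's
    19 mm square. ``counted_fraction`` is the fraction of the square area
    covered by the counted transects and must lie in (0, 1].
    """
    frac = samples["counted_fraction"]
    if ((frac <= 0) | (frac > 1)).any():
        raise ValueError("counted_fraction must lie in (0, 1]")
    if (samples["grains"] < 0).any():
        raise ValueError("pollen grain counts must be non-negative")
    out = samples.copy()
    area_cm2 = (out["square_side_mm"] / 10.0) ** 2
    out["grains_per_cm2"] = out["grains"] / (frac * area_cm2)
    return out.drop(columns=["grains"])


def merge_pollen_types(
    densities: pd.DataFrame,
    rules: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Merge pollen types per the configured source→target rules.

    The target's density is the sum of its sources; AP/NAP/NA categories
    and unmapped types pass through unchanged. Total density is conserved.
    A source appearing as the source of two different targets is rejected
    (dict keys are unique, but a source may not also be a target of a
    different merge).
    """
    if rules is None:
        rules = dict(DEFAULT_POLLEN_MERGE_RULES)
    targets = set(rules.values())
    for src, tgt in rules.items():
        if src in POLLEN_PASSTHROUGH:
            raise ValueError(f"category {src!r} cannot be merged")
        # a source that is also another rule's target would be mapped twice
        if src in targets and tgt != src:
            raise ValueError(
                f"pollen type {src!r} is both a merge target and a merge "
                f"source (to {tgt!r}); rules must be disjoint"
            )
    out = densities.copy()
    out["pollen_type"] = out["pollen_type"].map(lambda t: rules.get(t, t))
    keys = [c for c in ("vineyard_id", "date_index") if c in out.columns]
    grouped = out.groupby(keys + ["pollen_type"], as_index=False).agg(
        {c: "sum" if c == "grains_per_cm2" else "first"
         for c in out.columns if c not in keys + ["pollen_type"]}
    )
    return grouped


def total_pollen_density(
    densities: pd.DataFrame, include_na: bool = True
) -> pd.DataFrame:
    """Total grains per cm² per vineyard-date.

    ``include_na=False`` drops the unidentifiable NA category from the
    total (composition analyses exclude it; totals include it by default).
    """
    d = densities if include_na else densities.loc[densities["pollen_type"] != "NA"]
    return (
        d.groupby(["vineyard_id", "date_index"], as_index=False)["grains_per_cm2"]
        .sum()
        .rename(columns={"grains_per_cm2": "total_per_cm2"})
    )
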