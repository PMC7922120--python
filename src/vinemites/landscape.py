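"""Landscape composition within 500-m circles around focal vineyards.

Habitat patches (pre-classified, pre-delimited by ``circle_id``) are
aggregated into four composition percentages — woody semi-natural habitats
(SNHs), total SNHs, vineyards, total agriculture — plus Shannon's landscape
diversity index (SHDI, nats) and the minimum edge-to-edge distance from the
focal vineyard to the nearest woody SNH patch.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: habitat classes entering the statistical analysis
ANALYZED_CLASSES = (
    "hedgerow",
    "solitary_trees",
    "tree_rows",
    "woodland",
    "fallow",
    "grassland",
    "grass_strip",
    "vineyard",
    "arable_crops",
    "orchard",
    "scrub",
    "garden",
    "ruderal_vegetation",
    "reed",
)

#: classes mapped but excluded from the analysis (they still occupy circle area)
EXCLUDED_CLASSES = ("artificial", "ponds_rivers", "roads", "yards")

ALL_CLASSES = ANALYZED_CLASSES + EXCLUDED_CLASSES

WOODY_SNH_CLASSES = ("hedgerow", "solitary_trees", "tree_rows", "woodland")
TOTAL_SNH_CLASSES = WOODY_SNH_CLASSES + ("fallow", "grassland", "grass_strip")
AGRICULTURE_CLASSES = ("vineyard", "arable_crops")

#: grouping map from composition parameter to its habitat classes
DEFAULT_GROUPING = {
    "pct_woody_snh": WOODY_SNH_CLASSES,
    "pct_total_snh": TOTAL_SNH_CLASSES,
    "pct_vineyards": ("vineyard",),
    "pct_total_agriculture": AGRICULTURE_CLASSES,
}


def _check_classes(patches: pd.DataFrame) -> None:
    unknown = set(patches["habitat_class"].astype(str)) - set(ALL_CLASSES)
    if unknown:
        raise ValueError(f"unknown habitat classes: {sorted(unknown)}")
    if (patches["area_m2"] <= 0).any():
        raise ValueError("patch areas must be positive")


def composition(
    patches: pd.DataFrame,
    grouping: dict[str, tuple[str, ...]] | None = None,
    analyzed_only: bool = False,
) -> pd.Series:
    """Composition percentages for the patches of one landscape circle.

    Each percentage is 100 × grouped area / denominator area. The default
    denominator is the full circle area including the four excluded classes
    (their patches physically occupy the circle); ``analyzed_only=True``
    restricts the denominator to the 14 analysed classes.
    """
    if grouping is None:
        grouping = DEFAULT_GROUPING
    _check_classes(patches)
    by_class = patches.groupby("habitat_class")["area_m2"].sum()
    if analyzed_only:
        denom = by_class.reindex(ANALYZED_CLASSES, fill_value=0.0).sum()
    else:
        denom = by_class.sum()
    if denom <= 0:
        raise ValueError("total patch area must be positive")
    out = {}
    for name, classes in grouping.items():
        area = by_class.reindex(classes, fill_value=0.0).sum()
        out[name] = 100.0 * area / denom
    return pd.Series(out)


def shdi(patches: pd.DataFrame, analyzed_only: bool = False) -> float:
    """Shannon's landscape diversity index, −Σ p ln p over class area shares.

    Zero-area classes contribute nothing; a single-class circle has SHDI 0.
    """
    _check_classes(patches)
    sub = patches
    if analyzed_only:
        sub = patches.loc[patches["habitat_class"].isin(ANALYZED_CLASSES)]
    areas = sub.groupby("habitat_class")["area_m2"].sum()
    total = areas.sum()
    if total <= 0:
        raise ValueError("total patch area must be positive")
    p = (areas / total).to_numpy()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def min_distance_to_woody(vineyard_geometry, woody_geometries) -> float:
    """Minimum edge-to-edge distance (m) from the focal vineyard polygon to
    any woody-SNH polygon of its circle.

    Geometries must share a projected metric coordinate system. Adjacent or
    overlapping polygons give 0. With no woody patch in the circle the
    distance is undefined: NaN is returned with a warning (never 0).
    """
    woody = list(woody_geometries)
    if not woody:
        warnings.warn(
            "no woody SNH patch in circle; minimum distance is undefined",
            stacklevel=2,
        )
        return math.nan
    return float(min(vineyard_geometry.distance(g) for g in woody))


def circle_metrics(
    patches: pd.DataFrame,
    analyzed_only: bool = False,
    distances: pd.Series | None = None,
    geometries: dict | None = None,
    vineyard_geometries: dict | None = None,
) -> pd.DataFrame:
    """Composition, SHDI and woody-SNH distance for every circle in *patches*.

    ``distances`` (indexed by circle_id) supplies precomputed minimum
    distances verbatim; alternatively ``geometries`` maps patch_id to a
    shapely geometry and ``vineyard_geometries`` maps circle_id to the
    focal vineyard polygon, in which case distances are computed.
    """
    rows = []
    for cid, sub in patches.groupby("circle_id", sort=True):
        row = composition(sub, analyzed_only=analyzed_only).to_dict()
        row["circle_id"] = cid
        row["shdi"] = shdi(sub, analyzed_only=analyzed_only)
        dist = math.nan
        if distances is not None and cid in distances.index:
            dist = float(distances.loc[cid])
        elif geometries is not None and vineyard_geometries is not None:
            woody = [
                geometries[p.patch_id]
                for p in sub.itertuples(index=False)
                if p.habitat_class in WOODY_SNH_CLASSES and p.patch_id in geometries
            ]
            if cid in vineyard_geometries:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    dist = min_distance_to_woody(vineyard_geometries[cid], woody)
        row["min_dist_woody"] = dist
        rows.append(row)
    cols = ["circle_id", *DEFAULT_GROUPING.keys(), "shdi", "min_dist_woody"]
    return pd.DataFrame(rows)[cols]
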