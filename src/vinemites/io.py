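"""Readers, writers and schema validation for the delimited interchange
tables (UTF-8, comma-separated, ``.`` decimal, ISO-8601 dates).

Every pipeline input has a declared schema; :func:`validate_inputs` checks
column presence, types, closed categorical sets and ranges, and reports
fatal errors (schema violations) separately from recoverable warnings
(expected missing toxicology values, absent optional files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import ALL_CLASSES
from .toxicity import APPLICATION_CATEGORIES

logger = logging.getLogger(__name__)

HARM_CLASSES = ("harmless", "slightly_harmful", "harmful", "unknown")

MITE_TAXA_ALLOWED = (
    "phytoseiid",
    "tydeoid",
    "eriophyoid_colomerus",
    "eriophyoid_calepitrimerus",
    "eriophyoid",
    "spider_mite",
)


@dataclass
class ValidationReport:
    """Outcome of schema validation: fatal errors and recoverable warnings."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def extend(self, other: "ValidationReport") -> None:
        self.errors.extend(other.errors)
        self.warnings.extend(other.warnings)

    def raise_if_failed(self) -> None:
        if self.errors:
            raise SchemaError("\n".join(self.errors))

    def __str__(self) -> str:
        lines = [f"{len(self.errors)} error(s), {len(self.warnings)} warning(s)"]
        lines += [f"ERROR: {e}" for e in self.errors]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)


class SchemaError(ValueError):
    """A fatal schema violation in an input table."""


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _require_columns(df: pd.DataFrame, cols, name: str, rep: ValidationReport) -> bool:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        rep.errors.append(f"{name}: missing columns {missing}")
        return False
    return True


def _check_rows(df, mask, name, message, rep, fatal=True):
    idx = df.index[mask].tolist()
    if idx:
        target = rep.errors if fatal else rep.warnings
        target.append(f"{name}: {message} (rows {idx[:10]}{'...' if len(idx) > 10 else ''})")


def validate_spray(df: pd.DataFrame) -> ValidationReport:
    rep = ValidationReport()
    if not _require_columns(
        df, ["vineyard_id", "date", "product", "dose_g_per_ha", "category"],
        "spray", rep,
    ):
        return rep
    _check_rows(df, pd.to_numeric(df["dose_g_per_ha"], errors="coerce") < 0,
                "spray", "negative dose_g_per_ha", rep)
    _check_rows(df, pd.to_numeric(df["dose_g_per_ha"], errors="coerce").isna(),
                "spray", "non-numeric dose_g_per_ha", rep)
    _check_rows(df, ~df["category"].astype(str).isin(APPLICATION_CATEGORIES),
                "spray", "category outside the closed set", rep)
    _check_rows(df, pd.to_datetime(df["date"], errors="coerce").isna(),
                "spray", "unparseable ISO date", rep)
    return rep


def validate_ingredients(df: pd.DataFrame) -> ValidationReport:
    rep = ValidationReport()
    if not _require_columns(
        df, ["name", "ld50_contact_ug_per_bee", "half_life_days", "harm_class"],
        "ingredients", rep,
    ):
        return rep
    ld50 = pd.to_numeric(df["ld50_contact_ug_per_bee"], errors="coerce")
    hl = pd.to_numeric(df["half_life_days"], errors="coerce")
    _check_rows(df, ld50 <= 0, "ingredients", "non-positive ld50_contact", rep)
    _check_rows(df, hl <= 0, "ingredients", "non-positive half_life", rep)
    _check_rows(df, df["ld50_contact_ug_per_bee"].isna(), "ingredients",
                "missing ld50_contact (ingredient will be excluded)", rep, fatal=False)
    _check_rows(df, df["half_life_days"].isna(), "ingredients",
                "missing half_life (excluded unless a default applies)", rep, fatal=False)
    harm = df["harm_class"].fillna("unknown").astype(str)
    _check_rows(df, ~harm.isin(HARM_CLASSES), "ingredients",
                "harm_class outside the closed set", rep)
    return rep


def validate_products(df: pd.DataFrame) -> ValidationReport:
    rep = ValidationReport()
    if not _require_columns(df, ["product", "ingredient", "concentration_pct"],
                            "products", rep):
        return rep
    pct = pd.to_numeric(df["concentration_pct"], errors="coerce")
    _check_rows(df, (pct <= 0) | (pct > 100), "products",
                "concentration_pct outside (0, 100]", rep)
    return rep


def validate_mites(df: pd.DataFrame) -> ValidationReport:
    rep = ValidationReport()
    if not _require_columns(
        df, ["vineyard_id", "date_index", "taxon", "count", "leaf_area_cm2"],
        "mites", rep,
    ):
        return rep
    _check_rows(df, ~df["date_index"].astype(int).isin(range(1, 6)),
                "mites", "date_index outside 1-5", rep)
    _check_rows(df, pd.to_numeric(df["count"], errors="coerce") < 0,
                "mites", "negative count", rep)
    _check_rows(df, pd.to_numeric(df["leaf_area_cm2"], errors="coerce") <= 0,
                "mites", "non-positive leaf_area_cm2", rep)
    _check_rows(df, ~df["taxon"].astype(str).isin(MITE_TAXA_ALLOWED),
                "mites", "unknown taxon", rep)
    return rep


def validate_pollen(df: pd.DataFrame) -> ValidationReport:
    rep = ValidationReport()
    if not _require_columns(
        df,
        ["vineyard_id", "date_index", "pollen_type", "grains",
         "counted_fraction", "square_side_mm"],
        "pollen", rep,
    ):
        return rep
    frac = pd.to_numeric(df["counted_fraction"], errors="coerce")
    _check_rows(df, (frac <= 0) | (frac > 1), "pollen",
                "counted_fraction outside (0, 1]", rep)
    _check_rows(df, pd.to_numeric(df["grains"], errors="coerce") < 0,
                "pollen", "negative grains", rep)
    _check_rows(df, pd.to_numeric(df["square_side_mm"], errors="coerce") <= 0,
                "pollen", "non-positive square_side_mm", rep)
    return rep


def validate_patches(df: pd.DataFrame) -> ValidationReport:
    rep = ValidationReport()
    if not _require_columns(df, ["patch_id", "circle_id", "habitat_class", "area_m2"],
                            "patches", rep):
        return rep
    _check_rows(df, pd.to_numeric(df["area_m2"], errors="coerce") <= 0,
                "patches", "non-positive area_m2", rep)
    _check_rows(df, ~df["habitat_class"].astype(str).isin(ALL_CLASSES),
                "patches", "habitat_class outside the closed set", rep)
    return rep


def validate_metadata(df: pd.DataFrame) -> ValidationReport:
    rep = ValidationReport()
    if not _require_columns(
        df,
        ["vineyard_id", "circle_id", "management", "cover_crop",
         "vegetation_cover_spring", "vegetation_cover_summer"],
        "vineyards", rep,
    ):
        return rep
    _check_rows(df, ~df["management"].astype(str).isin(["organic", "integrated"]),
                "vineyards", "management outside {organic, integrated}", rep)
    _check_rows(
        df,
        ~df["cover_crop"].astype(str).isin(
            ["species_poor", "species_rich", "spontaneous"]),
        "vineyards", "cover_crop outside the closed set", rep,
    )
    for col in ("vegetation_cover_spring", "vegetation_cover_summer"):
        v = pd.to_numeric(df[col], errors="coerce")
        _check_rows(df, (v < 0) | (v > 100), "vineyards",
                    f"{col} outside 0-100", rep)
    return rep


_VALIDATORS = {
    "spray": validate_spray,
    "ingredients": validate_ingredients,
    "products": validate_products,
    "mites": validate_mites,
    "pollen": validate_pollen,
    "patches": validate_patches,
    "vineyards": validate_metadata,
}


def validate_inputs(paths: dict[str, str | Path]) -> ValidationReport:
    """Validate every provided input file against its schema.

    *paths* maps table kind (spray, ingredients, products, mites, pollen,
    patches, vineyards) to a file path. Unknown kinds are an error;
    unreadable files are fatal.
    """
    rep = ValidationReport()
    for kind, path in paths.items():
        if kind not in _VALIDATORS:
            rep.errors.append(f"unknown input kind {kind!r}")
            continue
        try:
            df = read_table(path)
        except Exception as exc:  # noqa: BLE001 - report any read failure
            rep.errors.append(f"{kind}: cannot read {path}: {exc}")
            continue
        sub = _VALIDATORS[kind](df)
        rep.extend(sub)
        logger.info("validated %s (%s): %d errors, %d warnings",
                    kind, path, len(sub.errors), len(sub.warnings))
    return rep


def read_geojson_patches(path: str | Path) -> dict:
    """Patch geometries from a GeoJSON FeatureCollection keyed by patch_id.

    Coordinates must be in a projected metric system.
    """
    from shapely.geometry import shape

    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise SchemaError("geometry file must be a GeoJSON FeatureCollection")
    out = {}
    for feat in data.get("features", []):
        pid = feat.get("properties", {}).get("patch_id")
        if pid is None:
            raise SchemaError("every feature needs a properties.patch_id")
        out[str(pid)] = shape(feat["geometry"])
    return out


# ---------------------------------------------------------------------------
# deposit adapter
# ---------------------------------------------------------------------------

#: column-rename maps from deposit-style spreadsheets to the package schemas;
#: the only component expected to change on inspection of an actual deposit
DEPOSIT_COLUMN_MAP = {
    "spray": {
        "Vineyard": "vineyard_id",
        "Date": "date",
        "Product": "product",
        "Dose_g_ha": "dose_g_per_ha",
        "Category": "category",
    },
    "mites": {
        "Vineyard": "vineyard_id",
        "SamplingDate": "date_index",
        "Taxon": "taxon",
        "Count": "count",
        "LeafArea_cm2": "leaf_area_cm2",
    },
    "pollen": {
        "Vineyard": "vineyard_id",
        "SamplingDate": "date_index",
        "PollenType": "pollen_type",
        "Grains": "grains",
        "CountedFraction": "counted_fraction",
        "SquareSide_mm": "square_side_mm",
    },
}


def adapt_deposit_table(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Map a deposit-shaped table onto the package schema for *kind*.

    Columns already matching the schema pass through; known deposit
    spellings are renamed. Unmapped extra columns are preserved.
    """
    if kind not in DEPOSIT_COLUMN_MAP:
        raise KeyError(f"no deposit adapter for table kind {kind!r}")
    return df.rename(columns=DEPOSIT_COLUMN_MAP[kind])
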