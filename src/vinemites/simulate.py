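"""Synthetic paired-vineyard studies with known ground truth.

The generator emulates the study design the pipeline targets: 16 landscape
circles each holding one organic and one integrated vineyard, three
inter-row cover-crop types, five sampling dates with seasonally declining
mite densities, an early-June (date 2) pollen peak, near-zero zero-inflated
eriophyoid counts, absent spider mites, management-specific spray regimes
(organic = sulfur/copper/potassium-bicarbonate-heavy, integrated =
synthetic-fungicide-based), and landscape circles whose total
semi-natural-habitat share spans 10-55%.

Density effects are injected on the log10(y+1) scale — the scale of the
downstream Gaussian GLMs — so model-recovery experiments have an exact
generating model. Everything is driven by one integer seed; identical
config + seed reproduces the study byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .landscape import (
    ANALYZED_CLASSES,
    EXCLUDED_CLASSES,
    TOTAL_SNH_CLASSES,
    WOODY_SNH_CLASSES,
)

CIRCLE_RADIUS_M = 500.0
CIRCLE_AREA_M2 = math.pi * CIRCLE_RADIUS_M**2

RESPONSES = ("phytoseiid", "tydeoid", "eriophyoid", "pollen")

#: per-application product doses (g/ha) by category
_DOSES = {
    "sulfur": 3500.0,
    "copper": 2000.0,
    "potassium_bicarbonate": 5000.0,
    "synthetic_fungicide": 1500.0,
    "insecticide": 200.0,
    "acaricide": 1000.0,
}

#: mean ± sd application counts per category, organic / integrated
_SPRAY_PROFILE = {
    "organic": {
        "insecticide": (0.0, 0.0),
        "acaricide": (0.25, 0.45),
        "synthetic_fungicide": (0.0, 0.0),
        "sulfur": (9.19, 1.6),
        "copper": (8.88, 1.84),
        "potassium_bicarbonate": (4.44, 2.76),
    },
    "integrated": {
        "insecticide": (0.25, 0.45),
        "acaricide": (0.38, 0.5),
        "synthetic_fungicide": (5.79, 2.58),
        "sulfur": (4.13, 1.84),
        "copper": (1.25, 0.83),
        "potassium_bicarbonate": (0.0, 0.0),
    },
}


def reference_ingredients() -> pd.DataFrame:
    """Example active-ingredient table with plausible toxicology.

    Honeybee contact LD50s and soil half-lives are in the ranges published
    for these compounds; harm classes store the worst published rating per
    ingredient. Potassium bicarbonate ships with a blank half-life (the
    configured 7-day default applies) and azadirachtin with a blank LD50 to
    exercise the exclusion path.
    """
    rows = [
        ("sulfur", 400.0, 30.0, "slightly_harmful"),
        ("copper_hydroxide", 57.0, 1000.0, "harmless"),
        ("potassium_bicarbonate", 332.0, np.nan, "harmless"),
        ("folpet", 236.0, 4.7, "slightly_harmful"),
        ("cymoxanil", 25.0, 0.7, "harmless"),
        ("lambda_cyhalothrin", 0.038, 175.0, "harmful"),
        ("fenpyroximate", 15.1, 25.0, "slightly_harmful"),
        ("azadirachtin", np.nan, 25.0, "harmless"),
    ]
    return pd.DataFrame(
        rows, columns=["name", "ld50_contact_ug_per_bee", "half_life_days", "harm_class"]
    )


def reference_products() -> pd.DataFrame:
    """Example product composition table (long format)."""
    rows = [
        ("Sulfur 80 WG", "sulfur", 80.0),
        ("CopperShield", "copper_hydroxide", 50.0),
        ("Bicarb Plus", "potassium_bicarbonate", 85.0),
        ("FungiMix Duo", "folpet", 25.0),
        ("FungiMix Duo", "cymoxanil", 5.0),
        ("PyreStrike", "lambda_cyhalothrin", 5.0),
        ("AcaStop", "fenpyroximate", 5.0),
        ("AcaStop", "azadirachtin", 1.0),
    ]
    return pd.DataFrame(rows, columns=["product", "ingredient", "concentration_pct"])


_CATEGORY_PRODUCT = {
    "sulfur": "Sulfur 80 WG",
    "copper": "CopperShield",
    "potassium_bicarbonate": "Bicarb Plus",
    "synthetic_fungicide": "FungiMix Duo",
    "insecticide": "PyreStrike",
    "acaricide": "AcaStop",
}

#: seasonal pollen-type weights (date 1-2 tree-heavy spring, 3-5 summer)
_POLLEN_TYPES = (
    "Poaceae", "Plantaginaceae", "Pinaceae", "Betulaceae", "Juglandaceae",
    "Amaranthaceae", "Caryophyllaceae", "Moraceae", "Urticaceae",
    "Asteraceae", "AP", "NAP", "NA",
)
_POLLEN_WEIGHTS_SPRING = np.array(
    [0.42, 0.06, 0.12, 0.09, 0.04, 0.03, 0.02, 0.02, 0.03, 0.02, 0.06, 0.05, 0.04]
)
_POLLEN_WEIGHTS_SUMMER = np.array(
    [0.62, 0.10, 0.04, 0.01, 0.01, 0.04, 0.02, 0.01, 0.04, 0.03, 0.02, 0.02, 0.04]
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Effect sizes are on the log10(y+1) density scale. Landscape slopes are
    per percentage point of the (mean-centred) composition predictor;
    ``min_dist_woody`` slope is per metre.
    """

    n_pairs: int = 16
    seed: int = 0

    # date baselines per response: transformed mean at dates 1..5
    date_profile: dict = field(default_factory=lambda: {
        "phytoseiid": (0.91, 0.74, 0.65, 0.57, 0.50),
        "tydeoid": (0.65, 0.50, 0.32, 0.18, 0.15),
        "eriophyoid": (0.26, 0.20, 0.14, 0.10, 0.08),
        "pollen": (1.79, 2.14, 1.95, 1.74, 1.57),
    })
    # additive effects (log10 scale), keyed by response
    management_effect: dict = field(default_factory=lambda: {
        "phytoseiid": -0.20, "tydeoid": -0.10, "eriophyoid": 0.0, "pollen": -0.15,
    })  # effect of organic relative to integrated
    cover_crop_effect: dict = field(default_factory=lambda: {
        "phytoseiid": {"species_poor": 0.0, "species_rich": 0.05, "spontaneous": 0.20},
        "tydeoid": {"species_poor": 0.0, "species_rich": 0.05, "spontaneous": 0.25},
        "eriophyoid": {"species_poor": 0.0, "species_rich": 0.0, "spontaneous": 0.0},
        "pollen": {"species_poor": 0.0, "species_rich": 0.08, "spontaneous": 0.12},
    })
    pct_vineyards_effect: dict = field(default_factory=lambda: {
        "phytoseiid": 0.010, "tydeoid": 0.006, "eriophyoid": -0.008, "pollen": -0.004,
    })
    pct_total_snh_effect: dict = field(default_factory=lambda: {
        "phytoseiid": -0.010, "tydeoid": 0.0, "eriophyoid": 0.0, "pollen": 0.0,
    })
    min_dist_woody_effect: dict = field(default_factory=lambda: {
        "phytoseiid": 0.0, "tydeoid": 0.0, "eriophyoid": 0.0, "pollen": 0.0008,
    })
    veg_summer_effect: dict = field(default_factory=lambda: {
        "phytoseiid": 0.0, "tydeoid": 0.0, "eriophyoid": 0.004, "pollen": 0.0,
    })
    residual_sd: dict = field(default_factory=lambda: {
        "phytoseiid": 0.15, "tydeoid": 0.15, "eriophyoid": 0.08, "pollen": 0.12,
    })

    eriophyoid_zero_inflation: float = 0.5
    spray_profile: dict = field(default_factory=lambda: {
        m: dict(v) for m, v in _SPRAY_PROFILE.items()
    })
    snh_share_range: tuple = (0.10, 0.55)
    counted_fraction: float = 0.10  # 4 transects of the 19 mm tape square
    square_side_mm: float = 19.0
    n_leaves: int = 25
    leaf_area_range_cm2: tuple = (100.0, 200.0)

    def zeroed(self) -> "SyntheticConfig":
        """Copy with every density effect (incl. date structure) nulled —
        the generating model is then the intercept-only null model."""
        cfg = dataclasses.replace(self)
        cfg.date_profile = {
            r: tuple([np.mean(v)] * 5) for r, v in self.date_profile.items()
        }
        cfg.management_effect = {r: 0.0 for r in RESPONSES}
        cfg.cover_crop_effect = {
            r: {lvl: 0.0 for lvl in lv} for r, lv in self.cover_crop_effect.items()
        }
        cfg.pct_vineyards_effect = {r: 0.0 for r in RESPONSES}
        cfg.pct_total_snh_effect = {r: 0.0 for r in RESPONSES}
        cfg.min_dist_woody_effect = {r: 0.0 for r in RESPONSES}
        cfg.veg_summer_effect = {r: 0.0 for r in RESPONSES}
        return cfg


@dataclass
class SyntheticStudy:
    """A complete generated study: every pipeline input plus ground truth."""

    metadata: pd.DataFrame
    spray: pd.DataFrame
    ingredients: pd.DataFrame
    products: pd.DataFrame
    mite_samples: pd.DataFrame
    pollen_samples: pd.DataFrame
    patches: pd.DataFrame
    distances: pd.Series
    ground_truth: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metadata.to_csv(out / "vineyards.csv", index=False)
        self.spray.to_csv(out / "spray_records.csv", index=False)
        self.ingredients.to_csv(out / "ingredients.csv", index=False)
        self.products.to_csv(out / "products.csv", index=False)
        self.mite_samples.to_csv(out / "mite_counts.csv", index=False)
        self.pollen_samples.to_csv(out / "pollen_counts.csv", index=False)
        self.patches.to_csv(out / "habitat_patches.csv", index=False)
        self.distances.rename("min_dist_woody").rename_axis("circle_id").reset_index() \
            .to_csv(out / "woody_distances.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def generate_design(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Vineyard metadata: paired organic/integrated vineyards per circle,
    near-balanced cover-crop types, Table-1-like vegetation cover."""
    rows = []
    cover_levels = ("species_poor", "species_rich", "spontaneous")
    i = 0
    for p in range(config.n_pairs):
        cid = f"C{p + 1:02d}"
        for mgmt in ("organic", "integrated"):
            cover = cover_levels[i % 3]
            i += 1
            spring = float(np.clip(rng.normal(81.5, 19.0), 5.0, 100.0))
            if mgmt == "organic":
                summer = float(np.clip(rng.normal(61.7, 22.3), 0.0, 100.0))
            else:
                summer = float(np.clip(rng.normal(40.4, 24.8), 0.0, 100.0))
            rows.append(
                {
                    "vineyard_id": f"V{p + 1:02d}{mgmt[0]}",
                    "circle_id": cid,
                    "management": mgmt,
                    "cover_crop": cover,
                    "vegetation_cover_spring": spring,
                    "vegetation_cover_summer": summer,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spray regimes
# ---------------------------------------------------------------------------

def generate_spray_regimes(
    config: SyntheticConfig, metadata: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Spray records per vineyard from the management-specific profiles.

    Category counts are truncated-normal draws rounded to integers;
    products applied in the same spray round share a date (fungicide
    rounds are weekly), so the total distinct-date count is close to the
    study's total-applications structure.
    """
    schedule = pd.date_range("2019-04-15", periods=16, freq="7D")
    rows = []
    for rec in metadata.itertuples(index=False):
        profile = config.spray_profile[rec.management]
        for category, (mean, sd) in profile.items():
            if mean == 0 and sd == 0:
                continue
            n = int(round(max(0.0, rng.normal(mean, sd))))
            product = _CATEGORY_PRODUCT[category]
            for j in range(n):
                rows.append(
                    {
                        "vineyard_id": rec.vineyard_id,
                        "date": schedule[min(j, len(schedule) - 1)].date().isoformat(),
                        "product": product,
                        "dose_g_per_ha": _DOSES[category],
                        "category": category,
                    }
                )
    return pd.DataFrame(
        rows, columns=["vineyard_id", "date", "product", "dose_g_per_ha", "category"]
    )


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

_OPEN_SNH = ("fallow", "grassland", "grass_strip")
_OTHER_ANALYZED = ("orchard", "scrub", "garden", "ruderal_vegetation", "reed")


def generate_landscape(
    config: SyntheticConfig, metadata: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Habitat patch tables per circle plus woody-SNH distances.

    The total SNH share is drawn uniformly inside the configured band
    (10-55% by default) and split between woody and open SNH classes by a
    Dirichlet draw; most of the remainder goes to vineyards and arable
    crops, the rest to the other analysed classes and a small
    excluded-class share. Patch areas sum exactly to the 500-m circle
    area.
    """
    lo, hi = config.snh_share_range
    rows = []
    dists = {}
    patch_id = 0
    for cid in metadata["circle_id"].unique():
        snh = rng.uniform(lo, hi)
        woody_frac = rng.uniform(0.25, 0.75)
        woody_total = snh * woody_frac
        open_total = snh * (1 - woody_frac)
        # vineyard share drawn independently of the SNH share (rescaled only
        # when the circle would overflow) so the two composition predictors
        # are not collinear by construction
        vine_share = rng.uniform(0.10, 0.50)
        arable_share = rng.uniform(0.02, 0.15)
        other = 1.0 - snh - vine_share - arable_share
        if other < 0.05:
            squeeze = (1.0 - snh - 0.05) / (vine_share + arable_share)
            vine_share *= squeeze
            arable_share *= squeeze
            other = 0.05
        excluded_total = other * rng.uniform(0.3, 0.6)
        other_analyzed_total = other - excluded_total

        shares: dict[str, float] = {}
        w = rng.dirichlet(np.ones(len(WOODY_SNH_CLASSES)))
        for cls, s in zip(WOODY_SNH_CLASSES, w):
            shares[cls] = woody_total * s
        o = rng.dirichlet(np.ones(len(_OPEN_SNH)))
        for cls, s in zip(_OPEN_SNH, o):
            shares[cls] = open_total * s
        shares["vineyard"] = vine_share
        shares["arable_crops"] = arable_share
        a = rng.dirichlet(np.ones(len(_OTHER_ANALYZED)))
        for cls, s in zip(_OTHER_ANALYZED, a):
            shares[cls] = other_analyzed_total * s
        e = rng.dirichlet(np.ones(len(EXCLUDED_CLASSES)))
        for cls, s in zip(EXCLUDED_CLASSES, e):
            shares[cls] = excluded_total * s

        for cls, share in shares.items():
            if share <= 0:
                continue
            patch_id += 1
            rows.append(
                {
                    "patch_id": f"P{patch_id:04d}",
                    "circle_id": cid,
                    "habitat_class": cls,
                    "area_m2": share * CIRCLE_AREA_M2,
                }
            )
        dists[cid] = float(rng.lognormal(mean=3.5, sigma=0.8))
    patches = pd.DataFrame(rows)
    return patches, pd.Series(dists, name="min_dist_woody")


# ---------------------------------------------------------------------------
# field samples
# ---------------------------------------------------------------------------

def _linear_predictor(
    config: SyntheticConfig,
    response: str,
    meta_row,
    landscape_row,
    date_index: int,
) -> float:
    eta = config.date_profile[response][date_index - 1]
    if meta_row.management == "organic":
        eta += config.management_effect[response]
    eta += config.cover_crop_effect[response][meta_row.cover_crop]
    # composition effects are centred at the generator's expected shares so
    # the linear predictor stays in the positive-density regime
    eta += config.pct_vineyards_effect[response] * (landscape_row["pct_vineyards"] - 30.0)
    eta += config.pct_total_snh_effect[response] * (landscape_row["pct_total_snh"] - 30.0)
    eta += config.min_dist_woody_effect[response] * (landscape_row["min_dist_woody"] - 40.0)
    eta += config.veg_summer_effect[response] * (meta_row.vegetation_cover_summer - 50.0)
    return eta


def generate_field_samples(
    config: SyntheticConfig,
    metadata: pd.DataFrame,
    landscape_summary: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leaf-wash mite counts and sticky-tape pollen counts.

    Transformed densities are Gaussian around the response's linear
    predictor, back-transformed and converted to integer counts given the
    drawn leaf area (25 leaves of 100-200 cm²). Eriophyoid counts are
    additionally zero-inflated and split between the two species; spider
    mites are always zero. Pollen grains are allocated to types by a
    season-specific composition dominated by grasses.
    """
    land = landscape_summary.set_index("circle_id")
    mite_rows, pollen_rows = [], []
    tape_area_cm2 = (config.square_side_mm / 10.0) ** 2
    for rec in metadata.itertuples(index=False):
        lrow = land.loc[rec.circle_id]
        for date_index in range(1, 6):
            leaf_area = float(
                rng.uniform(*config.leaf_area_range_cm2, size=config.n_leaves).sum()
            )
            counts = {}
            for response in ("phytoseiid", "tydeoid", "eriophyoid"):
                eta = _linear_predictor(config, response, rec, lrow, date_index)
                eta += rng.normal(0.0, config.residual_sd[response])
                density = max(0.0, 10.0**eta - 1.0)
                if response == "eriophyoid":
                    if rng.uniform() < config.eriophyoid_zero_inflation:
                        density = 0.0
                    total = int(round(density * leaf_area / 100.0))
                    c1 = int(rng.binomial(total, 0.72)) if total else 0
                    counts["eriophyoid_colomerus"] = c1
                    counts["eriophyoid_calepitrimerus"] = total - c1
                else:
                    counts[response] = int(round(density * leaf_area / 100.0))
            counts["spider_mite"] = 0
            for taxon, count in counts.items():
                mite_rows.append(
                    {
                        "vineyard_id": rec.vineyard_id,
                        "date_index": date_index,
                        "taxon": taxon,
                        "count": count,
                        "leaf_area_cm2": leaf_area,
                    }
                )
            # pollen
            eta = _linear_predictor(config, "pollen", rec, lrow, date_index)
            eta += rng.normal(0.0, config.residual_sd["pollen"])
            total_per_cm2 = max(0.0, 10.0**eta - 1.0)
            weights = (
                _POLLEN_WEIGHTS_SPRING if date_index <= 2 else _POLLEN_WEIGHTS_SUMMER
            )
            comp = rng.dirichlet(weights * 60.0)
            counted_area = config.counted_fraction * tape_area_cm2
            total_grains = int(round(total_per_cm2 * counted_area))
            alloc = rng.multinomial(total_grains, comp)
            for ptype, grains in zip(_POLLEN_TYPES, alloc):
                pollen_rows.append(
                    {
                        "vineyard_id": rec.vineyard_id,
                        "date_index": date_index,
                        "pollen_type": ptype,
                        "grains": int(grains),
                        "counted_fraction": config.counted_fraction,
                        "square_side_mm": config.square_side_mm,
                    }
                )
    return pd.DataFrame(mite_rows), pd.DataFrame(pollen_rows)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def generate_study(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate a complete study (design, sprays, landscape, samples)."""
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    metadata = generate_design(config, rng)
    spray = generate_spray_regimes(config, metadata, rng)
    patches, distances = generate_landscape(config, metadata, rng)

    from .landscape import circle_metrics

    summary = circle_metrics(patches, distances=distances)
    mites, pollen = generate_field_samples(config, metadata, summary, rng)
    truth = {
        "seed": config.seed,
        "n_pairs": config.n_pairs,
        "date_profile": {r: list(v) for r, v in config.date_profile.items()},
        "management_effect": config.management_effect,
        "cover_crop_effect": config.cover_crop_effect,
        "pct_vineyards_effect": config.pct_vineyards_effect,
        "pct_total_snh_effect": config.pct_total_snh_effect,
        "min_dist_woody_effect": config.min_dist_woody_effect,
        "veg_summer_effect": config.veg_summer_effect,
        "residual_sd": config.residual_sd,
        "true_terms": {
            r: true_terms(config, r) for r in RESPONSES
        },
    }
    return SyntheticStudy(
        metadata=metadata,
        spray=spray,
        ingredients=reference_ingredients(),
        products=reference_products(),
        mite_samples=mites,
        pollen_samples=pollen,
        patches=patches,
        distances=distances,
        ground_truth=truth,
    )


def true_terms(config: SyntheticConfig, response: str) -> list[str]:
    """The generating model's term set for *response* (date included when
    the date profile is non-constant)."""
    terms = []
    if len(set(config.date_profile[response])) > 1:
        terms.append("date")
    if config.management_effect[response] != 0:
        terms.append("management")
    if any(v != 0 for v in config.cover_crop_effect[response].values()):
        terms.append("cover_crop")
    if config.pct_vineyards_effect[response] != 0:
        terms.append("pct_vineyards")
    if config.pct_total_snh_effect[response] != 0:
        terms.append("pct_total_snh")
    if config.min_dist_woody_effect[response] != 0:
        terms.append("min_dist_woody")
    if config.veg_summer_effect[response] != 0:
        terms.append("vegetation_cover_summer")
    return terms
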