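"""End-to-end analysis: toxicity → densities → landscape → analysis table →
model selection per response → correlations → seasonal ordinations.

The stages mirror the field study's workflow. Each stage writes its table
into the results bundle as it completes, so a failure preserves partial
outputs; optional inputs (pollen) degrade gracefully with a logged reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import NMDSOrdination, correlation_table, split_season
from .field_samples import (
    merge_eriophyoid,
    merge_pollen_types,
    mite_density,
    pollen_density,
    total_pollen_density,
)
from .io import read_table, validate_inputs, write_table
from .landscape import circle_metrics
from .model_selection import (
    CandidateModel,
    DensityModelSelection,
    enumerate_candidates,
    study_candidate_config,
    transform_response,
)
from .toxicity import DEFAULT_SCALING, compute_toxicity

logger = logging.getLogger(__name__)

#: cross-response predictors added per response (other densities on the
#: transformed scale, ordinary additive columns)
CROSS_PREDICTORS = {
    "phytoseiid": ("tydeoid_log", "eriophyoid_log", "pollen_log"),
    "eriophyoid": ("phytoseiid_log",),
    "tydeoid": (),
    "pollen": (),
}

#: Spearman correlation pairs reported by the pipeline
CORRELATION_PAIRS = [
    ("aaptlc", "tpyri_rating"),
    ("aaptlc", "phytoseiid_log"),
    ("tpyri_rating", "phytoseiid_log"),
]


@dataclass
class PipelineConfig:
    """Paths, constants and seeds for a full pipeline run."""

    spray: str | None = None
    ingredients: str | None = None
    products: str | None = None
    mites: str | None = None
    pollen: str | None = None
    patches: str | None = None
    vineyards: str | None = None
    distances: str | None = None
    out_dir: str = "results"

    scaling: float = DEFAULT_SCALING
    khco3_half_life: float = 7.0
    analyzed_only: bool = False
    include_na_in_total: bool = True
    dissimilarity: str = "braycurtis"
    ordination_k: int = 2
    n_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def build_analysis_table(
    metadata: pd.DataFrame,
    toxicity: pd.DataFrame,
    mite_densities: pd.DataFrame,
    landscape_summary: pd.DataFrame,
    pollen_totals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the one-row-per-vineyard-date analysis table.

    Joins the wide mite densities with management metadata, per-vineyard
    toxicity, circle-level landscape metrics and (optionally) total pollen
    density; adds log10(y+1) cross-response predictor columns
    (``*_log``). ``date`` is categorical (five levels).
    """
    wide = (
        mite_densities.pivot_table(
            index=["vineyard_id", "date_index"],
            columns="taxon",
            values="density_per_100cm2",
            aggfunc="first",
        )
        .reset_index()
        .rename_axis(None, axis=1)
    )
    table = wide.merge(metadata, on="vineyard_id", how="left", validate="m:1")
    table = table.merge(
        toxicity[["vineyard_id", "aaptlc", "tpyri_rating", "n_applications_total"]],
        on="vineyard_id", how="left", validate="m:1",
    )
    table = table.merge(landscape_summary, on="circle_id", how="left", validate="m:1")
    if pollen_totals is not None:
        table = table.merge(
            pollen_totals.rename(columns={"total_per_cm2": "pollen"}),
            on=["vineyard_id", "date_index"], how="left", validate="1:1",
        )
    table["date"] = table["date_index"].astype(int).astype(str)
    for resp in ("phytoseiid", "tydeoid", "eriophyoid", "pollen"):
        if resp in table.columns:
            table[f"{resp}_log"] = transform_response(table[resp].fillna(0.0))
    counts = table.groupby(["vineyard_id", "date"]).size()
    if (counts > 1).any():
        raise ValueError("each vineyard must appear exactly once per date")
    return table.sort_values(["vineyard_id", "date_index"]).reset_index(drop=True)


def select_models(
    table: pd.DataFrame, response: str, seedless: bool = True
) -> "pd.DataFrame":
    """Run the 42-model AICc selection for one response, extending the pool
    with the response's cross-response predictors."""
    cfg = study_candidate_config()
    pool = tuple(t for t in cfg["pool"] if t in table.columns)
    pool = pool + tuple(
        t for t in CROSS_PREDICTORS.get(response, ()) if t in table.columns
    )
    candidates = enumerate_candidates(
        response, pool, exclusions=cfg["exclusions"],
        max_extra_terms=cfg["max_extra_terms"], forced=cfg["forced"],
    )
    model = DensityModelSelection(table, response, candidates=candidates)
    return model.fit()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write the results bundle.

    Returns the output directory. All randomness flows from
    ``config.seed``; two runs with identical config and inputs produce an
    identical bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    def _stage(name):
        def deco(fn):
            def run(*a, **kw):
                try:
                    res = fn(*a, **kw)
                    log["stages"][name] = "ok"
                    return res
                except Exception as exc:
                    log["stages"][name] = f"failed: {exc}"
                    _write_log()
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return run
        return deco

    def _write_log():
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)

    # --- validation -------------------------------------------------------
    paths = {
        k: getattr(config, k)
        for k in ("spray", "ingredients", "products", "mites", "pollen",
                  "patches", "vineyards")
        if getattr(config, k)
    }
    report = validate_inputs(paths)
    log["validation"] = {"errors": report.errors, "warnings": report.warnings}
    report.raise_if_failed()

    # --- toxicity ---------------------------------------------------------
    @_stage("toxicity")
    def toxicity_stage():
        spray = read_table(config.spray)
        ingredients = read_table(config.ingredients)
        products = read_table(config.products)
        tox = compute_toxicity(
            spray, ingredients, products,
            scaling=config.scaling,
            default_half_lives={"potassium_bicarbonate": config.khco3_half_life},
        )
        write_table(tox, out / "toxicity.csv")
        return tox

    tox = toxicity_stage()

    # --- densities --------------------------------------------------------
    @_stage("densities")
    def densities_stage():
        mites = read_table(config.mites)
        dens = merge_eriophyoid(mite_density(mites))
        write_table(dens, out / "mite_densities.csv")
        return dens

    dens = densities_stage()

    pollen_totals = None
    pollen_merged = None
    if config.pollen:
        @_stage("pollen")
        def pollen_stage():
            raw = read_table(config.pollen)
            merged = merge_pollen_types(pollen_density(raw))
            totals = total_pollen_density(merged, include_na=config.include_na_in_total)
            write_table(merged, out / "pollen_densities.csv")
            write_table(totals, out / "pollen_totals.csv")
            return merged, totals

        pollen_merged, pollen_totals = pollen_stage()
    else:
        log["stages"]["pollen"] = "skipped: no pollen input configured"
        logger.info("pollen input absent; ordination stage will be skipped")

    # --- landscape --------------------------------------------------------
    @_stage("landscape")
    def landscape_stage():
        patches = read_table(config.patches)
        distances = None
        if config.distances:
            dist_df = read_table(config.distances)
            distances = dist_df.set_index("circle_id")["min_dist_woody"]
        summary = circle_metrics(
            patches, analyzed_only=config.analyzed_only, distances=distances
        )
        write_table(summary, out / "landscape.csv")
        return summary

    land = landscape_stage()

    # --- analysis table + model selection ---------------------------------
    @_stage("model_selection")
    def selection_stage():
        metadata = read_table(config.vineyards)
        table = build_analysis_table(metadata, tox, dens, land, pollen_totals)
        write_table(table, out / "analysis_table.csv")
        responses = [r for r in ("phytoseiid", "tydeoid", "eriophyoid", "pollen")
                     if r in table.columns]
        for resp in responses:
            results = select_models(table, resp)
            write_table(results.selection_table(), out / f"selection_{resp}.csv")
            write_table(results.coefficients(), out / f"coefficients_{resp}.csv")
        return table

    table = selection_stage()

    # --- correlations -----------------------------------------------------
    @_stage("correlations")
    def correlation_stage():
        pairs = [(a, b) for a, b in CORRELATION_PAIRS
                 if a in table.columns and b in table.columns]
        corr = correlation_table(table, pairs)
        write_table(corr, out / "correlations.csv")
        return corr

    correlation_stage()

    # --- seasonal ordinations ---------------------------------------------
    if pollen_merged is not None:
        @_stage("ordination")
        def ordination_stage():
            community_long = pollen_merged.loc[pollen_merged["pollen_type"] != "NA"]
            for label, subset in zip(
                ("spring", "summer"), split_season(community_long)
            ):
                mat = subset.pivot_table(
                    index="vineyard_id", columns="pollen_type",
                    values="grains_per_cm2", aggfunc="mean", fill_value=0.0,
                )
                if mat.shape[0] < 3:
                    log["stages"][f"ordination_{label}"] = "skipped: too few sites"
                    continue
                trait_cols = ["cover_crop", "vegetation_cover_spring",
                              "vegetation_cover_summer", "shdi", "min_dist_woody",
                              "pct_total_snh", "pct_total_agriculture",
                              "phytoseiid_log"]
                traits = (
                    table.groupby("vineyard_id")
                    .agg({c: "first" for c in trait_cols if c in table.columns})
                    .loc[mat.index]
                )
                ord_model = NMDSOrdination(
                    mat, dissimilarity=config.dissimilarity,
                    k=config.ordination_k, traits=traits,
                )
                res = ord_model.fit(
                    seed=config.seed, n_permutations=config.n_permutations
                )
                res.scores.rename_axis("vineyard_id").reset_index().to_csv(
                    out / f"ordination_{label}_scores.csv", index=False
                )
                if res.traits is not None:
                    write_table(res.traits, out / f"ordination_{label}_traits.csv")
                with open(out / f"ordination_{label}_stress.json", "w") as fh:
                    json.dump({"stress": res.stress, "k": res.k,
                               "converged": bool(res.converged)}, fh)

        ordination_stage()
    else:
        log["stages"]["ordination"] = "skipped: no pollen input"

    _write_log()
    return out
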