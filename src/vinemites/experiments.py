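"""Seeded simulation experiments: model recovery and null retention.

These experiments quantify how reliably the AICc selection recovers a
known generating model from synthetic studies, and how often the null
model stays in the parsimonious set when no effects exist. They are run
by the test suite and the acceptance script at the replicate counts the
package documents (200 / 100).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .field_samples import merge_eriophyoid, mite_density, pollen_density, \
    merge_pollen_types, total_pollen_density
from .landscape import circle_metrics
from .model_selection import (
    DensityModelSelection,
    enumerate_candidates,
    study_candidate_config,
)
from .pipeline import build_analysis_table
from .simulate import SyntheticConfig, generate_study, true_terms
from .toxicity import compute_toxicity


def study_analysis_table(study) -> pd.DataFrame:
    """Run a generated study through the density/toxicity/landscape stages
    and assemble its analysis table (no file round-trip)."""
    tox = compute_toxicity(study.spray, study.ingredients, study.products)
    dens = merge_eriophyoid(mite_density(study.mite_samples))
    land = circle_metrics(study.patches, distances=study.distances)
    totals = total_pollen_density(
        merge_pollen_types(pollen_density(study.pollen_samples))
    )
    return build_analysis_table(study.metadata, tox, dens, land, totals)


def recovery_experiment(
    n_replicates: int = 200,
    seed: int = 0,
    response: str = "phytoseiid",
    zero_effects: bool = False,
    delta_threshold: float = 2.0,
) -> dict:
    """Replicate model selection over seeded synthetic studies.

    For each replicate a fresh study is generated, pushed through the
    pipeline stages to the analysis table, and the candidate set (forced
    ``date``, study pool and exclusions, up to 4 non-date terms so the
    generating model is enumerable) is ranked by AICc.

    Returns a dict with the recovery rate (share of replicates whose
    generating term set sits inside the Δi <= threshold set), the
    coefficient coverage rate (share of generating effects within 2 SE of
    truth in the true model's fit), and with ``zero_effects=True`` the
    share of replicates keeping the null model in the parsimonious set.
    """
    base = SyntheticConfig()
    if zero_effects:
        base = base.zeroed()
    cfg = study_candidate_config()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)

    hits = 0
    null_hits = 0
    coef_total = 0
    coef_within = 0
    for rep_seed in seeds:
        config = dataclasses.replace(base, seed=int(rep_seed))
        study = generate_study(config)
        table = study_analysis_table(study)
        candidates = enumerate_candidates(
            response, cfg["pool"], exclusions=cfg["exclusions"],
            max_extra_terms=4, forced=cfg["forced"],
        )
        results = DensityModelSelection(
            table, response, candidates=candidates,
            delta_threshold=delta_threshold,
        ).fit()
        truth = frozenset(true_terms(config, response))
        selected_sets = {frozenset(f.model.terms) for f in results.parsimonious}
        if zero_effects:
            if frozenset() in selected_sets:
                null_hits += 1
            continue
        if truth in selected_sets:
            hits += 1
        true_fit = next(
            (f for f in results.fits if frozenset(f.model.terms) == truth), None
        )
        if true_fit is not None:
            n_within, n_checked = _coefficients_within_2se(config, response, true_fit)
            coef_within += n_within
            coef_total += n_checked
    out = {
        "n_replicates": n_replicates,
        "response": response,
        "delta_threshold": delta_threshold,
    }
    if zero_effects:
        out["null_retention_rate"] = null_hits / n_replicates
    else:
        out["recovery_rate"] = hits / n_replicates
        out["coefficient_coverage"] = (
            coef_within / coef_total if coef_total else float("nan")
        )
    return out


def _coefficients_within_2se(config: SyntheticConfig, response: str, fit) -> tuple[int, int]:
    """Count generating effects whose estimate lies within 2 SE of truth."""
    truth_values = {
        "management[organic]": config.management_effect[response],
        "cover_crop[species_rich]":
            config.cover_crop_effect[response]["species_rich"],
        "cover_crop[spontaneous]":
            config.cover_crop_effect[response]["spontaneous"],
        "pct_vineyards": config.pct_vineyards_effect[response],
        "pct_total_snh": config.pct_total_snh_effect[response],
        "min_dist_woody": config.min_dist_woody_effect[response],
        "vegetation_cover_summer": config.veg_summer_effect[response],
    }
    within = checked = 0
    for name, true_val in truth_values.items():
        if name not in fit.params.index:
            continue
        checked += 1
        if abs(fit.params[name] - true_val) <= 2.0 * fit.bse[name]:
            within += 1
    return within, checked


def toxicity_fuzz(
    n_cases: int = 1000, seed: int = 0, max_applications: int = 5
) -> dict:
    """Randomized spray regimes checked against a brute-force per-term
    evaluation of the toxicity loading formula.

    Returns the maximum relative error over all cases (0 for exact
    agreement within floating point).
    """
    import math

    from .toxicity import aaptlc

    rng = np.random.default_rng(seed)
    max_rel = 0.0
    ln2 = math.log(2.0)
    for _ in range(n_cases):
        n_apps = int(rng.integers(0, max_applications + 1))
        n_ing = int(rng.integers(1, 4))
        names = [f"ai{j}" for j in range(n_ing)]
        ld50 = rng.uniform(0.01, 500.0, n_ing)
        hl = rng.uniform(0.1, 1000.0, n_ing)
        ingredients = pd.DataFrame(
            {
                "name": names,
                "ld50_contact_ug_per_bee": ld50,
                "half_life_days": hl,
                "harm_class": ["harmless"] * n_ing,
            }
        )
        prod_rows = []
        for j, name in enumerate(names):
            prod_rows.append(("P", name, float(rng.uniform(1.0, 100.0))))
        products = pd.DataFrame(
            prod_rows, columns=["product", "ingredient", "concentration_pct"]
        )
        doses = rng.uniform(0.0, 5000.0, n_apps)
        spray = pd.DataFrame(
            {
                "vineyard_id": ["v"] * n_apps,
                "date": [f"2019-05-{d + 1:02d}" for d in range(n_apps)],
                "product": ["P"] * n_apps,
                "dose_g_per_ha": doses,
                "category": ["sulfur"] * n_apps,
            }
        )
        score, _ = aaptlc(spray, ingredients, products)
        # brute force: explicit loop over every (application, ingredient) term
        expected = 0.0
        for dose in doses:
            for j in range(n_ing):
                amount = dose * products["concentration_pct"].iloc[j] / 100.0
                expected += (amount / ld50[j]) * (hl[j] / ln2)
        expected *= 1e-4
        denom = max(abs(expected), 1e-300)
        max_rel = max(max_rel, abs(score - expected) / denom)
    return {"n_cases": n_cases, "max_relative_error": max_rel}
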