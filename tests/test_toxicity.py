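"""Toxicity loading and categorical rating arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vinemites.toxicity import (
    UnresolvableProductError,
    aaptlc,
    active_ingredient_amounts,
    application_counts,
    compute_toxicity,
    tpyri_rating,
)

from conftest import make_spray


def ingredient_table(rows):
    return pd.DataFrame(
        rows,
        columns=["name", "ld50_contact_ug_per_bee", "half_life_days", "harm_class"],
    )


def product_table(rows):
    return pd.DataFrame(rows, columns=["product", "ingredient", "concentration_pct"])


EMPTY_SPRAY = make_spray([])


class TestIngredientAmounts:
    def test_empty_regime_gives_empty_map(self, products):
        contributions, totals = active_ingredient_amounts(EMPTY_SPRAY, products)
        assert contributions.empty
        assert totals.empty

    def test_dose_times_concentration(self):
        products = product_table([("S80", "sulfur", 80.0)])
        spray = make_spray([("v1", "2019-05-01", "S80", 2000.0, "sulfur")])
        _, totals = active_ingredient_amounts(spray, products)
        assert totals["sulfur"] == pytest.approx(2000 * 0.80)

    def test_contributions_kept_per_application_and_summed(self):
        products = product_table([("P", "ai", 50.0)])
        spray = make_spray(
            [
                ("v1", "2019-05-01", "P", 1000.0, "sulfur"),
                ("v1", "2019-06-01", "P", 1000.0, "sulfur"),
            ]
        )
        contributions, totals = active_ingredient_amounts(spray, products)
        assert list(contributions["amount_g_per_ha"]) == [500.0, 500.0]
        assert totals["ai"] == pytest.approx(1000.0)

    def test_unresolvable_product_is_named(self, products):
        spray = make_spray([("v1", "2019-05-01", "NoSuchProduct", 10.0, "other")])
        with pytest.raises(UnresolvableProductError, match="NoSuchProduct"):
            active_ingredient_amounts(spray, products)

    def test_negative_dose_rejected(self, products):
        spray = make_spray([("v1", "2019-05-01", "Sulfur 80 WG", -5.0, "sulfur")])
        with pytest.raises(ValueError, match="negative dose"):
            active_ingredient_amounts(spray, products)


class TestAaptlc:
    def test_empty_regime_scores_zero(self, ingredients, products):
        score, excluded = aaptlc(EMPTY_SPRAY, ingredients, products)
        assert score == 0.0
        assert excluded == []

    def test_hand_evaluated_single_term(self):
        """1000 g/ha at LD50 100 and half-life ln2 days: 10 × 1 × 1e-4."""
        ing = ingredient_table([("ai", 100.0, math.log(2.0), "harmless")])
        prod = product_table([("P", "ai", 100.0)])
        spray = make_spray([("v1", "2019-05-01", "P", 1000.0, "sulfur")])
        score, excluded = aaptlc(spray, ing, prod)
        assert score == pytest.approx(1.0e-3, rel=1e-12)
        assert excluded == []

    def test_potassium_bicarbonate_default_half_life(self):
        ing = ingredient_table(
            [("potassium_bicarbonate", 332.0, np.nan, "harmless")]
        )
        prod = product_table([("B", "potassium_bicarbonate", 85.0)])
        spray = make_spray([("v1", "2019-05-01", "B", 5000.0, "potassium_bicarbonate")])
        score, excluded = aaptlc(spray, ing, prod)
        expected = 1e-4 * (5000 * 0.85 / 332.0) * (7.0 / math.log(2.0))
        assert score == pytest.approx(expected, rel=1e-12)
        assert excluded == []
        # and the default is overridable
        score14, _ = aaptlc(
            spray, ing, prod, default_half_lives={"potassium_bicarbonate": 14.0}
        )
        assert score14 == pytest.approx(2 * score, rel=1e-12)

    def test_missing_values_excluded_and_reported(self):
        ing = ingredient_table(
            [("a", np.nan, 5.0, "harmless"), ("b", 10.0, np.nan, "harmful")]
        )
        prod = product_table([("P", "a", 50.0), ("P", "b", 50.0)])
        spray = make_spray([("v1", "2019-05-01", "P", 100.0, "other")])
        score, excluded = aaptlc(spray, ing, prod)
        assert score == 0.0
        assert dict(excluded) == {
            "a": "missing ld50_contact",
            "b": "missing half_life",
        }

    def test_scaling_must_be_positive(self, ingredients, products):
        with pytest.raises(ValueError, match="scaling"):
            aaptlc(EMPTY_SPRAY, ingredients, products, scaling=0.0)

    @given(
        doses=st.lists(
            st.floats(0.0, 5000.0, allow_nan=False), min_size=0, max_size=5
        ),
        ld50=st.floats(0.01, 500.0, allow_nan=False),
        hl=st.floats(0.1, 1000.0, allow_nan=False),
        pct=st.floats(1.0, 100.0, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_per_term_oracle(self, doses, ld50, hl, pct):
        ing = ingredient_table([("ai", ld50, hl, "harmless")])
        prod = product_table([("P", "ai", pct)])
        spray = make_spray(
            [("v1", f"2019-05-{i + 1:02d}", "P", d, "sulfur") for i, d in enumerate(doses)]
        )
        score, _ = aaptlc(spray, ing, prod)
        expected = 1e-4 * sum(
            (d * pct / 100.0 / ld50) * (hl / math.log(2.0)) for d in doses
        )
        assert score == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_additive_over_concatenated_regimes(self, ingredients, products):
        a = make_spray([("v1", "2019-05-01", "Sulfur 80 WG", 3000.0, "sulfur")])
        b = make_spray(
            [
                ("v1", "2019-06-01", "CopperShield", 2000.0, "copper"),
                ("v1", "2019-06-08", "FungiMix Duo", 1500.0, "synthetic_fungicide"),
            ]
        )
        both = pd.concat([a, b], ignore_index=True)
        sa, _ = aaptlc(a, ingredients, products)
        sb, _ = aaptlc(b, ingredients, products)
        sab, _ = aaptlc(both, ingredients, products)
        assert sab == pytest.approx(sa + sb, rel=1e-12)

    def test_linear_in_dose(self, ingredients, products):
        spray = make_spray(
            [
                ("v1", "2019-05-01", "Sulfur 80 WG", 3000.0, "sulfur"),
                ("v1", "2019-06-01", "CopperShield", 2000.0, "copper"),
            ]
        )
        doubled = spray.assign(dose_g_per_ha=spray["dose_g_per_ha"] * 2)
        s1, _ = aaptlc(spray, ingredients, products)
        s2, _ = aaptlc(doubled, ingredients, products)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_adding_application_never_decreases(self, ingredients, products):
        spray = make_spray([("v1", "2019-05-01", "Sulfur 80 WG", 3000.0, "sulfur")])
        more = pd.concat(
            [spray, make_spray([("v1", "2019-07-01", "CopperShield", 500.0, "copper")])],
            ignore_index=True,
        )
        s1, _ = aaptlc(spray, ingredients, products)
        s2, _ = aaptlc(more, ingredients, products)
        assert s2 >= s1

    def test_half_life_ln2_gives_unit_persistence(self):
        """With half-life exactly ln 2 days the persistence factor is 1, so
        the score reduces to the bare hazard quotient (times scaling)."""
        ing = ingredient_table([("ai", 50.0, math.log(2.0), "harmless")])
        prod = product_table([("P", "ai", 100.0)])
        spray = make_spray([("v1", "2019-05-01", "P", 500.0, "other")])
        score, _ = aaptlc(spray, ing, prod, scaling=1.0)
        assert score == pytest.approx(500.0 / 50.0, rel=1e-12)

    def test_contribution_vanishes_as_ld50_grows(self):
        prod = product_table([("P", "ai", 100.0)])
        spray = make_spray([("v1", "2019-05-01", "P", 500.0, "other")])
        scores = []
        for ld50 in (1e2, 1e6, 1e12):
            ing = ingredient_table([("ai", ld50, 10.0, "harmless")])
            s, _ = aaptlc(spray, ing, prod)
            scores.append(s)
        assert scores[0] > scores[1] > scores[2]
        assert scores[2] < 1e-12


class TestTpyriRating:
    def test_empty_regime(self, ingredients, products):
        score, excluded = tpyri_rating(EMPTY_SPRAY, ingredients, products)
        assert score == 0.0 and excluded == []

    def test_single_harmless_application_scores_04(self):
        ing = ingredient_table([("ai", 10.0, 1.0, "harmless")])
        prod = product_table([("P", "ai", 100.0)])
        spray = make_spray([("v1", "2019-05-01", "P", 100.0, "other")])
        score, _ = tpyri_rating(spray, ing, prod)
        assert score == pytest.approx(0.4)

    def test_three_class_sum(self):
        ing = ingredient_table(
            [
                ("a", 1.0, 1.0, "harmless"),
                ("b", 1.0, 1.0, "slightly_harmful"),
                ("c", 1.0, 1.0, "harmful"),
            ]
        )
        prod = product_table([("A", "a", 50.0), ("B", "b", 50.0), ("C", "c", 50.0)])
        spray = make_spray(
            [
                ("v1", "2019-05-01", "A", 100.0, "other"),
                ("v1", "2019-05-08", "B", 100.0, "other"),
                ("v1", "2019-05-15", "C", 100.0, "other"),
            ]
        )
        score, _ = tpyri_rating(spray, ing, prod)
        assert score == pytest.approx(0.4 + 0.8 + 1.0)

    def test_unknown_class_excluded_and_reported(self):
        ing = ingredient_table(
            [("a", 1.0, 1.0, "harmful"), ("b", 1.0, 1.0, "unknown")]
        )
        prod = product_table([("P", "a", 50.0), ("P", "b", 10.0)])
        spray = make_spray([("v1", "2019-05-01", "P", 100.0, "other")])
        score, excluded = tpyri_rating(spray, ing, prod)
        assert score == pytest.approx(1.0)
        assert excluded == [("b", "unknown harm_class")]

    @given(
        classes=st.lists(
            st.sampled_from(["harmless", "slightly_harmful", "harmful"]),
            min_size=0,
            max_size=6,
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_occurrence_sum_and_bounds(self, classes):
        scale = {"harmless": 0.4, "slightly_harmful": 0.8, "harmful": 1.0}
        ing = ingredient_table(
            [(f"ai{i}", 1.0, 1.0, c) for i, c in enumerate(classes)]
        )
        prod = product_table([(f"P{i}", f"ai{i}", 50.0) for i in range(len(classes))])
        spray = make_spray(
            [
                ("v1", f"2019-05-{i + 1:02d}", f"P{i}", 100.0, "other")
                for i in range(len(classes))
            ]
        )
        score, _ = tpyri_rating(spray, ing, prod)
        assert score == pytest.approx(sum(scale[c] for c in classes))
        n = len(classes)
        assert 0.4 * n - 1e-12 <= score <= 1.0 * n + 1e-12


class TestApplicationCounts:
    def test_empty_regime_all_zero(self):
        total, by_cat = application_counts(EMPTY_SPRAY)
        assert total == 0
        assert all(v == 0 for v in by_cat.values())

    def test_shared_date_is_one_application(self):
        spray = make_spray(
            [
                ("v1", "2019-05-01", "A", 100.0, "sulfur"),
                ("v1", "2019-05-01", "B", 100.0, "copper"),
            ]
        )
        total, by_cat = application_counts(spray)
        assert total == 1
        assert by_cat["sulfur"] == 1 and by_cat["copper"] == 1

    def test_distinct_dates_counted(self):
        spray = make_spray(
            [
                ("v1", "2019-05-01", "A", 100.0, "sulfur"),
                ("v1", "2019-05-08", "A", 100.0, "sulfur"),
                ("v1", "2019-05-15", "A", 100.0, "sulfur"),
            ]
        )
        total, by_cat = application_counts(spray)
        assert total == 3 and by_cat["sulfur"] == 3

    def test_unknown_category_rejected(self):
        spray = make_spray([("v1", "2019-05-01", "A", 1.0, "weird")])
        with pytest.raises(ValueError, match="weird"):
            application_counts(spray)


def test_per_vineyard_summary_consistency(study):
    """compute_toxicity agrees with the per-regime operations and carries
    consistent application counts."""
    tox = compute_toxicity(study.spray, study.ingredients, study.products)
    assert set(tox["vineyard_id"]) == set(study.spray["vineyard_id"])
    cat_cols = [c for c in tox.columns if c.startswith("n_applications_") and
                c != "n_applications_total"]
    # every vineyard's aaptlc matches a direct single-regime computation
    vid = tox["vineyard_id"].iloc[0]
    regime = study.spray[study.spray["vineyard_id"] == vid]
    score, _ = aaptlc(regime, study.ingredients, study.products)
    assert tox.set_index("vineyard_id").at[vid, "aaptlc"] == pytest.approx(score)
    assert (tox[cat_cols].sum(axis=1) >= tox["n_applications_total"]).all()
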