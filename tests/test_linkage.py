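"""Fibre linkage, non-reporter tabulation and contribution/rank tables."""

import numpy as np
import pandas as pd
import pytest

from fibresub.linkage import LinkageError, contribution_table, link_fibre, nonreporter_table
from tests.conftest import make_persons


def events_frame(rows):
    return pd.DataFrame(rows, columns=["person_id", "recall_day", "bread_category", "amount"])


class TestLinkFibre:
    def test_single_event_median_density(self, densities):
        events = events_frame([("P1", 1, "white_wheat", 100.0)])
        out = link_fibre(events, densities)
        assert out.loc[0, "fibre_white_wheat"] == pytest.approx(3.0)
        assert out.loc[0, "total_fibre"] == pytest.approx(3.0)

    def test_mixed_basket_hand_arithmetic(self, densities):
        events = events_frame([
            ("P1", 1, "wholegrain", 50.0),
            ("P1", 1, "white_wheat", 50.0),
        ])
        out = link_fibre(events, densities)
        assert out.loc[0, "total_fibre"] == pytest.approx(0.5 * 7.7 + 0.5 * 3.0)  # 5.35

    def test_no_events_gives_zero_records(self, densities):
        persons = make_persons(2)
        out = link_fibre(events_frame([]), densities, persons=persons, n_recall_days=2)
        assert len(out) == 4
        assert (out["total_fibre"] == 0).all() and (out["total_grams"] == 0).all()

    def test_multiple_rows_same_day_summed(self, densities):
        events = events_frame([
            ("P1", 1, "white_wheat", 40.0),
            ("P1", 1, "white_wheat", 60.0),
        ])
        out = link_fibre(events, densities)
        assert out.loc[0, "grams_white_wheat"] == pytest.approx(100.0)

    def test_unmapped_category_named(self, densities):
        events = events_frame([("P1", 1, "white_wheat", 10.0)])
        bad = dict(densities)
        del bad["wholegrain"]
        with pytest.raises(LinkageError, match="wholegrain"):
            link_fibre(events, bad)

    def test_linearity(self, densities, small_cohort):
        _, persons, events = small_cohort
        base = link_fibre(events, densities, persons=persons)
        doubled = events.assign(amount=events["amount"] * 2)
        out = link_fibre(doubled, densities, persons=persons)
        np.testing.assert_allclose(out["total_fibre"], 2 * base["total_fibre"], rtol=1e-12)

    def test_category_consistency_invariant(self, densities, small_cohort):
        _, persons, events = small_cohort
        out = link_fibre(events, densities, persons=persons)
        for cat, dens in densities.items():
            np.testing.assert_allclose(
                out[f"fibre_{cat}"], out[f"grams_{cat}"] * dens / 100.0, atol=1e-9
            )
        np.testing.assert_allclose(
            out["total_fibre"],
            sum(out[f"fibre_{c}"] for c in densities),
            atol=1e-9,
        )


class TestNonreporters:
    def test_printed_survey_rates(self):
        # 158 of 234 older-adult females without white-wheat events -> 67.5%;
        # 94 of 252 adolescent males -> 37.3%
        for n_stratum, n_non, age, sex, expected in [
            (234, 158, "older_adult", "female", 67.5),
            (252, 94, "adolescent", "male", 37.3),
        ]:
            persons = make_persons(n_stratum, age_group=age, sex=sex)
            reporters = persons["person_id"].iloc[n_non:]
            events = events_frame([(pid, 1, "white_wheat", 50.0) for pid in reporters])
            table = nonreporter_table(persons, events)
            row = table[(table["category"] == "white_wheat")].iloc[0]
            assert row["n_nonreporters"] == n_non
            assert round(row["pct_nonreporters"], 1) == expected

    def test_everyone_consumes_daily(self, densities):
        persons = make_persons(5)
        events = events_frame([
            (pid, d, c, 30.0)
            for pid in persons["person_id"]
            for d in (1, 2)
            for c in densities
        ])
        table = nonreporter_table(persons, events)
        assert (table["n_nonreporters"] == 0).all()

    def test_true_nonconsumers_counted(self):
        persons = make_persons(4)
        events = events_frame([("P0000", 1, "mixed", 30.0)])
        table = nonreporter_table(persons, events)
        any_bread = table[table["category"] == "any_bread"].iloc[0]
        assert any_bread["n_nonreporters"] == 3
        assert any_bread["pct_nonreporters"] == pytest.approx(75.0)


def habitual_frame(persons, contributions):
    """One habitual row per (person, category) with stratum-constant values."""
    rows = []
    for pid in persons["person_id"]:
        for cat, value in contributions.items():
            rows.append({"person_id": pid, "category": cat, "habitual": value})
    return pd.DataFrame(rows)


class TestContributions:
    def test_single_cell_share(self):
        # contribution 80.0 of total 146.4 -> 54.6%
        persons = make_persons(10, age_group="adolescent")
        hab = habitual_frame(persons, {
            "white_wheat": 80.0, "half_white_wheat": 13.3, "dark_wheat": 26.8,
            "mixed": 10.8, "wholegrain": 15.6,
        })
        table = contribution_table(hab, persons)
        white = table[table["category"] == "white_wheat"].iloc[0]
        assert white["total_mean"] == pytest.approx(146.5, abs=0.1)
        assert round(white["pct_of_total"], 1) == 54.6
        assert white["rank"] == 1

    def test_adult_male_column(self):
        contributions = {
            "white_wheat": 62.6, "half_white_wheat": 25.9, "dark_wheat": 41.6,
            "mixed": 7.6, "wholegrain": 21.2,
        }
        persons = make_persons(6)
        table = contribution_table(habitual_frame(persons, contributions), persons)
        got = table.set_index("category")
        expected_pct = {"white_wheat": 39.4, "half_white_wheat": 16.3,
                        "dark_wheat": 26.2, "mixed": 4.8, "wholegrain": 13.3}
        expected_rank = {"white_wheat": 1, "half_white_wheat": 3,
                         "dark_wheat": 2, "mixed": 5, "wholegrain": 4}
        for cat in contributions:
            assert round(got.loc[cat, "pct_of_total"], 1) == expected_pct[cat]
            assert got.loc[cat, "rank"] == expected_rank[cat]

    def test_single_category_is_everything(self):
        persons = make_persons(3)
        hab = habitual_frame(persons, {"wholegrain": 25.0})
        table = contribution_table(hab, persons)
        whole = table[table["category"] == "wholegrain"].iloc[0]
        assert whole["pct_of_total"] == pytest.approx(100.0)
        assert whole["rank"] == 1

    def test_conservation_and_rounded_sum(self, small_cohort, densities):
        from fibresub.habitual import fit_habitual
        from fibresub.linkage import link_fibre

        _, persons, events = small_cohort
        persondays = link_fibre(events, densities, persons=persons)
        hab = fit_habitual(persondays, persons,
                           quantities=tuple(f"grams_{c}" for c in densities))
        table = contribution_table(hab[hab["quantity"] == "bread_grams"], persons)
        for (_, _), grp in table.groupby(["age_group", "sex"]):
            assert grp["mean_contribution"].sum() == pytest.approx(
                grp["total_mean"].iloc[0], abs=1e-9
            )
            assert grp["pct_of_total"].sum() == pytest.approx(100.0, abs=1e-9)
            rounded = grp["pct_of_total"].round(1).sum()
            assert abs(rounded - 100.0) <= 0.3

    def test_zero_total_flagged(self):
        persons = make_persons(2)
        hab = habitual_frame(persons, {"white_wheat": 0.0})
        table = contribution_table(hab, persons)
        assert table["undefined_total"].all()
        assert table["pct_of_total"].isna().all()

    def test_mean_intake_among_reporters_only(self):
        persons = make_persons(4)
        hab = pd.DataFrame({
            "person_id": persons["person_id"],
            "category": "white_wheat",
            "habitual": [100.0, 0.0, 50.0, 0.0],
        })
        table = contribution_table(hab, persons)
        row = table[table["category"] == "white_wheat"].iloc[0]
        assert row["mean_intake_reporters"] == pytest.approx(75.0)
        assert row["mean_contribution"] == pytest.approx(37.5)
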