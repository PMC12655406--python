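"""Two-part habitual-intake estimator: shrinkage, limits, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from fibresub.config import BREAD_CATEGORIES, CohortConfig, HabitualModelSpec
from fibresub.habitual import (
    HabitualIntakeModel,
    fit_habitual,
    habitual_distribution,
    shrinkage_factor,
)
from fibresub.linkage import link_fibre
from fibresub.synthetic import generate_cohort
from tests.conftest import constant_white_bread_events, make_persons


def test_shrinkage_factor_closed_form():
    assert shrinkage_factor(1.0, 1.0, 2) == pytest.approx(2.0 / 3.0)
    assert shrinkage_factor(0.0, 1.0, 2) == 0.0
    assert shrinkage_factor(1.0, 0.0, 2) == 1.0
    assert shrinkage_factor(0.0, 0.0, 2) == 1.0  # noiseless limit


def test_noiseless_limit_recovers_observed_intake(noiseless_white_bread, densities):
    """Constant intake on both days => sigma_w = 0 and habitual == observed."""
    persons, events, amounts = noiseless_white_bread
    persondays = link_fibre(events, densities, persons=persons)
    res = HabitualIntakeModel(persondays, persons, value_col="total_fibre").fit()
    assert res.sigma2_within == pytest.approx(0.0, abs=1e-20)
    expected = amounts * densities["white_wheat"] / 100.0
    got = res.estimates.sort_values("person_id")["habitual"].to_numpy()
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_identity_limit_equals_person_mean(densities):
    """min_days=1 and shrink=False reproduce the observed mean daily intake."""
    rng = np.random.default_rng(0)
    persons = make_persons(40)
    rows = []
    for pid in persons["person_id"]:
        for day in (1, 2):
            if rng.random() < 0.7:
                rows.append({"person_id": pid, "recall_day": day,
                             "bread_category": "white_wheat",
                             "amount": float(rng.lognormal(4.5, 0.5))})
    events = pd.DataFrame(rows)
    persondays = link_fibre(events, densities, persons=persons)
    spec = HabitualModelSpec(min_days=1, shrink=False)
    res = HabitualIntakeModel(persondays, persons, spec=spec, value_col="total_fibre").fit()
    observed = persondays.groupby("person_id")["total_fibre"].mean().sort_index()
    got = res.estimates.set_index("person_id")["habitual"].sort_index()
    np.testing.assert_allclose(got.to_numpy(), observed.to_numpy(), atol=1e-8)


def _recovery_cohort(n_persons=2000, seed=13, sd=0.35, p=1.0):
    """Cohort with strong covariate structure and 1:1 variance ratio."""
    prefs, mus = {}, {}
    base_mu = {
        ("adolescent", "male"): 4.2, ("adolescent", "female"): 4.6,
        ("adult", "male"): 5.0, ("adult", "female"): 5.4,
        ("older_adult", "male"): 5.8, ("older_adult", "female"): 6.2,
    }
    for (age, sex), mu in base_mu.items():
        for cat in BREAD_CATEGORIES:
            prefs[(age, sex, cat)] = p if cat == "white_wheat" else 0.0
            mus[(age, sex, cat)] = mu
    return CohortConfig(
        n_persons=n_persons, n_recall_days=2,
        age_group_weights={"adolescent": 1 / 3, "adult": 1 / 3, "older_adult": 1 - 2 / 3},
        sex_weights={"male": 0.5, "female": 0.5},
        category_preference=prefs, amount_log_mean=mus,
        amount_log_sd_between=sd, amount_log_sd_within=sd,
        propensity_sd=0.0, seed=seed,
    )


def test_parameter_recovery_correlation():
    """Estimated habitual intake tracks the generator's true person-level mean."""
    cfg = _recovery_cohort()
    persons, events, latents = generate_cohort(cfg, return_latents=True)
    densities = {c: 3.0 for c in BREAD_CATEGORIES}
    persondays = link_fibre(events, densities, persons=persons)
    res = HabitualIntakeModel(persondays, persons, value_col="total_grams").fit()

    mu_map = {
        (a, s): cfg.amount_log_mean[(a, s, "white_wheat")]
        for a in cfg.age_group_weights for s in cfg.sex_weights
    }
    merged = persons.merge(latents, on="person_id")
    mu = np.array([mu_map[(a, s)] for a, s in zip(merged["age_group"], merged["sex"])])
    sd_b, sd_w = cfg.amount_log_sd_between, cfg.amount_log_sd_within
    truth = np.exp(mu + sd_b * merged["b_amount"].to_numpy() + sd_w**2 / 2)

    est = res.estimates.set_index("person_id")["habitual"]
    est = est.reindex(merged["person_id"]).to_numpy()
    corr = np.corrcoef(est, truth)[0, 1]
    assert corr > 0.9


def test_shrinkage_reduces_dispersion(small_cohort, densities):
    _, persons, events = small_cohort
    persondays = link_fibre(events, densities, persons=persons)
    res = HabitualIntakeModel(persondays, persons, value_col="total_fibre").fit()
    raw_means = persondays.groupby("person_id")["total_fibre"].mean()
    assert res.estimates["habitual"].std(ddof=1) <= raw_means.std(ddof=1)


def test_mean_preserved_by_back_transform(small_cohort, densities):
    """Population mean of habitual fibre within 5% of raw daily mean."""
    _, persons, events = small_cohort
    persondays = link_fibre(events, densities, persons=persons)
    res = HabitualIntakeModel(persondays, persons, value_col="total_fibre").fit()
    assert res.estimates["habitual"].mean() == pytest.approx(
        persondays["total_fibre"].mean(), rel=0.05
    )


def test_monotone_in_person_amounts(small_cohort, densities):
    """Scaling one person's amounts up never lowers that person's habitual."""
    _, persons, events = small_cohort
    pid = events["person_id"].iloc[0]
    persondays = link_fibre(events, densities, persons=persons)
    base = HabitualIntakeModel(persondays, persons, value_col="total_fibre").fit()
    boosted = events.copy()
    boosted.loc[boosted["person_id"] == pid, "amount"] *= 1.5
    res2 = HabitualIntakeModel(
        link_fibre(boosted, densities, persons=persons), persons, value_col="total_fibre"
    ).fit()
    before = base.estimates.set_index("person_id").loc[pid, "habitual"]
    after = res2.estimates.set_index("person_id").loc[pid, "habitual"]
    assert after >= before


def test_all_zero_stratum_warns_and_zeroes(densities):
    persons = make_persons(5)
    persondays = link_fibre(pd.DataFrame(
        columns=["person_id", "recall_day", "bread_category", "amount"]
    ), densities, persons=persons)
    with pytest.warns(UserWarning, match="zero"):
        res = HabitualIntakeModel(persondays, persons, value_col="total_fibre").fit()
    assert (res.estimates["habitual"] == 0).all()


def test_min_days_exclusion_logged(densities):
    persons = make_persons(3)
    events = constant_white_bread_events([100.0, 100.0, 100.0])
    persondays = link_fibre(events, densities, persons=persons)
    persondays = persondays[~((persondays["person_id"] == "P0000")
                              & (persondays["recall_day"] == 2))]
    res = HabitualIntakeModel(persondays, persons, value_col="total_fibre").fit()
    assert res.excluded_persons == ["P0000"]
    assert len(res.estimates) == 2


def test_summary_mentions_variance_components(noiseless_white_bread, densities):
    persons, events, _ = noiseless_white_bread
    persondays = link_fibre(events, densities, persons=persons)
    res = HabitualIntakeModel(persondays, persons, value_col="total_fibre").fit()
    text = res.summary()
    assert "sigma^2 between" in text and "habitual" in text


def test_fit_habitual_long_format(small_cohort, densities):
    _, persons, events = small_cohort
    persondays = link_fibre(events, densities, persons=persons)
    hab = fit_habitual(persondays, persons)
    assert set(hab["quantity"]) == {"bread_grams", "fibre_grams"}
    assert "total" in set(hab["category"])
    assert ((hab["prob"] >= 0) & (hab["prob"] <= 1)).all()
    assert (hab["habitual"] >= 0).all()
    # habitual = prob x usual amount
    np.testing.assert_allclose(
        hab["habitual"], hab["prob"] * hab["usual_amount_on_consumption_days"], atol=1e-12
    )


class TestDistribution:
    def test_two_person_hand_arithmetic(self):
        d = habitual_distribution([3.0, 5.0], bin_width=1.0)
        assert d["mean"] == 4.0
        assert d["sd"] == pytest.approx(np.sqrt(2))

    def test_degenerate_single_bin(self):
        d = habitual_distribution([2.2, 2.2, 2.2], bin_width=0.5)
        assert d["sd"] == 0.0
        assert (d["counts"] > 0).sum() == 1

    def test_needs_two_persons(self):
        with pytest.raises(ValueError):
            habitual_distribution([1.0])
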