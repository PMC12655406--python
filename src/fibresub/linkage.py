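"""Linking recall events to analytical fibre densities.

Each eating occasion's bread grams are converted to fibre grams with the
median analytical fibre density of its bread category, then summed within
(person, recall day).  Persons without events on a day receive an explicit
all-zero record so that downstream usual-intake estimation sees every recall
day.  Reporter/non-reporter tabulations and contribution/rank tables are the
survey-style summaries built on top.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import BREAD_CATEGORIES


class LinkageError(ValueError):
    pass


def _check_densities(densities: dict[str, float]) -> None:
    missing = [c for c in BREAD_CATEGORIES if c not in densities]
    if missing:
        raise LinkageError(f"fibre density table is missing categories: {missing}")
    nonpos = [c for c in BREAD_CATEGORIES if densities[c] <= 0]
    if nonpos:
        raise LinkageError(f"fibre densities must be > 0; offending: {nonpos}")


def link_fibre(
    events: pd.DataFrame,
    densities: dict[str, float],
    persons: pd.DataFrame | None = None,
    n_recall_days: int = 2,
) -> pd.DataFrame:
    """Per-(person, day) bread and fibre intake by category.

    fibre[cat] = grams[cat] * density[cat] / 100.  Multiple events of a
    category within a day are summed.  When ``persons`` is given, every
    (person, day in 1..n_recall_days) pair appears, zero-filled if no event
    was reported.
    """
    _check_densities(densities)
    unknown = set(events["bread_category"]) - set(BREAD_CATEGORIES)
    if unknown:
        raise LinkageError(f"events contain unmapped bread categories: {sorted(unknown)}")

    if len(events):
        grams = events.pivot_table(
            index=["person_id", "recall_day"],
            columns="bread_category",
            values="amount",
            aggfunc="sum",
            fill_value=0.0,
        )
    else:
        grams = pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["person_id", "recall_day"])
        )
    for cat in BREAD_CATEGORIES:
        if cat not in grams.columns:
            grams[cat] = 0.0
    grams = grams[list(BREAD_CATEGORIES)]

    if persons is not None:
        full = pd.MultiIndex.from_product(
            [persons["person_id"], range(1, n_recall_days + 1)],
            names=["person_id", "recall_day"],
        )
        grams = grams.reindex(full, fill_value=0.0)

    out = grams.rename(columns={c: f"grams_{c}" for c in BREAD_CATEGORIES})
    for cat in BREAD_CATEGORIES:
        out[f"fibre_{cat}"] = grams[cat] * densities[cat] / 100.0
    out["total_grams"] = grams.sum(axis=1)
    out["total_fibre"] = sum(out[f"fibre_{c}"] for c in BREAD_CATEGORIES)
    return out.reset_index()


def nonreporter_table(persons: pd.DataFrame, events: pd.DataFrame) -> pd.DataFrame:
    """Non-reporters per (age group, sex, category), plus true non-consumers.

    A person is a *non-reporter* for a category when they logged no event of
    that category on any recall day; a *true non-consumer* logged no bread at
    all.  Percentages are relative to the stratum size.  The non-consumer
    rows carry category ``any_bread``.
    """
    merged = persons[["person_id", "age_group", "sex"]]
    reported = (
        events.merge(merged, on="person_id")
        .groupby(["age_group", "sex", "bread_category"], observed=True)["person_id"]
        .nunique()
    )
    any_reported = (
        events.merge(merged, on="person_id")
        .groupby(["age_group", "sex"], observed=True)["person_id"]
        .nunique()
    )
    sizes = merged.groupby(["age_group", "sex"], observed=True)["person_id"].nunique()

    rows = []
    for (age, sex), n_stratum in sizes.items():
        for cat in BREAD_CATEGORIES:
            n_rep = int(reported.get((age, sex, cat), 0))
            n_non = int(n_stratum) - n_rep
            rows.append({
                "age_group": age, "sex": sex, "category": cat,
                "n_stratum": int(n_stratum), "n_nonreporters": n_non,
                "pct_nonreporters": 100.0 * n_non / n_stratum,
            })
        n_non_consumer = int(n_stratum) - int(any_reported.get((age, sex), 0))
        rows.append({
            "age_group": age, "sex": sex, "category": "any_bread",
            "n_stratum": int(n_stratum), "n_nonreporters": n_non_consumer,
            "pct_nonreporters": 100.0 * n_non_consumer / n_stratum,
        })
    return pd.DataFrame(rows)


def contribution_table(habitual: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    """Contribution of each category to the stratum-mean habitual intake.

    ``habitual`` holds one row per (person, category) with the person's
    model-based usual daily intake (bread grams or fibre grams) in column
    ``habitual``.  Per (age group, sex) stratum and category the table
    reports:

    - ``mean_intake_reporters``: mean habitual intake among persons with a
      positive habitual value for the category;
    - ``mean_contribution``: mean over the whole stratum (zeros included);
    - ``pct_of_total``: 100 * mean_contribution / total stratum mean;
    - ``rank``: dense rank of the percentages, 1 = largest, ties broken by
      the fixed category declaration order.

    A stratum whose total mean intake is zero gets NaN percentages and a
    ``undefined_total`` flag.
    """
    merged = habitual.merge(persons[["person_id", "age_group", "sex"]], on="person_id")
    rows = []
    for (age, sex), grp in merged.groupby(["age_group", "sex"], observed=True):
        n_persons = grp["person_id"].nunique()
        means = {}
        reporters = {}
        for cat in BREAD_CATEGORIES:
            sub = grp[grp["category"] == cat]
            # zeros for persons without a row for this category
            means[cat] = sub["habitual"].sum() / n_persons
            pos = sub.loc[sub["habitual"] > 0, "habitual"]
            reporters[cat] = (float(pos.mean()) if len(pos) else float("nan"), len(pos))
        total = sum(means.values())
        undefined = total <= 0
        pcts = {
            cat: (float("nan") if undefined else 100.0 * means[cat] / total)
            for cat in BREAD_CATEGORIES
        }
        order = sorted(
            BREAD_CATEGORIES,
            key=lambda c: (-(pcts[c] if not np.isnan(pcts[c]) else -np.inf),
                           BREAD_CATEGORIES.index(c)),
        )
        ranks = {cat: order.index(cat) + 1 for cat in BREAD_CATEGORIES}
        for cat in BREAD_CATEGORIES:
            rows.append({
                "age_group": age, "sex": sex, "category": cat,
                "n_reporters": reporters[cat][1],
                "mean_intake_reporters": reporters[cat][0],
                "mean_contribution": means[cat],
                "total_mean": total,
                "pct_of_total": pcts[cat],
                "rank": ranks[cat],
                "undefined_total": undefined,
            })
    return pd.DataFrame(rows)
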