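"""Synthetic dietary-survey generator.

Produces a persons table, a consumption-events table (person x recall day x
bread category, zero-inflated log-normal amounts) and analytical bread
samples with the statistical structure the downstream habitual-intake
analysis assumes: stable person-level differences in both the propensity to
eat a bread category and the amount eaten, plus independent day-to-day noise.

Zero inflation is modelled per (person, day, category) with independent
Bernoulli draws given the person's latent propensity; at most one event per
(person, day, category) is emitted.  The latent propensity factor and the
person-level amount effect may share one Gaussian factor through a
configurable correlation (default 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import AGE_GROUPS, BREAD_CATEGORIES, CohortConfig, ConfigError
from .defaults import BREAD_SAMPLE_PARAMS

PERSON_COLUMNS = [
    "person_id", "sex", "age_group", "region", "urbanisation",
    "education", "employment", "income", "ipaq", "smoking",
]
EVENT_COLUMNS = ["person_id", "recall_day", "bread_category", "amount"]
SAMPLE_COLUMNS = [
    "sample_id", "declared_category", "assigned_category", "has_seeds", "outlet", "fibre",
]

#: covariates undefined for adolescents (school-age participants).
ADULT_ONLY_COVARIATES = ("education", "employment", "smoking")

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(41)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _calibrated_logit(p: float, propensity_sd: float) -> float:
    """Baseline logit such that E_u[sigmoid(alpha + s*u)] = p for u ~ N(0,1).

    Gauss-Hermite quadrature over the latent factor; keeps the configured
    preference the *marginal* daily consumption probability regardless of the
    person-effect scale.
    """
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    if propensity_sd == 0.0:
        return float(np.log(p / (1.0 - p)))

    def marginal(alpha: float) -> float:
        return float(_GH_WEIGHTS @ _sigmoid(alpha + propensity_sd * _GH_NODES)) - p

    lo = np.log(p / (1 - p)) - 8 * propensity_sd - 1
    hi = np.log(p / (1 - p)) + 8 * propensity_sd + 1
    return float(optimize.brentq(marginal, lo, hi, xtol=1e-12))


def _draw_categorical(rng: np.random.Generator, weights: dict[str, float], n: int) -> np.ndarray:
    labels = np.array(list(weights.keys()), dtype=object)
    probs = np.array(list(weights.values()), dtype=float)
    probs = probs / probs.sum()
    return labels[rng.choice(len(labels), size=n, p=probs)]


def generate_cohort(
    config: CohortConfig, return_latents: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the synthetic survey.

    Returns
    -------
    persons : DataFrame with :data:`PERSON_COLUMNS`
    events : DataFrame with :data:`EVENT_COLUMNS`; absence of a row encodes
        zero consumption (no zero-amount rows are emitted).
    latents : only when ``return_latents``; per person the latent propensity
        factor ``u`` and the amount person effect ``b`` (standard scale),
        for validating estimators against generator truth.

    Identical config (including seed) gives bit-identical output.  The root
    seed is split deterministically into independent sub-streams (persons,
    events) so the draws of one stage never shift another.
    """
    root = np.random.SeedSequence(config.seed)
    persons_ss, events_ss, _samples_ss = root.spawn(3)
    prng = np.random.default_rng(persons_ss)
    erng = np.random.default_rng(events_ss)

    n = config.n_persons
    persons = pd.DataFrame({
        "person_id": [f"P{i + 1:05d}" for i in range(n)],
        "sex": _draw_categorical(prng, config.sex_weights, n),
        "age_group": _draw_categorical(prng, config.age_group_weights, n),
    })
    for cov in ("region", "urbanisation", "education", "employment", "income", "ipaq", "smoking"):
        weights = config.covariate_weights.get(cov)
        persons[cov] = _draw_categorical(prng, weights, n) if weights else pd.NA
    adolescent = persons["age_group"] == "adolescent"
    persons.loc[adolescent, list(ADULT_ONLY_COVARIATES)] = pd.NA
    persons = persons[PERSON_COLUMNS]

    # latent person factors: u drives consumption propensity, b the amount
    # person effect; they share variance through the configured correlation.
    u = erng.standard_normal(n)
    z = erng.standard_normal(n)
    rho = config.propensity_amount_corr
    b = rho * u + np.sqrt(1.0 - rho**2) * z

    # calibrated per-stratum baseline logits (cache: few strata)
    logit_cache: dict[tuple[str, str, str], float] = {}
    for key, p in config.category_preference.items():
        logit_cache[key] = _calibrated_logit(p, config.propensity_sd)

    age = persons["age_group"].to_numpy()
    sex = persons["sex"].to_numpy()
    sd_b, sd_w = config.amount_log_sd_between, config.amount_log_sd_within

    rows: list[pd.DataFrame] = []
    for cat in BREAD_CATEGORIES:
        alpha = np.full(n, -np.inf)
        mu = np.zeros(n)
        seen = np.zeros(n, dtype=bool)
        for (a, s), _ in {(x, y): 0 for x, y in zip(age, sex)}.items():
            mask = (age == a) & (sex == s)
            key = (a, s, cat)
            if key in logit_cache:
                alpha[mask] = logit_cache[key]
                mu[mask] = config.amount_log_mean.get(key, 0.0)
                seen[mask] = True
        p_person = np.where(
            np.isneginf(alpha), 0.0,
            np.where(np.isposinf(alpha), 1.0, _sigmoid(alpha + config.propensity_sd * u)),
        )
        for day in range(1, config.n_recall_days + 1):
            eats = erng.random(n) < p_person
            if not eats.any():
                continue
            log_amt = mu[eats] + sd_b * b[eats] + sd_w * erng.standard_normal(int(eats.sum()))
            rows.append(pd.DataFrame({
                "person_id": persons.loc[eats, "person_id"].to_numpy(),
                "recall_day": day,
                "bread_category": cat,
                "amount": np.exp(log_amt),
            }))

    if rows:
        events = pd.concat(rows, ignore_index=True)
        events = events.sort_values(
            ["person_id", "recall_day", "bread_category"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    if return_latents:
        latents = pd.DataFrame({
            "person_id": persons["person_id"], "u_propensity": u, "b_amount": b,
        })
        return persons, events[EVENT_COLUMNS], latents
    return persons, events[EVENT_COLUMNS]


_ALLOWED_SAMPLE_CATEGORIES = tuple(BREAD_CATEGORIES) + ("mixed_with_seeds", "mixed_without_seeds")


def generate_bread_samples(
    per_category_params: dict[str, tuple[float, float, int]] | None = None,
    seed: int = 0,
    outlet: str = "large_retail",
) -> pd.DataFrame:
    """Draw analytical bread samples from per-category truncated normals.

    ``per_category_params`` maps category -> (mean g/100 g, sd, n); fibre
    values are drawn from a normal truncated at zero.  Categories
    ``mixed_with_seeds`` / ``mixed_without_seeds`` are accepted and map to the
    ``mixed`` category with the seed flag set accordingly.
    """
    params = per_category_params if per_category_params is not None else BREAD_SAMPLE_PARAMS
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])

    rows = []
    idx = 0
    for cat, (mean, sd, n) in params.items():
        if cat not in _ALLOWED_SAMPLE_CATEGORIES:
            raise ConfigError(
                f"unknown bread category {cat!r}; allowed: {_ALLOWED_SAMPLE_CATEGORIES}"
            )
        if n < 1:
            raise ConfigError(f"{cat}: sample count must be >= 1 (got {n})")
        if sd < 0:
            raise ConfigError(f"{cat}: sd must be >= 0 (got {sd})")
        if sd == 0:
            fibre = np.full(n, float(mean))
        else:
            a = (0.0 - mean) / sd  # truncate at zero
            fibre = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
        if cat == "mixed_with_seeds":
            assigned, seeds = "mixed", True
        elif cat == "mixed_without_seeds":
            assigned, seeds = "mixed", False
        elif cat == "mixed":
            assigned, seeds = "mixed", False
        else:
            assigned, seeds = cat, False
        for f in fibre:
            idx += 1
            rows.append({
                "sample_id": f"S{idx:03d}",
                "declared_category": assigned,
                "assigned_category": assigned,
                "has_seeds": seeds,
                "outlet": outlet,
                "fibre": float(f),
            })
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
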