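"""Usual (habitual) intake estimation from sparse repeated 24-h recalls.

Two or three recall days per person are too few to read off anyone's long-run
average: the observed day-to-day values mix the stable person level with
large within-person noise.  The estimator here is a transparent two-part
model in the tradition of the Multiple Source Method and the NCI method:

Part 1 (probability)
    The day-level consumption indicator is regressed on person-level
    covariates plus the person's observed reporting frequency; the fitted
    person value, clipped to [0, 1], is the usual probability of consuming
    on a day.

Part 2 (amount)
    Positive-day amounts are transformed (log1p by default), covariate fixed
    effects are removed by OLS, and the residual variance is split into
    between-person (sigma^2_b) and within-person (sigma^2_w) components by
    one-way method-of-moments ANOVA on the person grouping.  Each person's
    residual mean is shrunk toward its covariate prediction with

        lambda_i = sigma^2_b / (sigma^2_b + sigma^2_w / n_i),

    and the person's usual consumption-day amount is recovered on the
    original scale by Duan-type smearing over the pooled within-person
    residual deviations together with Gauss-Hermite integration of the
    shrinkage posterior (exactly the observed mean when shrinkage is off).

The habitual intake is the product of the two parts.  No claim of
bit-compatibility with the external MSM program is made; the covariate set
and the variance decomposition follow the same design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BREAD_CATEGORIES, HabitualModelSpec
from .linkage import link_fibre

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# transforms


def _forward(y: np.ndarray, spec: HabitualModelSpec) -> np.ndarray:
    if spec.transform == "log1p":
        return np.log1p(y)
    if spec.transform == "identity":
        return np.asarray(y, dtype=float)
    lam = spec.box_cox_lambda
    if lam == 0.0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def _inverse(z: np.ndarray, spec: HabitualModelSpec) -> np.ndarray:
    if spec.transform == "log1p":
        return np.expm1(z)
    if spec.transform == "identity":
        return np.asarray(z, dtype=float)
    lam = spec.box_cox_lambda
    if lam == 0.0:
        return np.exp(z)
    return np.power(np.maximum(lam * z + 1.0, 0.0), 1.0 / lam)


def _design(frame: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    """Intercept + dummy-coded categorical covariates + numeric columns."""
    cols = [np.ones(len(frame))]
    for cov in covariates:
        if cov == "reporting_frequency":
            cols.append(frame["reporting_frequency"].to_numpy(dtype=float))
        else:
            values = frame[cov].astype(str)
            levels = sorted(values.unique())
            for level in levels[1:]:  # first level is the reference
                cols.append((values == level).to_numpy(dtype=float))
    return np.column_stack(cols)


def _variance_components(resid: np.ndarray, person_idx: np.ndarray) -> tuple[float, float]:
    """Unbalanced one-way method-of-moments decomposition of residuals.

    Returns (sigma^2_between, sigma^2_within); a negative between estimate is
    clipped to zero (full shrinkage).
    """
    k = person_idx.max() + 1
    n_i = np.bincount(person_idx, minlength=k).astype(float)
    sums = np.bincount(person_idx, weights=resid, minlength=k)
    means = np.divide(sums, n_i, out=np.zeros_like(sums), where=n_i > 0)
    within_ss = float(np.sum((resid - means[person_idx]) ** 2))
    df_within = float(np.sum(np.maximum(n_i - 1.0, 0.0)))
    sigma2_w = within_ss / df_within if df_within > 0 else 0.0

    groups = n_i > 0
    k_eff = int(groups.sum())
    n_total = float(n_i.sum())
    if k_eff < 2:
        return 0.0, sigma2_w
    grand = float(resid.mean())
    between_ss = float(np.sum(n_i[groups] * (means[groups] - grand) ** 2))
    msb = between_ss / (k_eff - 1)
    n0 = (n_total - float(np.sum(n_i[groups] ** 2)) / n_total) / (k_eff - 1)
    sigma2_b = max(0.0, (msb - sigma2_w) / n0) if n0 > 0 else 0.0
    return sigma2_b, sigma2_w


def shrinkage_factor(sigma2_between: float, sigma2_within: float, n_days: int) -> float:
    """lambda = sigma^2_b / (sigma^2_b + sigma^2_w / n); 1 in the noiseless limit."""
    denom = sigma2_between + sigma2_within / n_days
    if denom == 0.0:
        return 1.0
    return sigma2_between / denom


# ---------------------------------------------------------------------------
# model / results


@dataclass
class HabitualIntakeResults:
    """Per-person habitual-intake estimates and variance components."""

    estimates: pd.DataFrame
    sigma2_between: float
    sigma2_within: float
    spec: HabitualModelSpec
    n_persons: int
    n_persondays: int
    excluded_persons: list[str] = field(default_factory=list)
    quantity: str = "value"

    def summary(self) -> str:
        est = self.estimates
        lines = [
            "Habitual intake model (two-part, shrinkage)",
            "=" * 46,
            f"quantity:           {self.quantity}",
            f"transform:          {self.spec.transform}",
            f"covariates:         {', '.join(self.spec.covariates)}",
            f"persons:            {self.n_persons}"
            + (f"  (excluded: {len(self.excluded_persons)})" if self.excluded_persons else ""),
            f"person-days:        {self.n_persondays}",
            f"sigma^2 between:    {self.sigma2_between:.6f}",
            f"sigma^2 within:     {self.sigma2_within:.6f}",
            f"mean prob:          {est['prob'].mean():.4f}",
            f"mean habitual:      {est['habitual'].mean():.4f}",
            f"SD habitual:        {est['habitual'].std(ddof=1):.4f}",
        ]
        return "\n".join(lines)


class HabitualIntakeModel:
    """Two-part usual-intake model for one daily quantity.

    Parameters
    ----------
    persondays
        One row per (person, recall day) with the daily amount in
        ``value_col`` (zero on non-consumption days).
    persons
        Person table carrying the covariates.
    spec
        Transform, covariate set, minimum recall days and shrinkage switch.
    value_col
        Column of ``persondays`` holding the daily amount.
    """

    def __init__(
        self,
        persondays: pd.DataFrame,
        persons: pd.DataFrame,
        spec: HabitualModelSpec | None = None,
        value_col: str = "total_fibre",
    ) -> None:
        self.spec = spec or HabitualModelSpec()
        self.value_col = value_col
        cov_cols = [c for c in self.spec.covariates if c != "reporting_frequency"]
        data = persondays.merge(persons[["person_id"] + cov_cols], on="person_id", how="left")
        counts = data.groupby("person_id")["recall_day"].count()
        keep = counts[counts >= self.spec.min_days].index
        self.excluded_persons = sorted(set(counts.index) - set(keep))
        if self.excluded_persons:
            logger.info(
                "excluding %d persons with fewer than %d recall days",
                len(self.excluded_persons), self.spec.min_days,
            )
        self.data = data[data["person_id"].isin(keep)].copy()

    @classmethod
    def from_events(
        cls,
        events: pd.DataFrame,
        persons: pd.DataFrame,
        densities: dict[str, float],
        spec: HabitualModelSpec | None = None,
        quantity: str = "total_fibre",
        n_recall_days: int = 2,
    ) -> "HabitualIntakeModel":
        persondays = link_fibre(events, densities, persons=persons, n_recall_days=n_recall_days)
        return cls(persondays, persons, spec=spec, value_col=quantity)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> HabitualIntakeResults:
        spec = self.spec
        data = self.data
        y = data[self.value_col].to_numpy(dtype=float)
        consumed = y > 0

        person_ids, person_idx = np.unique(data["person_id"].to_numpy(), return_inverse=True)
        n_persons = len(person_ids)

        freq = np.bincount(person_idx, weights=consumed.astype(float)) / np.bincount(person_idx)
        data = data.assign(reporting_frequency=freq[person_idx])
        person_rows = data.groupby("person_id", sort=True).head(1).sort_values("person_id")

        if not consumed.any():
            warnings.warn(
                f"{self.value_col}: all daily amounts are zero; habitual set to 0",
                stacklevel=2,
            )
            est = pd.DataFrame({
                "person_id": person_ids,
                "prob": 0.0,
                "usual_amount_on_consumption_days": 0.0,
                "habitual": 0.0,
                "n_days": np.bincount(person_idx),
                "n_consumption_days": 0,
            })
            return HabitualIntakeResults(
                est, 0.0, 0.0, spec, n_persons, len(data),
                self.excluded_persons, self.value_col,
            )

        # Part 1: usual consumption probability
        X_day = _design(data, spec.covariates)
        beta_p, *_ = np.linalg.lstsq(X_day, consumed.astype(float), rcond=None)
        X_person = _design(person_rows, spec.covariates)
        prob = np.clip(X_person @ beta_p, 0.0, 1.0)

        # Part 2: usual amount on consumption days
        pos = data[consumed].copy()
        z = _forward(pos[self.value_col].to_numpy(dtype=float), spec)
        Xa = _design(pos, spec.covariates)
        beta_a, *_ = np.linalg.lstsq(Xa, z, rcond=None)
        resid = z - Xa @ beta_a

        pos_ids, pos_idx = np.unique(pos["person_id"].to_numpy(), return_inverse=True)
        sigma2_b, sigma2_w = _variance_components(resid, pos_idx)

        n_i = np.bincount(pos_idx).astype(float)
        rbar = np.bincount(pos_idx, weights=resid) / n_i

        if spec.shrink:
            lam = np.array([
                shrinkage_factor(sigma2_b, sigma2_w, int(n)) for n in n_i
            ])
            # person-level covariate prediction (covariates are person-constant)
            pos_person_rows = pos.groupby("person_id", sort=True).head(1).sort_values("person_id")
            Xp = _design_like(pos_person_rows, pos, spec)
            mu = Xp @ beta_a + lam * rbar
            usual_pos = _mean_consistent_backtransform(
                mu, n_i, lam, resid, rbar, pos_idx, sigma2_b, spec
            )
        else:
            # no shrinkage: the estimator reduces exactly to the observed
            # mean amount on consumption days.
            amounts = pos[self.value_col].to_numpy(dtype=float)
            usual_pos = np.bincount(pos_idx, weights=amounts) / n_i

        usual_map = dict(zip(pos_ids, usual_pos))
        ndays_map = dict(zip(pos_ids, n_i.astype(int)))
        usual = np.array([usual_map.get(pid, 0.0) for pid in person_ids])

        habitual = prob * usual
        est = pd.DataFrame({
            "person_id": person_ids,
            "prob": prob,
            "usual_amount_on_consumption_days": usual,
            "habitual": habitual,
            "n_days": np.bincount(person_idx),
            "n_consumption_days": [ndays_map.get(pid, 0) for pid in person_ids],
        })
        est["sigma2_between"] = sigma2_b
        est["sigma2_within"] = sigma2_w
        return HabitualIntakeResults(
            est, sigma2_b, sigma2_w, spec, n_persons, len(data),
            self.excluded_persons, self.value_col,
        )


def _mean_consistent_backtransform(
    mu: np.ndarray,
    n_i: np.ndarray,
    lam: np.ndarray,
    resid: np.ndarray,
    rbar: np.ndarray,
    pos_idx: np.ndarray,
    sigma2_b: float,
    spec: HabitualModelSpec,
) -> np.ndarray:
    """Back-transform shrunken person means to the original scale.

    Two sources of transformed-scale dispersion must be integrated out for
    the original-scale mean to be preserved:

    * day-to-day noise, handled by Duan-type smearing over the pooled
      within-person residual deviations (rescaled by sqrt(n/(n-1)), since
      observed deviations carry only (1 - 1/n) of the within variance);
    * the person-effect uncertainty left after shrinkage,
      Var(b_i | rbar_i) = (1 - lambda_i) * sigma^2_b, integrated by
      Gauss-Hermite quadrature over a normal person effect.

    For log-type transforms this reproduces the closed-form lognormal mean;
    for the identity transform both corrections vanish by linearity.
    """
    dev = resid - rbar[pos_idx]
    scale = np.sqrt(np.divide(n_i, n_i - 1.0, out=np.ones_like(n_i), where=n_i > 1))
    mask = n_i[pos_idx] > 1
    pool = dev[mask] * scale[pos_idx][mask]
    if pool.size == 0:
        pool = np.zeros(1)
    elif pool.size > 128:
        # deterministic quantile sketch of the deviation distribution
        pool = np.quantile(pool, (np.arange(128) + 0.5) / 128)

    nodes, gh_w = np.polynomial.hermite_e.hermegauss(11)
    gh_w = gh_w / gh_w.sum()

    usual = np.zeros(len(mu))
    for n in np.unique(n_i):
        sel = n_i == n
        lam_n = float(lam[sel][0])
        post_sd = np.sqrt(max(1.0 - lam_n, 0.0) * sigma2_b)
        offsets = (post_sd * nodes[:, None] + pool[None, :]).ravel()
        w = np.repeat(gh_w / pool.size, pool.size)
        mu_sel = mu[sel]
        vals = np.empty(mu_sel.size)
        for start in range(0, mu_sel.size, 2048):  # bound peak memory
            block = mu_sel[start:start + 2048]
            vals[start:start + 2048] = _inverse(block[:, None] + offsets[None, :], spec) @ w
        usual[sel] = np.maximum(vals, 0.0)
    return usual


def _design_like(person_rows: pd.DataFrame, full: pd.DataFrame, spec: HabitualModelSpec) -> np.ndarray:
    """Design for person rows using the dummy levels of the full positive-day frame."""
    cols = [np.ones(len(person_rows))]
    for cov in spec.covariates:
        if cov == "reporting_frequency":
            cols.append(person_rows["reporting_frequency"].to_numpy(dtype=float))
        else:
            levels = sorted(full[cov].astype(str).unique())
            values = person_rows[cov].astype(str)
            for level in levels[1:]:
                cols.append((values == level).to_numpy(dtype=float))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# drivers


def fit_habitual(
    persondays: pd.DataFrame,
    persons: pd.DataFrame,
    spec: HabitualModelSpec | None = None,
    quantities: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Fit the two-part model for every requested quantity column.

    By default fits total bread grams, total fibre grams and the per-category
    bread-gram and fibre-gram columns produced by :func:`link_fibre`.
    Returns one long frame: person_id, quantity, category, prob,
    usual_amount, habitual, sigma2_between, sigma2_within.
    """
    if quantities is None:
        quantities = (
            ["total_grams", "total_fibre"]
            + [f"grams_{c}" for c in BREAD_CATEGORIES]
            + [f"fibre_{c}" for c in BREAD_CATEGORIES]
        )
    frames = []
    for col in quantities:
        res = HabitualIntakeModel(persondays, persons, spec=spec, value_col=col).fit()
        frame = res.estimates[[
            "person_id", "prob", "usual_amount_on_consumption_days", "habitual",
        ]].copy()
        if col.startswith("grams_"):
            quantity, category = "bread_grams", col[len("grams_"):]
        elif col.startswith("fibre_"):
            quantity, category = "fibre_grams", col[len("fibre_"):]
        elif col == "total_grams":
            quantity, category = "bread_grams", "total"
        else:
            quantity, category = "fibre_grams", "total"
        frame.insert(1, "quantity", quantity)
        frame.insert(2, "category", category)
        frame["sigma2_between"] = res.sigma2_between
        frame["sigma2_within"] = res.sigma2_within
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def habitual_distribution(
    values: np.ndarray | pd.Series,
    bin_width: float = 0.5,
    percentiles: tuple[float, ...] = (5, 25, 50, 75, 95),
) -> dict:
    """Summary of a habitual-intake distribution: mean, SD, percentiles and a
    fixed-width histogram starting at zero."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("habitual_distribution: need at least 2 persons")
    hi = max(float(v.max()), bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(v, bins=edges)
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        "percentiles": {f"p{int(p)}": float(np.percentile(v, p)) for p in percentiles},
        "bin_edges": edges,
        "counts": counts,
    }
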