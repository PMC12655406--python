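"""Adaptive LASSO selection of sociodemographic determinants.

The response is each participant's bread fibre density (grams of fibre per
100 g of bread consumed, from the habitual-intake model); the predictors are
dummy-coded sociodemographic and lifestyle factors.  An initial unpenalized
fit supplies per-coefficient adaptive weights w_j = 1 / |beta_init_j|^gamma,
and the penalized problem

    (1 / 2n) * ||y - X beta||^2 + lambda * sum_j w_j |beta_j|

is solved by cyclic coordinate descent over a decreasing lambda path, with
the penalty chosen by K-fold cross-validation and the one-standard-error
rule.  Columns are standardized to unit variance before penalization;
reported coefficients are returned on the original scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: convergence threshold on the maximum coefficient change per sweep.
CD_TOL = 1e-7
_MAX_SWEEPS = 100_000
#: an initial coefficient of exactly zero gives an effectively infinite
#: penalty weight; capped to keep arithmetic finite.
_WEIGHT_CAP = 1e12


def _soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    weights: np.ndarray,
    beta0: np.ndarray | None = None,
    tol: float = CD_TOL,
) -> np.ndarray:
    """Cyclic coordinate descent for the weighted lasso (no intercept).

    Minimizes (1/2n)||y - X beta||^2 + lam * sum w_j |beta_j|.  ``X`` and
    ``y`` are assumed centered.  Warm start via ``beta0``.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    col_sq = (X * X).sum(axis=0) / n
    resid = y - X @ beta
    for _ in range(_MAX_SWEEPS):
        max_change = 0.0
        for j in range(p):
            if col_sq[j] == 0.0:
                continue
            old = beta[j]
            rho = (X[:, j] @ resid) / n + col_sq[j] * old
            new = _soft_threshold(rho, lam * weights[j]) / col_sq[j]
            if new != old:
                resid += X[:, j] * (old - new)
                beta[j] = new
                max_change = max(max_change, abs(new - old))
        if max_change < tol:
            break
    return beta


@dataclass
class AdaptiveLassoResults:
    """Fitted adaptive-LASSO path and the selected model."""

    feature_names: list[str]
    coefficients: np.ndarray  # original scale, at the chosen lambda
    intercept: float
    lambda_selected: float
    lambda_path: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    adaptive_weights: np.ndarray  # on the standardized scale
    coef_path: np.ndarray  # (n_lambda, p), original scale
    rule: str = "1se"
    selected: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.selected = [
            name for name, b in zip(self.feature_names, self.coefficients) if b != 0.0
        ]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    def summary(self) -> str:
        lines = [
            "Adaptive LASSO",
            "=" * 40,
            f"lambda ({self.rule} rule): {self.lambda_selected:.6g}",
            f"selected {len(self.selected)} / {len(self.feature_names)} predictors",
            "",
            f"{'predictor':<32}{'coef':>12}",
        ]
        for name, b in zip(self.feature_names, self.coefficients):
            mark = " *" if b != 0.0 else ""
            lines.append(f"{name:<32}{b:>12.5f}{mark}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "lambda_selected": float(self.lambda_selected),
            "rule": self.rule,
            "lambda_path": self.lambda_path.tolist(),
            "cv_mean": self.cv_mean.tolist(),
            "cv_se": self.cv_se.tolist(),
            "adaptive_weights": self.adaptive_weights.tolist(),
            "coefficients": dict(zip(self.feature_names, map(float, self.coefficients))),
            "intercept": float(self.intercept),
            "selected": self.selected,
        }


class AdaptiveLasso:
    """Adaptive-LASSO linear model.

    Parameters
    ----------
    X, y
        Design matrix (no intercept column) and response.
    feature_names
        Optional column labels.
    gamma
        Exponent of the adaptive weights, w_j = 1/|beta_init_j|^gamma.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        feature_names: list[str] | None = None,
        gamma: float = 1.0,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be 2-D with one row per element of y")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response contains non-finite values")
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j}" for j in range(self.X.shape[1])]
        )
        self.gamma = gamma

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        factors: list[str],
        continuous: list[str] | None = None,
        gamma: float = 1.0,
    ) -> "AdaptiveLasso":
        """Dummy-code factor columns (first level as reference) and stack
        continuous columns."""
        cols, names = [], []
        for f in factors:
            values = data[f].astype(str)
            levels = sorted(values.unique())
            for level in levels[1:]:
                cols.append((values == level).to_numpy(dtype=float))
                names.append(f"{f}[{level}]")
        for c in continuous or []:
            cols.append(data[c].to_numpy(dtype=float))
            names.append(c)
        X = np.column_stack(cols) if cols else np.empty((len(data), 0))
        return cls(X, data[response].to_numpy(dtype=float), feature_names=names, gamma=gamma)

    # -- internals ---------------------------------------------------------

    def _standardize(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
        x_mean = self.X.mean(axis=0)
        x_sd = self.X.std(axis=0, ddof=0)
        x_sd_safe = np.where(x_sd > 0, x_sd, 1.0)
        Xs = (self.X - x_mean) / x_sd_safe
        y_mean = float(self.y.mean())
        return Xs, x_mean, x_sd, x_sd_safe, y_mean

    def _initial_weights(self, Xs: np.ndarray, yc: np.ndarray) -> np.ndarray:
        n, p = Xs.shape
        if n > p and p > 0:
            beta_init, _, rank, _ = np.linalg.lstsq(Xs, yc, rcond=None)
            if rank < p:
                logger.warning("singular initial fit; falling back to ridge weights")
                beta_init = np.linalg.solve(Xs.T @ Xs / n + 1e-3 * np.eye(p), Xs.T @ yc / n)
        else:
            logger.warning("n <= p; using ridge weights for the adaptive penalty")
            beta_init = np.linalg.solve(
                Xs.T @ Xs / max(n, 1) + 1e-3 * np.eye(p), Xs.T @ yc / max(n, 1)
            )
        with np.errstate(divide="ignore"):
            w = 1.0 / np.abs(beta_init) ** self.gamma
        return np.minimum(w, _WEIGHT_CAP)

    def null_lambda(self) -> float:
        """Smallest lambda at which every coefficient is zero:
        max_j |x_j' y / n| / w_j on the standardized, centered problem."""
        Xs, _, _, _, y_mean = self._standardize()
        yc = self.y - y_mean
        w = self._initial_weights(Xs, yc)
        n = len(yc)
        grads = np.abs(Xs.T @ yc) / n
        return float(np.max(grads / w)) if len(grads) else 0.0

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        lambda_path: np.ndarray | None = None,
        cv_folds: int = 10,
        seed: int = 0,
        rule: str = "1se",
        n_lambda: int = 50,
        lambda_min_ratio: float = 1e-3,
    ) -> AdaptiveLassoResults:
        """Fit the path and pick lambda by K-fold cross-validation.

        ``rule`` is ``"1se"`` (largest lambda within one standard error of
        the CV minimum) or ``"min"``.  Deterministic under ``seed``.
        """
        Xs, x_mean, x_sd, x_sd_safe, y_mean = self._standardize()
        yc = self.y - y_mean
        n, p = Xs.shape
        weights = self._initial_weights(Xs, yc)

        if lambda_path is None:
            lam_max = self.null_lambda()
            if lam_max <= 0:
                lam_max = 1.0
            lambda_path = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
        lambda_path = np.asarray(lambda_path, dtype=float)
        if np.any(np.diff(lambda_path) > 0):
            raise ValueError("lambda_path must be decreasing")

        # cross-validated prediction error
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        folds = np.array_split(perm, cv_folds)
        errors = np.full((cv_folds, len(lambda_path)), np.nan)
        for k, test_idx in enumerate(folds):
            train = np.setdiff1d(perm, test_idx, assume_unique=True)
            Xt, yt = Xs[train], yc[train]
            Xv, yv = Xs[test_idx], yc[test_idx]
            beta = np.zeros(p)
            for li, lam in enumerate(lambda_path):
                beta = coordinate_descent(Xt, yt, lam, weights, beta0=beta)
                errors[k, li] = float(np.mean((yv - Xv @ beta) ** 2))
        cv_mean = errors.mean(axis=0)
        cv_se = errors.std(axis=0, ddof=1) / np.sqrt(cv_folds)

        i_min = int(np.argmin(cv_mean))
        if rule == "1se":
            cutoff = cv_mean[i_min] + cv_se[i_min]
            candidates = np.where(cv_mean <= cutoff)[0]
            i_sel = int(candidates[0])  # path is decreasing: first = largest lambda
        elif rule == "min":
            i_sel = i_min
        else:
            raise ValueError(f"unknown rule {rule!r}")

        # full-data path with warm starts; keep coefficients at every lambda
        coef_path = np.zeros((len(lambda_path), p))
        beta = np.zeros(p)
        for li, lam in enumerate(lambda_path):
            beta = coordinate_descent(Xs, yc, lam, weights, beta0=beta)
            coef_path[li] = beta
        beta_sel = coef_path[i_sel]

        # back to the original scale
        coef_orig_path = coef_path / x_sd_safe
        coef_orig_path[:, x_sd == 0] = 0.0
        coefficients = coef_orig_path[i_sel]
        intercept = y_mean - float(x_mean @ coefficients)

        return AdaptiveLassoResults(
            feature_names=self.feature_names,
            coefficients=coefficients,
            intercept=intercept,
            lambda_selected=float(lambda_path[i_sel]),
            lambda_path=lambda_path,
            cv_mean=cv_mean,
            cv_se=cv_se,
            adaptive_weights=weights,
            coef_path=coef_orig_path,
            rule=rule,
        )


def fit_adaptive_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lambda_path: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    **kwargs,
) -> AdaptiveLassoResults:
    """Functional wrapper around :class:`AdaptiveLasso`."""
    return AdaptiveLasso(X, y, **kwargs).fit(
        lambda_path=lambda_path, cv_folds=cv_folds, seed=seed
    )


# ---------------------------------------------------------------------------
# determinants analysis

#: factors observed for every participant.
COMMON_FACTORS = ["sex", "age_group", "urbanisation", "region", "ipaq", "income"]
#: factors observed only for adults and older adults.
ADULT_ONLY_FACTORS = ["education", "employment", "smoking"]


def select_determinants(
    data: pd.DataFrame,
    response: str = "fibre_density",
    seed: int = 0,
    cv_folds: int = 10,
    rule: str = "1se",
) -> dict:
    """Adaptive-LASSO selection of determinants of bread fibre density.

    ``data`` is one row per participant with the response column and the
    sociodemographic factors.  Factors undefined for adolescents (education,
    employment, smoking) are fitted on the adult subsample in a second model;
    their selection status comes from that fit.  A continuous ``bmi`` column
    is included when present.  Returns the two fits and the per-variable
    selection map.
    """
    continuous = ["bmi"] if "bmi" in data.columns else []
    fit_all = AdaptiveLasso.from_dataframe(
        data, response, COMMON_FACTORS, continuous=continuous
    ).fit(cv_folds=cv_folds, seed=seed, rule=rule)

    adults = data[data["age_group"] != "adolescent"]
    adult_factors = [f for f in ADULT_ONLY_FACTORS if data[f].notna().any()]
    fit_adults = None
    if len(adults) and adult_factors:
        logger.info(
            "fitting adult-only factors %s on the %d-person adult subsample",
            adult_factors, len(adults),
        )
        fit_adults = AdaptiveLasso.from_dataframe(
            adults.dropna(subset=adult_factors),
            response,
            COMMON_FACTORS + adult_factors,
            continuous=continuous,
        ).fit(cv_folds=cv_folds, seed=seed, rule=rule)

    def _var_selected(fit: AdaptiveLassoResults | None, variable: str) -> bool:
        if fit is None:
            return False
        return any(name.startswith(f"{variable}[") or name == variable for name in fit.selected)

    selection = {v: _var_selected(fit_all, v) for v in COMMON_FACTORS + continuous}
    for v in ADULT_ONLY_FACTORS:
        selection[v] = _var_selected(fit_adults, v)
    return {"fit_all": fit_all, "fit_adults": fit_adults, "selection": selection}


def determinant_report(data: pd.DataFrame, selection: dict, response: str = "fibre_density") -> pd.DataFrame:
    """Per variable-level descriptives with the LASSO selection marker.

    One row per (variable, level): n, % within the variable's non-missing
    sample, mean (SD) of the response, and ``selected`` = True when any level
    of the variable carried a nonzero coefficient.
    """
    rows = []
    for variable in COMMON_FACTORS + ADULT_ONLY_FACTORS + (["bmi"] if "bmi" in data.columns else []):
        if variable not in data.columns:
            continue
        if variable == "bmi":
            rows.append({
                "variable": "bmi", "level": "(continuous)",
                "n": int(data["bmi"].notna().sum()), "pct": 100.0,
                "mean": float(data[response].mean()), "sd": float(data[response].std(ddof=1)),
                "selected": bool(selection.get("bmi", False)),
            })
            continue
        sub = data[data[variable].notna()]
        n_var = len(sub)
        for level, grp in sub.groupby(variable, observed=True, sort=True):
            rows.append({
                "variable": variable, "level": str(level),
                "n": int(len(grp)), "pct": 100.0 * len(grp) / n_var if n_var else float("nan"),
                "mean": float(grp[response].mean()),
                "sd": float(grp[response].std(ddof=1)) if len(grp) > 1 else float("nan"),
                "selected": bool(selection.get(variable, False)),
            })
    return pd.DataFrame(rows)
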