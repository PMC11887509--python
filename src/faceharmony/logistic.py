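"""Binary logistic regression by IRLS, and forward-backward AIC selection.

The fit is a plain Newton/Fisher-scoring iteration written as
iteratively reweighted least squares, with step-halving so the deviance
path is non-increasing on every fit that converges.  Quasi-separation —
common in small surgical cohorts where a predictor level has no
failures — is flagged (huge standard errors, capped iterations) rather
than raised, so separated fits still report the table structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import InvalidMeasurementError

#: A coefficient standard error above this flags quasi-separation.
SEPARATION_SE = 100.0

#: Reference levels for categorical cohort predictors.  The normal-range
#: harmony category is the reference so contrasts are the H and L (or
#: SF and LF) deviations; Angle class I, Le Fort 1 surgery and male sex
#: are the references for the demographic terms.
REFERENCE_LEVELS: dict[str, str] = {
    "angle_class": "I",
    "surgery": "LeFort1",
    "sex": "male",
    "pre_vertical": "NF",
    "pre_oli": "N",
    "pre_uli": "N",
    "pre_mi": "N",
}

_LEVEL_ORDER: dict[str, list[str]] = {
    "angle_class": ["I", "II", "III"],
    "surgery": ["LeFort1", "BSSO", "Bimax"],
    "sex": ["male", "female"],
    "pre_vertical": ["NF", "SF", "LF"],
    "pre_oli": ["N", "H", "L"],
    "pre_uli": ["N", "H", "L"],
    "pre_mi": ["N", "H", "L"],
}


@dataclass
class LogisticModel:
    """A fitted logistic regression with Wald inference.

    ``summary_frame`` lays the fit out with the usual report columns:
    Estimate, Odds Ratio, CI (lower), CI (upper), Std. Error, z value,
    Pr(>|z|).
    """

    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    deviance: float
    df_resid: int
    n_iter: int
    converged: bool
    separated: bool
    deviance_path: list[float] = field(default_factory=list)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - q * self.bse, self.params + q * self.bse])

    @property
    def aic(self) -> float:
        return self.deviance + 2 * len(self.params)

    def summary_frame(self) -> pd.DataFrame:
        with np.errstate(over="ignore"):  # separated fits have infinite CIs
            ci = np.exp(self.conf_int())
        return pd.DataFrame(
            {
                "Estimate": self.params,
                "Odds Ratio": self.odds_ratios,
                "CI (lower)": ci[:, 0],
                "CI (upper)": ci[:, 1],
                "Std. Error": self.bse,
                "z value": self.zvalues,
                "Pr(>|z|)": self.pvalues,
            },
            index=self.terms,
        )


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    terms: list[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> LogisticModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Parameters
    ----------
    X:
        Design matrix including the intercept column.
    y:
        Binary outcome in {0, 1}.
    terms:
        Column names for reporting; defaults to x0..xk.

    Non-convergence and quasi-separation are reported through the
    ``converged`` and ``separated`` flags, never as exceptions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise InvalidMeasurementError("design matrix and outcome length mismatch")
    if not np.all((y == 0) | (y == 1)):
        raise InvalidMeasurementError("outcome must be binary 0/1")
    n, k = X.shape
    if n <= k:
        raise InvalidMeasurementError(f"need n > parameters, got n={n}, k={k}")
    if terms is None:
        terms = [f"x{i}" for i in range(k)]

    beta = np.zeros(k)
    mu = np.full(n, 0.5)
    dev = _deviance(y, mu)
    path = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        # Fisher scoring step expressed as weighted least squares
        eta = X @ beta
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        try:
            step_beta = np.linalg.solve(X.T @ Xw, X.T @ (w * z))
        except np.linalg.LinAlgError:
            step_beta = np.linalg.lstsq(X.T @ Xw, X.T @ (w * z), rcond=None)[0]
        # step-halving keeps the deviance path non-increasing
        direction = step_beta - beta
        frac = 1.0
        for _ in range(30):
            cand = beta + frac * direction
            mu_c = expit(X @ cand)
            dev_c = _deviance(y, mu_c)
            if dev_c <= dev + 1e-12:
                break
            frac *= 0.5
        beta, mu = cand, expit(X @ cand)
        new_dev = _deviance(y, mu)
        path.append(new_dev)
        if abs(dev - new_dev) < tol * (abs(dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev

    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        bse = np.full(k, np.inf)
    separated = bool(np.any(bse > SEPARATION_SE) or not np.all(np.isfinite(bse)))
    return LogisticModel(
        terms=list(terms),
        params=beta,
        bse=bse,
        deviance=dev,
        df_resid=n - k,
        n_iter=it,
        converged=converged,
        separated=separated,
        deviance_path=path,
    )


# ---- categorical design construction --------------------------------------


def build_design(
    df: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept and treatment contrasts.

    Categorical columns listed in :data:`REFERENCE_LEVELS` are dummy-coded
    against their documented reference level; numeric columns enter as-is.
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["(Intercept)"]
    for t in terms:
        if t not in df.columns:
            raise InvalidMeasurementError(f"unknown model term {t!r}")
        if t in _LEVEL_ORDER:
            levels = [l for l in _LEVEL_ORDER[t] if l in set(df[t])]
            ref = REFERENCE_LEVELS[t]
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((df[t] == lev).to_numpy(dtype=float))
                names.append(f"{t}:{lev}")
        else:
            cols.append(pd.to_numeric(df[t]).to_numpy(dtype=float))
            names.append(t)
    return np.column_stack(cols), names


def fit_cohort_model(
    df: pd.DataFrame, outcome: str, terms: list[str]
) -> LogisticModel:
    """Fit success ~ terms on a cohort frame with a binary outcome column."""
    X, names = build_design(df, terms)
    y = df[outcome].to_numpy(dtype=float)
    return logistic_irls(X, y, terms=names)


def stepwise_aic(
    df: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    max_steps: int = 50,
) -> tuple[LogisticModel, list[str]]:
    """Forward-backward stepwise search minimising AIC.

    Starts from the intercept-only model; at each step the single
    add-or-drop move with the lowest AIC is taken if it improves on the
    current model.  Ties are broken by candidate order, so the search is
    deterministic given the input ordering.  Returns the selected model
    and the selected term list.
    """
    selected: list[str] = []
    current = fit_cohort_model(df, outcome, selected)
    for _ in range(max_steps):
        best_aic = current.aic
        best_move: tuple[str, str] | None = None
        moves = [("add", c) for c in candidates if c not in selected] + [
            ("drop", c) for c in selected
        ]
        best_model = current
        for action, term in moves:
            trial = (
                selected + [term] if action == "add" else [t for t in selected if t != term]
            )
            m = fit_cohort_model(df, outcome, trial)
            if m.aic < best_aic - 1e-10:
                best_aic = m.aic
                best_move = (action, term)
                best_model = m
        if best_move is None:
            break
        action, term = best_move
        if action == "add":
            selected.append(term)
        else:
            selected.remove(term)
        current = best_model
    return current, selected
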