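"""Candidate regression families, repeated k-fold selection, and the
trait/condition regressions on the cooperation DVs.

Three families are compared on each proportion-type dependent variable:

- ``gaussian_identity`` — an ordinary linear model on the proportion scale
  (the family the cross-validation ends up selecting on these data);
- ``binomial_logit`` — a logistic regression on (successes, trials);
- ``beta_binomial`` — a beta-binomial fit by direct likelihood maximization,
  with a logit-linear mean and a common overdispersion parameter.

Selection is by repeated k-fold cross-validation over participants, scoring
mean squared error of the predicted mean response on the proportion scale —
the only loss comparable across the three families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.model_selection import RepeatedKFold
import statsmodels.api as sm

from .engine import Condition
from .errors import ConfigurationError, InputError
from .metrics import significance_stars

FAMILIES = ("gaussian_identity", "binomial_logit", "beta_binomial")

#: Fixed covariate set of the full cooperation regressions.
FULL_TERMS = (
    "gender",
    "maximise",
    "fearless_dominance",
    "self_centred_impulsivity",
    "coldheartedness",
    "narcissism",
    "positive_feedback",
    "negative_feedback",
    "positive_feedback:negative_feedback",
    "game_version",
)

#: Trait-only covariate set (the partialling check run first).
TRAIT_TERMS = (
    "fearless_dominance",
    "self_centred_impulsivity",
    "coldheartedness",
    "narcissism",
)


def factorial_encoding(condition: Condition | int) -> tuple[int, int]:
    """(positive_feedback, negative_feedback) flags for a condition id."""
    cond = condition if isinstance(condition, Condition) else Condition.from_id(condition)
    return cond.positive_feedback, cond.negative_feedback


@dataclass(frozen=True)
class ModelSpec:
    family: str
    response: str  # column holding the proportion-scale DV
    terms: tuple[str, ...] = ()
    trials_column: str = "rounds_for_dv"  # denominator for count families

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"family must be one of {FAMILIES}, got {self.family!r}")


@dataclass
class FitResult:
    family: str
    response: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    n: int
    converged: bool
    model: object = field(default=None, repr=False)
    extra: dict = field(default_factory=dict)

    def predict_mean(self, X: pd.DataFrame) -> np.ndarray:
        """Mean response on the proportion scale."""
        eta = X.to_numpy(dtype=float) @ self.params.to_numpy()
        if self.family == "gaussian_identity":
            return eta
        return special.expit(eta)


def _design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Intercept + main-effect and ``a:b[:c]`` product columns."""
    X = pd.DataFrame({"intercept": np.ones(len(data))}, index=data.index)
    for term in terms:
        parts = term.split(":")
        for p in parts:
            if p not in data.columns:
                raise InputError(f"term {term!r} references missing column {p!r}")
        col = data[parts[0]].astype(float)
        for p in parts[1:]:
            col = col * data[p].astype(float)
        X[term] = col
    return X


def _check_complete(data: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if data[c].isna().any()]
    if missing:
        raise InputError(f"missing values in analysis columns {missing}; complete cases required")


def _beta_binomial_loglik(params, X, successes, trials):
    k = X.shape[1]
    eta = X @ params[:k]
    mu = np.clip(special.expit(eta), 1e-12, 1 - 1e-12)
    theta = np.exp(np.clip(params[k], -30.0, 30.0))  # precision; dispersion vanishes as theta -> inf
    a = mu * theta
    b = (1 - mu) * theta
    ll = (
        special.betaln(successes + a, trials - successes + b)
        - special.betaln(a, b)
        + special.gammaln(trials + 1)
        - special.gammaln(successes + 1)
        - special.gammaln(trials - successes + 1)
    )
    return ll.sum()


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Maximum-likelihood fit of the declared family.

    The response column is on the proportion scale; count families multiply it
    by ``trials_column`` (or ``rounds - 1`` style denominators prepared by the
    caller) to recover successes.
    """
    X = _design_matrix(data, spec.terms)
    needed = [spec.response] + [p for t in spec.terms for p in t.split(":")]
    _check_complete(data, needed)
    y = data[spec.response].to_numpy(dtype=float)
    n = len(data)
    if n <= X.shape[1]:
        raise InputError(f"n={n} too small for {X.shape[1]} parameters")

    if spec.family == "gaussian_identity":
        res = sm.OLS(y, X).fit()
        return FitResult(
            spec.family, spec.response, res.params, res.bse, res.pvalues,
            float(res.llf), n, True, model=res,
        )

    trials = data[spec.trials_column].to_numpy(dtype=float)
    successes = np.rint(y * trials)
    if spec.family == "binomial_logit":
        endog = np.column_stack([successes, trials - successes])
        model = sm.GLM(endog, X, family=sm.families.Binomial())
        try:
            res = model.fit()
            converged = bool(res.converged)
        except Exception:  # perfect separation or the like — flag, don't hide
            res = model.fit(method="lbfgs", maxiter=500)
            converged = False
        return FitResult(
            spec.family, spec.response, res.params, res.bse, res.pvalues,
            float(res.llf), n, converged, model=res,
        )

    # beta-binomial by direct likelihood maximization
    k = X.shape[1]
    Xa = X.to_numpy(dtype=float)
    start_glm = sm.GLM(
        np.column_stack([successes, trials - successes]), X, family=sm.families.Binomial()
    ).fit()
    x0 = np.concatenate([start_glm.params.to_numpy(), [np.log(50.0)]])
    nll = lambda p: -_beta_binomial_loglik(p, Xa, successes, trials)
    sol = optimize.minimize(nll, x0, method="L-BFGS-B")
    # polish with Nelder-Mead if the gradient method stalled
    if not sol.success:
        sol = optimize.minimize(nll, sol.x, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    from statsmodels.tools.numdiff import approx_hess1

    hess = approx_hess1(sol.x, nll)
    try:
        cov = np.linalg.inv(hess)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_all = np.full(k + 1, np.nan)
    names = list(X.columns)
    params = pd.Series(sol.x[:k], index=names)
    bse = pd.Series(se_all[:k], index=names)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse
    pvals = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
    return FitResult(
        spec.family, spec.response, params, bse, pvals, float(-sol.fun), n,
        bool(sol.success), extra={"log_theta": sol.x[k], "log_theta_se": se_all[k]},
    )


@dataclass
class CVResult:
    mean_error: dict
    fold_errors: dict
    chosen_family: str
    chosen_spec: ModelSpec
    k: int
    repeats: int
    seed: int


def cv_select(
    specs: Sequence[ModelSpec],
    data: pd.DataFrame,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation over participants.

    Held-out loss is the MSE of the predicted mean response on the proportion
    scale.  The family with the lowest mean loss wins; exact ties go to the
    earlier spec in ``specs``.  Fold assignment depends only on ``seed`` and
    the number of rows, so row order does not affect the selection.
    """
    if k < 2:
        raise InputError("k must be >= 2")
    if len(data) < k:
        raise InputError(f"need at least k={k} participants, got {len(data)}")
    data = data.sort_values("participant_id").reset_index(drop=True) \
        if "participant_id" in data.columns else data.reset_index(drop=True)
    rkf = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    fold_errors: dict[str, list[float]] = {s.family: [] for s in specs}
    for train_idx, test_idx in rkf.split(data):
        train, test = data.iloc[train_idx], data.iloc[test_idx]
        for spec in specs:
            fit = fit_model(spec, train)
            Xte = _design_matrix(test, spec.terms)
            pred = fit.predict_mean(Xte)
            err = float(np.mean((test[spec.response].to_numpy(dtype=float) - pred) ** 2))
            fold_errors[spec.family].append(err)
    mean_error = {fam: float(np.mean(v)) for fam, v in fold_errors.items()}
    best = min(range(len(specs)), key=lambda i: mean_error[specs[i].family])
    return CVResult(
        mean_error, {f: list(v) for f, v in fold_errors.items()},
        specs[best].family, specs[best], k, repeats, seed,
    )


#: The four separately-regressed interaction blocks of the psychopathy x
#: condition analysis, each controlling for gender, game version, maximise,
#: narcissism and the two condition flags.
INTERACTION_TERMS = (
    "game_version:sum_psychopathic_traits",
    "positive_feedback:negative_feedback:sum_psychopathic_traits",
    "positive_feedback:sum_psychopathic_traits",
    "negative_feedback:sum_psychopathic_traits",
)
INTERACTION_CONTROLS = (
    "gender",
    "game_version",
    "maximise",
    "narcissism",
    "positive_feedback",
    "negative_feedback",
    "sum_psychopathic_traits",
)


def interaction_regressions(
    data: pd.DataFrame,
    responses: Sequence[str] = ("cooperation", "cac_proportion"),
    family: str = "gaussian_identity",
    controls: Sequence[str] = INTERACTION_CONTROLS,
) -> pd.DataFrame:
    """One fit per (DV, interaction term); rows report the interaction only."""
    if data["sum_psychopathic_traits"].std(ddof=0) == 0:
        raise InputError("sum_psychopathic_traits is constant; interactions are collinear")
    rows = []
    for response in responses:
        for term in INTERACTION_TERMS:
            spec = ModelSpec(family, response, tuple(controls) + (term,))
            fit = fit_model(spec, data)
            rows.append(
                {
                    "response": response,
                    "term": term,
                    "estimate": fit.params[term],
                    "se": fit.bse[term],
                    "p": fit.pvalues[term],
                    "stars": significance_stars(fit.pvalues[term]),
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def render_coefficient_table(fits: dict[str, FitResult], digits: int = 2) -> str:
    """Text table: one column per fitted DV, 'estimate stars' over '(SE)'."""
    all_terms: list[str] = []
    for fit in fits.values():
        for t in fit.params.index:
            if t not in all_terms:
                all_terms.append(t)
    lines = ["term\t" + "\t".join(fits)]
    for t in all_terms:
        est_cells, se_cells = [], []
        for fit in fits.values():
            if t in fit.params.index:
                est_cells.append(f"{fit.params[t]:.{digits}f}{significance_stars(fit.pvalues[t])}")
                se_cells.append(f"({fit.bse[t]:.{digits}f})")
            else:
                est_cells.append("")
                se_cells.append("")
        lines.append(t + "\t" + "\t".join(est_cells))
        lines.append("\t" + "\t".join(se_cells))
    return "\n".join(lines)
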