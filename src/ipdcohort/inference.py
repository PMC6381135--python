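"""Per-subject strategy inference with a tremble likelihood, cohort
aggregation with bootstrap uncertainty, and the population-level mixture
estimator (SFEM) as a cross-check.

Model.  A subject following strategy ``s`` executes its prescription each
round with probability ``beta`` and the opposite action with ``1 - beta``
(an implementation tremble, i.i.d. across rounds).  Prescriptions condition
on the *realized* joint history, so the likelihood of an observed choice
sequence under ``s`` is ``beta^m * (1-beta)^(T-m)`` with ``m`` the number of
rounds where the choice matches the prescription.  The error scale is
reported as ``gamma`` with ``beta = 1 / (1 + exp(-1/gamma))``: gamma near 0
means near-perfect compliance, gamma < 1 is conventionally read as a good
approximation of the subject by the strategy set.

Per-subject estimator.  A literal per-subject mixture MLE over strategy
weights is degenerate (the optimum always sits on a simplex vertex), so the
subject-level weights reported here are the normalized strategy likelihoods
at the subject's fitted gamma — the posterior over the strategy set under a
uniform prior.  gamma is fitted by bounded scalar maximization of the
uniform-mixture log-likelihood.  The vertex (argmax) estimator is also
available; cohort tables state which was averaged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .actions import JointHistory
from .automata import StrategyAutomaton, build_strategy_set
from .errors import ConfigurationError, InputError
from .metrics import significance_stars

GAMMA_BOUNDS = (0.01, 5.0)
GAMMA_XATOL = 1e-6


def beta_from_gamma(gamma) -> float | np.ndarray:
    """Compliance probability beta = 1 / (1 + exp(-1/gamma))."""
    gamma = np.asarray(gamma, dtype=float)
    out = special.expit(1.0 / gamma)
    return float(out) if out.ndim == 0 else out


def gamma_from_beta(beta) -> float | np.ndarray:
    """Inverse map; beta must be in (0.5, 1)."""
    beta = np.asarray(beta, dtype=float)
    out = 1.0 / special.logit(beta)
    return float(out) if out.ndim == 0 else out


def _log_beta_terms(gamma: float) -> tuple[float, float]:
    """(log beta, log(1-beta)) computed stably straight from gamma."""
    t = 1.0 / gamma
    log_beta = -np.log1p(np.exp(-t))
    return log_beta, log_beta - t


def sequence_likelihood(
    choices: Sequence[str], prescriptions: Sequence[str], beta: float
) -> float:
    """Tremble likelihood of a choice sequence given a prescription sequence."""
    if len(choices) != len(prescriptions):
        raise InputError(
            f"choices ({len(choices)}) and prescriptions ({len(prescriptions)}) differ in length"
        )
    if not (0.0 < beta <= 1.0):
        raise InputError(f"beta must be in (0, 1], got {beta}")
    m = sum(1 for c, p in zip(choices, prescriptions) if c == p)
    return beta**m * (1.0 - beta) ** (len(choices) - m)


def match_counts(
    history: JointHistory, strategies: Sequence[StrategyAutomaton]
) -> np.ndarray:
    """Rounds where the realized choice equals each strategy's prescription."""
    own = history.own
    return np.array(
        [
            sum(1 for c, p in zip(own, s.prescribed_sequence(history)) if c == p)
            for s in strategies
        ],
        dtype=float,
    )


@dataclass
class SubjectFit:
    participant_id: object
    strategy_names: tuple[str, ...]
    weights: np.ndarray
    gamma_hat: float
    loglik: float
    match_counts: np.ndarray
    n_rounds: int
    degenerate: bool = False

    @property
    def best_strategy(self) -> str:
        return self.strategy_names[int(np.argmax(self.weights))]

    @property
    def beta_hat(self) -> float:
        return beta_from_gamma(self.gamma_hat)

    def vertex_weights(self) -> np.ndarray:
        """Argmax estimator: all mass on the best-fitting strategies (ties split)."""
        best = self.weights >= self.weights.max() - 1e-12
        return best / best.sum()


def _mixture_loglik(gamma: float, m: np.ndarray, T: int) -> float:
    """log mean_s beta^m_s (1-beta)^(T-m_s) at the given gamma."""
    lb, l1b = _log_beta_terms(gamma)
    ll = m * lb + (T - m) * l1b
    mx = ll.max()
    return float(mx + np.log(np.exp(ll - mx).sum()) - np.log(len(m)))


def _mixture_loglik_grid(gammas: np.ndarray, m: np.ndarray, T: int) -> np.ndarray:
    """Vectorized mixture log-likelihood over an array of gammas."""
    inv = 1.0 / gammas
    lb = -np.log1p(np.exp(-inv))
    l1b = lb - inv
    ll = np.outer(lb, m) + np.outer(l1b, T - m)  # (G, S)
    mx = ll.max(axis=1, keepdims=True)
    return (mx[:, 0] + np.log(np.exp(ll - mx).sum(axis=1)) - np.log(len(m)))


#: Log-likelihood ties closer than this are broken toward the smaller gamma.
GAMMA_TIE_TOL = 1e-9


def _maximize_gamma(
    m: np.ndarray, T: int, gamma_bounds: tuple[float, float]
) -> tuple[float, float]:
    """Maximize the uniform-mixture log-likelihood over gamma.

    Bounded scalar search, guarded by a coarse scan (the mixture can be
    bimodal in gamma for short sessions) and by explicit boundary checks.
    Short sessions can also leave gamma unidentified (an exactly flat
    likelihood); ties within ``GAMMA_TIE_TOL`` are broken toward the smallest
    gamma — the least-tremble explanation of the data.
    """
    obj = lambda g: -_mixture_loglik(g, m, T)
    res = optimize.minimize_scalar(
        obj, bounds=gamma_bounds, method="bounded", options={"xatol": GAMMA_XATOL}
    )
    scan = np.geomspace(gamma_bounds[0], gamma_bounds[1], 64)
    candidates = list(scan) + [float(res.x)]
    lls = np.append(_mixture_loglik_grid(scan, m, T), -res.fun)
    # if a scan point beats the first search, re-optimize in its neighbourhood
    best_scan = int(np.argmax(lls))
    if lls[best_scan] > -res.fun + GAMMA_TIE_TOL and candidates[best_scan] != res.x:
        i = best_scan
        lo = candidates[i - 1] if i > 0 else gamma_bounds[0]
        hi = candidates[i + 1] if i + 1 < len(candidates) else gamma_bounds[1]
        res2 = optimize.minimize_scalar(
            obj, bounds=(lo, hi), method="bounded", options={"xatol": GAMMA_XATOL}
        )
        candidates.append(float(res2.x))
        lls = np.append(lls, -res2.fun)
    sup = float(lls.max())
    tied = [g for g, l in zip(candidates, lls) if l >= sup - GAMMA_TIE_TOL]
    gamma_hat = float(min(tied))
    return gamma_hat, _mixture_loglik(gamma_hat, m, T)


def _posterior_weights(gamma: float, m: np.ndarray, T: int) -> np.ndarray:
    lb, l1b = _log_beta_terms(gamma)
    ll = m * lb + (T - m) * l1b
    w = np.exp(ll - ll.max())
    return w / w.sum()


def fit_subject(
    history: JointHistory | Sequence,
    strategies: Sequence[StrategyAutomaton] | Sequence[str],
    participant_id: object = None,
    gamma_bounds: tuple[float, float] = GAMMA_BOUNDS,
) -> SubjectFit:
    """Fit the tremble model to one subject's session.

    ``history`` may be a :class:`JointHistory` or a list of round records with
    ``participant_action`` / ``computer_action`` attributes.  gamma is fitted
    by bounded scalar search of the uniform-mixture log-likelihood on
    ``gamma_bounds``; weights are the posterior over strategies at the
    optimum.
    """
    if not isinstance(history, JointHistory):
        history = JointHistory(
            tuple(r.participant_action for r in history),
            tuple(r.computer_action for r in history),
            rounds_total=max(len(history), 1),
        )
    if len(history) < 1:
        raise InputError("session must contain at least one round")
    if len(strategies) == 0:
        raise InputError("strategy set must be non-empty")
    if strategies and isinstance(strategies[0], str):
        strategies = build_strategy_set(list(strategies))
    T = len(history)
    m = match_counts(history, strategies)
    gamma_hat, ll = _maximize_gamma(m, T, gamma_bounds)
    weights = _posterior_weights(gamma_hat, m, T)
    degenerate = not np.isfinite(ll)
    if degenerate:
        weights = np.full(len(strategies), 1.0 / len(strategies))
    return SubjectFit(
        participant_id,
        tuple(s.abbreviation for s in strategies),
        weights,
        gamma_hat,
        ll,
        m,
        T,
        degenerate,
    )


def fit_cohort(
    rounds_df: pd.DataFrame, strategies: Sequence[StrategyAutomaton] | Sequence[str]
) -> list[SubjectFit]:
    """fit_subject for every participant in a tidy round table."""
    if strategies and isinstance(strategies[0], str):
        strategies = build_strategy_set(list(strategies))
    fits = []
    for pid, grp in rounds_df.sort_values("round").groupby("participant_id", sort=True):
        hist = JointHistory(
            tuple(grp["participant_action"]), tuple(grp["computer_action"]), len(grp)
        )
        fits.append(fit_subject(hist, strategies, participant_id=pid))
    return fits


@dataclass
class CohortStrategyEstimate:
    strategy_names: tuple[str, ...]
    frequencies: np.ndarray
    mean_gamma: float
    n: int
    estimator: str = "posterior_mean"
    se: np.ndarray | None = None
    gamma_se: float | None = None
    pvalues: np.ndarray | None = None
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    B: int | None = None
    seed: int | None = None

    def as_dict(self) -> dict:
        out = {
            "estimator": self.estimator,
            "n": self.n,
            "gamma": self.mean_gamma,
            "frequencies": dict(zip(self.strategy_names, map(float, self.frequencies))),
        }
        if self.se is not None:
            out["se"] = dict(zip(self.strategy_names, map(float, self.se)))
            out["gamma_se"] = self.gamma_se
            out["pvalues"] = dict(zip(self.strategy_names, map(float, self.pvalues)))
            out["B"] = self.B
            out["seed"] = self.seed
        return out


def _weights_matrix(fits: Sequence[SubjectFit], estimator: str) -> np.ndarray:
    if estimator == "posterior_mean":
        return np.vstack([f.weights for f in fits])
    if estimator == "vertex":
        return np.vstack([f.vertex_weights() for f in fits])
    raise ConfigurationError(f"unknown estimator {estimator!r}")


def cohort_estimates(
    fits: Sequence[SubjectFit], estimator: str = "posterior_mean"
) -> CohortStrategyEstimate:
    """Cohort strategy frequencies: the average of per-subject weights."""
    if len(fits) == 0:
        raise InputError("need at least one subject fit")
    W = _weights_matrix(fits, estimator)
    gammas = np.array([f.gamma_hat for f in fits])
    return CohortStrategyEstimate(
        fits[0].strategy_names, W.mean(axis=0), float(gammas.mean()), len(fits), estimator
    )


def bootstrap_se(
    fits: Sequence[SubjectFit],
    B: int = 1000,
    seed: int = 0,
    estimator: str = "posterior_mean",
) -> CohortStrategyEstimate:
    """Bootstrap over participants: SEs, normal-approximation p-values vs 0,
    and percentile intervals for the cohort frequencies and mean gamma.

    p-values are one-sided upper (H0: frequency = 0 against frequency > 0);
    a zero SE yields p = 0 for a positive estimate and p = 1 at zero.
    """
    if B < 100:
        raise InputError("B must be >= 100 for stable standard errors")
    est = cohort_estimates(fits, estimator)
    W = _weights_matrix(fits, estimator)
    gammas = np.array([f.gamma_hat for f in fits])
    n = len(fits)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    boot_freq = W[idx].mean(axis=1)  # (B, S)
    boot_gamma = gammas[idx].mean(axis=1)
    se = boot_freq.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, est.frequencies / se, np.inf)
    p = stats.norm.sf(z)
    p = np.where(est.frequencies <= 0, 1.0, p)
    lo, hi = np.percentile(boot_freq, [2.5, 97.5], axis=0)
    return CohortStrategyEstimate(
        est.strategy_names,
        est.frequencies,
        est.mean_gamma,
        n,
        estimator,
        se=se,
        gamma_se=float(boot_gamma.std(ddof=1)),
        pvalues=p,
        ci_lower=lo,
        ci_upper=hi,
        B=B,
        seed=seed,
    )


def trait_strategy_correlations(
    fits: Sequence[SubjectFit],
    traits: pd.DataFrame,
    trait_columns: Sequence[str] = (
        "fearless_dominance",
        "self_centred_impulsivity",
        "coldheartedness",
    ),
    estimator: str = "posterior_mean",
) -> pd.DataFrame:
    """Pearson r between per-subject strategy weights and trait scores.

    ``traits`` must carry ``participant_id`` matching the fits.  Constant
    weight columns are flagged NaN (correlation undefined).
    """
    W = _weights_matrix(fits, estimator)
    ids = [f.participant_id for f in fits]
    tr = traits.set_index("participant_id").loc[ids]
    rows = []
    for trait in trait_columns:
        x = tr[trait].to_numpy(dtype=float)
        for j, sname in enumerate(fits[0].strategy_names):
            w = W[:, j]
            if np.std(w) == 0 or np.std(x) == 0:
                r, p = np.nan, np.nan
            else:
                res = stats.pearsonr(x, w)
                r, p = res.statistic, res.pvalue
            rows.append(
                {
                    "trait": trait,
                    "strategy": sname,
                    "r": r,
                    "p": p,
                    "stars": "" if np.isnan(p) else significance_stars(p),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population-level mixture estimator (SFEM)


@dataclass
class PopulationEstimate:
    strategy_names: tuple[str, ...]
    phi: np.ndarray
    gamma: float
    loglik: float
    converged: bool
    n_starts: int
    iterations: int


def sfem_population(
    rounds_or_fits,
    strategies: Sequence[StrategyAutomaton] | Sequence[str] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> PopulationEstimate:
    """Population mixture MLE: max over (phi on the simplex, common gamma) of
    ``sum_i log sum_s phi_s beta^m_is (1-beta)^(T_i - m_is)``.

    EM with seeded multi-start: the E-step computes subject-level posteriors,
    the M-step updates phi to the posterior means and beta to the
    posterior-weighted match rate (clipped into the gamma bracket).  Accepts
    either a tidy round table plus a strategy set, or a list of
    :class:`SubjectFit` (whose match counts are sufficient statistics).
    """
    if isinstance(rounds_or_fits, pd.DataFrame):
        if strategies is None:
            raise InputError("a strategy set is required with a round table")
        fits = fit_cohort(rounds_or_fits, strategies)
    else:
        fits = list(rounds_or_fits)
    if len(fits) < 2:
        if len(fits) == 1 and len(fits[0].strategy_names) == 1:
            return PopulationEstimate(
                fits[0].strategy_names, np.array([1.0]), fits[0].gamma_hat,
                fits[0].loglik, True, 0, 0,
            )
        raise InputError("population estimation needs at least 2 participants")
    names = fits[0].strategy_names
    M = np.vstack([f.match_counts for f in fits])  # (n, S)
    T = np.array([f.n_rounds for f in fits], dtype=float)[:, None]
    n, S = M.shape
    if S == 1:
        beta_hat = float(M.sum() / T.sum())
        gamma = _clip_gamma_for_beta(beta_hat)
        ll = _population_loglik(np.array([1.0]), gamma, M, T)
        return PopulationEstimate(names, np.array([1.0]), gamma, ll, True, 0, 0)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(n_starts):
        phi = rng.dirichlet(np.ones(S)) if start else np.full(S, 1.0 / S)
        gamma = float(rng.uniform(0.2, 2.0)) if start else 0.5
        prev_ll = -np.inf
        iters = 0
        converged = False
        for iters in range(1, max_iter + 1):
            lb, l1b = _log_beta_terms(gamma)
            log_lik = M * lb + (T - M) * l1b  # (n, S)
            with np.errstate(divide="ignore"):
                log_post = log_lik + np.log(phi)
            norm = special.logsumexp(log_post, axis=1, keepdims=True)
            ll = float(norm.sum())
            post = np.exp(log_post - norm)
            phi = post.mean(axis=0)
            beta_hat = float((post * M).sum() / (post * T).sum())
            gamma = _clip_gamma_for_beta(beta_hat)
            if abs(ll - prev_ll) < tol:
                converged = True
                break
            prev_ll = ll
        cand = PopulationEstimate(names, phi, gamma, ll, converged, n_starts, iters)
        if best is None or cand.loglik > best.loglik:
            best = cand
    return best


def _clip_gamma_for_beta(beta_hat: float) -> float:
    lo_beta = beta_from_gamma(GAMMA_BOUNDS[1])  # largest error allowed
    hi_beta = beta_from_gamma(GAMMA_BOUNDS[0])  # near-perfect compliance
    return gamma_from_beta(float(np.clip(beta_hat, lo_beta, min(hi_beta, 1 - 1e-12))))


def _population_loglik(phi: np.ndarray, gamma: float, M: np.ndarray, T: np.ndarray) -> float:
    lb, l1b = _log_beta_terms(gamma)
    log_lik = M * lb + (T - M) * l1b
    with np.errstate(divide="ignore"):
        return float(special.logsumexp(log_lik + np.log(phi), axis=1).sum())


def render_strategy_table(est: CohortStrategyEstimate, corr: pd.DataFrame | None = None) -> str:
    """Text table of cohort frequencies, (bootstrap SEs), stars, and the
    optional trait-correlation block."""
    lines = ["\tGamma\t" + "\t".join(est.strategy_names)]
    freq_cells = [f"{est.mean_gamma:.2f}"] + [f"{v:.2f}" for v in est.frequencies]
    if est.pvalues is not None:
        freq_cells = [freq_cells[0]] + [
            f"{v:.2f}{significance_stars(p)}" for v, p in zip(est.frequencies, est.pvalues)
        ]
    lines.append("frequency\t" + "\t".join(freq_cells))
    if est.se is not None:
        lines.append(
            "(SE)\t"
            + f"({est.gamma_se:.2f})\t"
            + "\t".join(f"({s:.2f})" for s in est.se)
        )
    lines.append(f"estimator: {est.estimator}, n={est.n}")
    if corr is not None:
        lines.append("")
        lines.append("trait\t" + "\t".join(est.strategy_names))
        for trait, grp in corr.groupby("trait", sort=False):
            by_s = grp.set_index("strategy")
            cells = [
                f"{by_s.loc[s, 'r']:.2f}{by_s.loc[s, 'stars']}" for s in est.strategy_names
            ]
            lines.append(trait + "\t" + "\t".join(cells))
    return "\n".join(lines)
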