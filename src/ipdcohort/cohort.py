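"""Synthetic cohort generator for the IPD-with-feedback study design.

Emulates the study conditions end to end: 192 participants, balanced over the
2x2 feedback design crossed with the deception / non-deception game versions,
trait profiles matching the published sample moments, and 30 rounds of play
generated by automaton strategies with i.i.d. tremble noise against the
tit-for-two-tats computer opponent (which defects in the last two rounds).

Trait marginals are truncated normals; the parent (mu, sigma) are solved
numerically so that the moments *after* truncation equal the requested
mean/SD (plain parametrization by the target moments would shrink the SD and
shift the mean, severely so for the narcissism scale which lives close to its
floor).  The ordinal ``maximise`` rating uses the maximum-entropy distribution
on {1..5} with the requested mean and SD.  An optional Gaussian-copula mode
imposes the published trait inter-correlations on the same marginals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .actions import D, flip
from .automata import CATALOGUE, StrategyAutomaton, get_strategy
from .engine import Condition, GameConfig, RoundRecord, feedback_label, payoff
from .errors import ConfigurationError
from .traits import TraitProfile

#: Published sample moments (mean, SD, min, max) per trait.
DEFAULT_TRAIT_MOMENTS: dict[str, tuple[float, float, float, float]] = {
    "fearless_dominance": (34.67, 7.51, 17.0, 56.0),
    "self_centred_impulsivity": (30.91, 5.89, 16.0, 49.0),
    "coldheartedness": (10.78, 2.97, 5.0, 20.0),
    "narcissism": (0.08, 0.09, 0.0, 0.33),
}

#: Marginal family per trait.  The three PPI factors are well inside what a
#: truncated normal can express; the narcissism proportion (mean 0.08, SD 0.09
#: on [0, 0.33]) is over-dispersed relative to *any* truncated normal on that
#: interval (the family is log-concave; its best fit caps the SD near 0.075),
#: so it gets a moment-matched scaled beta, which also reproduces the pile-up
#: at zero typical of NPI-16 short-form scores.
DEFAULT_MARGINAL_FAMILIES: dict[str, str] = {
    "fearless_dominance": "truncnorm",
    "self_centred_impulsivity": "truncnorm",
    "coldheartedness": "truncnorm",
    "narcissism": "scaled_beta",
}

MAXIMISE_MEAN, MAXIMISE_SD = 4.26, 0.90
FEMALE_FRACTION = 112 / 192  # 1 = female, 2 = male

#: Strategy mix observed in the cohort-level estimates (the study conditions
#: a recovery experiment should reproduce).
DEFAULT_STRATEGY_MIX: dict[str, float] = {
    "ALLD": 0.55,
    "2TF2T": 0.22,
    "TF3T": 0.15,
    "Grim": 0.07,
    "ALLC": 0.01,
}

#: Published trait inter-correlations, used by the optional copula mode.
#: Order: self_centred_impulsivity, fearless_dominance, coldheartedness,
#: narcissism, maximise.
TRAIT_CORRELATION_VARS = (
    "self_centred_impulsivity",
    "fearless_dominance",
    "coldheartedness",
    "narcissism",
    "maximise",
)
DEFAULT_TRAIT_CORRELATIONS = np.array(
    [
        [1.00, -0.07, 0.28, 0.25, -0.01],
        [-0.07, 1.00, 0.13, 0.40, 0.01],
        [0.28, 0.13, 1.00, 0.27, 0.18],
        [0.25, 0.40, 0.27, 1.00, -0.01],
        [-0.01, 0.01, 0.18, -0.01, 1.00],
    ]
)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a synthetic cohort reproducibly."""

    n_participants: int = 192
    trait_moments: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MOMENTS))
    marginal_families: dict = field(default_factory=lambda: dict(DEFAULT_MARGINAL_FAMILIES))
    strategy_mix: dict = field(default_factory=lambda: dict(DEFAULT_STRATEGY_MIX))
    tremble_beta: float = 0.9
    trait_strategy_link: dict | None = None  # {strategy: {trait: coef}}
    copula_correlations: bool = False
    female_fraction: float = FEMALE_FRACTION
    maximise_mean: float = MAXIMISE_MEAN
    maximise_sd: float = MAXIMISE_SD
    irs_mean: float = 6.0
    irs_sd: float = 3.0
    balanced_design: bool = True
    rounds_total: int = 30
    endgame_defect_rounds: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be positive")
        if not (0.5 < self.tremble_beta <= 1.0):
            raise ConfigurationError(
                f"tremble_beta must be in (0.5, 1], got {self.tremble_beta}"
            )
        w = np.array(list(self.strategy_mix.values()), dtype=float)
        if (w < 0).any():
            raise ConfigurationError("strategy mix weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"strategy mix weights must sum to 1, got {w.sum()!r}")
        for name in self.strategy_mix:
            if name not in CATALOGUE:
                raise ConfigurationError(f"unknown strategy {name!r} in mix")
        for trait, (mean, sd, lo, hi) in self.trait_moments.items():
            if sd < 0:
                raise ConfigurationError(f"{trait}: SD must be >= 0")
            if lo >= hi:
                raise ConfigurationError(f"{trait}: min {lo} must be < max {hi}")
            if not (lo <= mean <= hi):
                raise ConfigurationError(f"{trait}: mean {mean} outside [{lo}, {hi}]")

    def spec_hash(self) -> str:
        payload = json.dumps(
            {
                k: (sorted(v.items()) if isinstance(v, dict) else v)
                for k, v in self.__dict__.items()
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# marginal distributions


@lru_cache(maxsize=None)
def _truncnorm_parent_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a truncated normal whose truncated moments match.

    Solved by least squares on (truncated mean, truncated SD); falls back to
    the best attainable fit if the requested moments sit outside what the
    truncated-normal family can express on [lo, hi].
    """

    def truncated_moments(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return float(m), float(np.sqrt(v))

    def residual(params):
        m, s = truncated_moments(params)
        return [(m - mean) / max(sd, 1e-12), (s - sd) / max(sd, 1e-12)]

    sol = optimize.least_squares(
        residual, x0=[mean, np.log(sd)], xtol=1e-12, ftol=1e-12, max_nfev=2000
    )
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    return mu, sigma


def truncnorm_marginal(mean: float, sd: float, lo: float, hi: float) -> stats.rv_continuous:
    """Frozen truncated normal whose post-truncation mean/SD match the targets."""
    mu, sigma = _truncnorm_parent_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


def scaled_beta_marginal(mean: float, sd: float, lo: float, hi: float) -> stats.rv_continuous:
    """Beta distribution rescaled to [lo, hi] with exact mean/SD."""
    span = hi - lo
    m = (mean - lo) / span
    s = sd / span
    if s**2 >= m * (1 - m):
        raise ConfigurationError(
            f"SD {sd} infeasible for a beta marginal with mean {mean} on [{lo}, {hi}]"
        )
    nu = m * (1 - m) / s**2 - 1
    return stats.beta(m * nu, (1 - m) * nu, loc=lo, scale=span)


def trait_marginal(mean: float, sd: float, lo: float, hi: float, family: str = "truncnorm"):
    if family == "truncnorm":
        return truncnorm_marginal(mean, sd, lo, hi)
    if family == "scaled_beta":
        return scaled_beta_marginal(mean, sd, lo, hi)
    raise ConfigurationError(f"unknown marginal family {family!r}")


@lru_cache(maxsize=None)
def maxent_ordinal_probs(mean: float, sd: float, lo: int = 1, hi: int = 5) -> tuple[float, ...]:
    """Max-entropy pmf on {lo..hi} with the given mean and SD.

    Exponential-family form p_k proportional to exp(a*k + b*k^2); (a, b) are
    solved so the first two moments match.
    """
    ks = np.arange(lo, hi + 1, dtype=float)
    target = np.array([mean, sd**2 + mean**2])

    def moments(params):
        logits = params[0] * ks + params[1] * ks**2
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()
        return np.array([p @ ks, p @ ks**2])

    sol = optimize.least_squares(
        lambda th: moments(th) - target, x0=[0.0, 0.0], xtol=1e-14, ftol=1e-14
    )
    logits = sol.x[0] * ks + sol.x[1] * ks**2
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return tuple(p)


# ---------------------------------------------------------------------------
# generation stages


def generate_traits(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw participant trait profiles from the spec's marginal moments.

    Independent marginals by default; with ``copula_correlations`` the traits
    (and maximise) share a Gaussian copula with the published correlation
    matrix.  Gender is Bernoulli at the published female fraction.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    n = spec.n_participants
    cols: dict[str, np.ndarray] = {}

    trait_names = list(spec.trait_moments)
    marginals = {}
    for trait in trait_names:
        mean, sd, lo, hi = spec.trait_moments[trait]
        family = spec.marginal_families.get(trait, "truncnorm")
        marginals[trait] = None if sd == 0 else trait_marginal(mean, sd, lo, hi, family)

    max_probs = np.array(maxent_ordinal_probs(spec.maximise_mean, spec.maximise_sd))
    max_cdf = np.cumsum(max_probs)

    if spec.copula_correlations:
        corr = DEFAULT_TRAIT_CORRELATIONS
        # guard against indefiniteness if a user swaps in their own matrix
        w, v = np.linalg.eigh(corr)
        if w.min() <= 0:
            corr = v @ np.diag(np.clip(w, 1e-6, None)) @ v.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
        z = rng.multivariate_normal(np.zeros(len(TRAIT_CORRELATION_VARS)), corr, size=n,
                                    method="cholesky")
        u = stats.norm.cdf(z)
        for j, name in enumerate(TRAIT_CORRELATION_VARS):
            if name == "maximise":
                cols[name] = 1 + np.searchsorted(max_cdf, np.clip(u[:, j], 0, 1 - 1e-12))
            else:
                mean, sd, lo, hi = spec.trait_moments[name]
                if marginals[name] is None:
                    cols[name] = np.full(n, mean)
                else:
                    cols[name] = marginals[name].ppf(u[:, j])
    else:
        for trait in trait_names:
            mean, sd, lo, hi = spec.trait_moments[trait]
            if marginals[trait] is None:
                cols[trait] = np.full(n, mean)
            else:
                cols[trait] = marginals[trait].rvs(size=n, random_state=rng)
        cols["maximise"] = 1 + np.searchsorted(max_cdf, rng.random(n))

    cols["gender"] = np.where(rng.random(n) < spec.female_fraction, 1, 2)
    irs = np.rint(
        truncnorm_marginal(spec.irs_mean, spec.irs_sd, 0.0, 12.0).rvs(size=n, random_state=rng)
    ).astype(int)
    cols["irs10"] = np.clip(irs, 0, 12)

    df = pd.DataFrame(cols)
    df.insert(0, "participant_id", np.arange(1, n + 1))
    df["maximise"] = df["maximise"].astype(int)
    df["sum_psychopathic_traits"] = (
        df["fearless_dominance"] + df["self_centred_impulsivity"] + df["coldheartedness"]
    )
    return df


def assign_strategies(
    traits: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator | None = None
) -> list[str]:
    """Assign a generating strategy to each participant.

    Without a trait link: i.i.d. draws from ``strategy_mix``.  With a link,
    per-participant probabilities are a softmax tilt of the mix:
    ``logit_s = log(mix_s) + sum_k coef_{s,k} * z_k`` with ``z_k`` the
    standardized trait.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed + 1)
    names = list(spec.strategy_mix)
    base = np.array([spec.strategy_mix[s] for s in names], dtype=float)
    n = len(traits)
    if not spec.trait_strategy_link:
        idx = rng.choice(len(names), size=n, p=base)
        return [names[i] for i in idx]

    with np.errstate(divide="ignore"):
        log_base = np.log(base)
    logits = np.tile(log_base, (n, 1))
    for s, coefs in spec.trait_strategy_link.items():
        if s not in names:
            raise ConfigurationError(f"trait link references {s!r}, not in the mix")
        j = names.index(s)
        for trait, coef in coefs.items():
            x = traits[trait].to_numpy(dtype=float)
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            logits[:, j] = logits[:, j] + coef * z
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs[:, base == 0] = 0.0
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = np.cumsum(probs, axis=1)
    idx = (u[:, None] > cum).sum(axis=1)
    return [names[i] for i in idx]


def simulate_choices(
    strategy: StrategyAutomaton | str,
    beta: float,
    config: GameConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[RoundRecord]:
    """Play one trembled session of the strategy against the computer.

    Each round the participant executes the automaton's prescription with
    probability ``beta`` and the opposite action with ``1 - beta``; future
    prescriptions condition on the realized (trembled) joint history.
    """
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    if not (0.5 < beta <= 1.0):
        raise ConfigurationError(f"beta must be in (0.5, 1], got {beta}")
    cfg = config or GameConfig()
    rng = rng if rng is not None else np.random.default_rng()

    comp = get_strategy("TF2T")
    s_state = strategy.initial_state()
    c_state = comp.initial_state()
    records: list[RoundRecord] = []
    endgame_start = cfg.rounds_total - cfg.endgame_defect_rounds
    trembles = rng.random(cfg.rounds_total) >= beta
    for t in range(1, cfg.rounds_total + 1):
        presc = strategy.action(s_state)
        pa = flip(presc) if trembles[t - 1] else presc
        ca = D if t > endgame_start else comp.action(c_state)
        pp, cp = payoff(pa, ca, cfg.payoffs)
        records.append(RoundRecord(t, pa, ca, pp, cp, feedback_label(pa, cfg.condition)))
        s_state = strategy.transition(s_state, pa, ca)
        c_state = comp.transition(c_state, ca, pa)  # computer's opponent = participant
    return records


@dataclass(frozen=True)
class SyntheticParticipant:
    participant_id: int
    profile: TraitProfile
    irs10: int
    strategy_true: str
    condition: Condition
    game_version: int
    rounds: list[RoundRecord]


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SyntheticParticipant], pd.DataFrame, pd.DataFrame, dict]:
    """Generate the full synthetic dataset.

    Returns ``(participants, participants_df, rounds_df, manifest)`` where the
    two DataFrames use the same tidy CSV schemas real data are ingested in.
    Condition x game-version assignment is exactly balanced whenever
    ``n_participants`` is divisible by 8 (cells tiled, then shuffled).
    """
    rng = np.random.default_rng(spec.rng_seed)
    traits = generate_traits(spec, rng)
    strategies = assign_strategies(traits, spec, rng)

    cells = [(cond, gv) for cond in (1, 2, 3, 4) for gv in (1, 2)]
    n = spec.n_participants
    if spec.balanced_design:
        tiled = (cells * (n // len(cells) + 1))[:n]
        order = rng.permutation(n)
        assignment = [tiled[i] for i in order]
    else:
        assignment = [cells[i] for i in rng.integers(0, len(cells), size=n)]

    participants: list[SyntheticParticipant] = []
    round_rows = []
    for i in range(n):
        cond_id, gv = assignment[i]
        cond = Condition.from_id(cond_id)
        cfg = GameConfig(
            rounds_total=spec.rounds_total,
            endgame_defect_rounds=spec.endgame_defect_rounds,
            game_version=gv,
            condition=cond,
        )
        recs = simulate_choices(strategies[i], spec.tremble_beta, cfg, rng)
        row = traits.iloc[i]
        profile = TraitProfile(
            fearless_dominance=float(row["fearless_dominance"]),
            self_centred_impulsivity=float(row["self_centred_impulsivity"]),
            coldheartedness=float(row["coldheartedness"]),
            narcissism=float(row["narcissism"]),
            gender=int(row["gender"]),
            maximise=int(row["maximise"]),
        )
        pid = int(row["participant_id"])
        participants.append(
            SyntheticParticipant(pid, profile, int(row["irs10"]), strategies[i], cond, gv, recs)
        )
        for r in recs:
            round_rows.append(
                {
                    "participant_id": pid,
                    "round": r.round,
                    "condition": cond_id,
                    "game_version": gv,
                    "participant_action": r.participant_action,
                    "computer_action": r.computer_action,
                    "participant_payoff": r.participant_payoff,
                    "computer_payoff": r.computer_payoff,
                    "feedback": r.feedback,
                }
            )

    participants_df = traits.copy()
    participants_df["strategy_true"] = strategies
    participants_df["condition"] = [a[0] for a in assignment]
    participants_df["game_version"] = [a[1] for a in assignment]
    participants_df["positive_feedback"] = [Condition.from_id(a[0]).positive_feedback for a in assignment]
    participants_df["negative_feedback"] = [Condition.from_id(a[0]).negative_feedback for a in assignment]
    participants_df["retained"] = 1  # generator draws IRS-10 below the cutoff

    rounds_df = pd.DataFrame(round_rows)
    manifest = {
        "seed": spec.rng_seed,
        "spec_hash": spec.spec_hash(),
        "n_participants": n,
        "n_rounds": int(len(rounds_df)),
        "tremble_beta": spec.tremble_beta,
        "strategy_mix": dict(spec.strategy_mix),
    }
    return participants, participants_df, rounds_df, manifest
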