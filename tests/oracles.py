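"""Independent brute-force oracles used by the tests.

These deliberately re-code the verbal strategy rules and the tremble
likelihood with different program structure than the package (string scans
over the opponent sequence instead of state machines; a dense gamma grid
instead of scalar optimization), so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np


def oracle_prescribe(abbrev: str, own: tuple, opp: tuple) -> str:
    """Verbal-rule interpreter: next action after the given joint history."""
    opp = tuple(opp)
    if abbrev == "ALLC":
        return "C"
    if abbrev == "ALLD":
        return "D"
    if abbrev == "TFT":
        return opp[-1] if opp else "C"
    if abbrev == "DTFT":
        return opp[-1] if opp else "D"
    if abbrev == "2TFT":
        return "D" if "D" in opp[-2:] else "C"
    if abbrev in ("TF2T", "TF3T"):
        n = 2 if abbrev == "TF2T" else 3
        # punishing iff at least n defections since the opponent's last cooperation,
        # equivalently: the last n opponent moves are all D
        return "D" if len(opp) >= n and set(opp[-n:]) == {"D"} else "C"
    if abbrev in ("Grim", "Grim2", "Grim3"):
        n = {"Grim": 1, "Grim2": 2, "Grim3": 3}[abbrev]
        return "D" if "D" * n in "".join(opp) else "C"
    if abbrev == "2TF2T":
        mode, run_d, run_c = "content", 0, 0
        for a in opp:
            if mode == "content":
                run_d = run_d + 1 if a == "D" else 0
                if run_d >= 2:
                    mode, run_c = "punish", 0
            else:
                run_c = run_c + 1 if a == "C" else 0
                if run_c >= 2:
                    mode, run_d = "content", 0
        return "D" if mode == "punish" else "C"
    raise ValueError(f"oracle does not know {abbrev!r}")


def all_joint_histories(max_len: int, min_len: int = 0):
    """Every (own, opp) action-pair sequence of length min_len..max_len."""
    for L in range(min_len, max_len + 1):
        for own in itertools.product("CD", repeat=L):
            for opp in itertools.product("CD", repeat=L):
                yield own, opp


def grid_fit_oracle(match_counts, T: int, grid_step: float = 0.001):
    """Exhaustive gamma-grid maximization of the uniform-mixture likelihood.

    Returns (gamma, weights) at the grid optimum; weights are the normalized
    per-strategy likelihoods there.
    """
    m = np.asarray(match_counts, dtype=float)
    grid = np.arange(0.01, 5.0 + grid_step / 2, grid_step)
    inv = 1.0 / grid
    log_beta = -np.log1p(np.exp(-inv))
    log_1mb = log_beta - inv
    # (G, S) per-strategy log-likelihoods
    ll = np.outer(log_beta, m) + np.outer(log_1mb, T - m)
    mix = np.logaddexp.reduce(ll, axis=1) - np.log(len(m))
    # same tie-break convention as the estimator: smallest gamma within 1e-9
    g = int(np.argmax(mix >= mix.max() - 1e-9))
    w = np.exp(ll[g] - ll[g].max())
    return grid[g], w / w.sum()
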