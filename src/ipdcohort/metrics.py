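"""Behavioural dependent variables and the bivariate correlation matrix.

Two headline DVs per participant: the overall fraction of cooperative choices
over the 30 rounds, and the count of cooperations immediately following the
participant's *own* previous cooperation (CaC) — a measure of persistence of
cooperative behaviour.  The symmetric count after an own defection (CaD) is
also computed, as are opponent-conditioned variants for sensitivity analysis.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .actions import C, D
from .errors import InputError

#: Two-sided p-value thresholds and their table markers.
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def significance_stars(p: float) -> str:
    for threshold, marker in STAR_LEVELS:
        if p < threshold:
            return marker
    return ""


def overall_cooperation(choices: Sequence[str]) -> float:
    """Fraction of rounds in which the participant cooperated."""
    if len(choices) == 0:
        raise InputError("empty choice sequence")
    return sum(1 for a in choices if a == C) / len(choices)


def _transition_count(choices: Sequence[str], prev: str, curr: str) -> int:
    if len(choices) < 2:
        raise InputError("need at least two rounds to count transitions")
    return sum(
        1 for a, b in zip(choices[:-1], choices[1:]) if a == prev and b == curr
    )


def cac_count(choices: Sequence[str]) -> int:
    """Cooperations immediately following the participant's own cooperation."""
    return _transition_count(choices, C, C)


def cad_count(choices: Sequence[str]) -> int:
    """Cooperations immediately following the participant's own defection."""
    return _transition_count(choices, D, C)


def coop_after_opponent_coop(own: Sequence[str], opponent: Sequence[str]) -> int:
    """Sensitivity variant: own cooperations following an *opponent* cooperation."""
    if len(own) != len(opponent):
        raise InputError("own/opponent sequences differ in length")
    if len(own) < 2:
        raise InputError("need at least two rounds to count transitions")
    return sum(1 for prev, b in zip(opponent[:-1], own[1:]) if prev == C and b == C)


def summarize_participants(
    rounds_df: pd.DataFrame,
    participants_df: pd.DataFrame | None = None,
    cac_normalization: str = "total",
) -> pd.DataFrame:
    """Build the per-participant summary table from tidy round records.

    ``cac_normalization`` sets the proportion handed to regressions:
    ``"total"`` divides the CaC count by (rounds - 1); ``"conditional"``
    divides by the number of own previous cooperations (NaN if none).
    Trait columns from ``participants_df`` are merged in when provided.
    """
    if cac_normalization not in ("total", "conditional"):
        raise InputError("cac_normalization must be 'total' or 'conditional'")
    rows = []
    for pid, grp in rounds_df.sort_values("round").groupby("participant_id", sort=True):
        ch = list(grp["participant_action"])
        n = len(ch)
        cac = cac_count(ch)
        cad = cad_count(ch)
        prev_coop = sum(1 for a in ch[:-1] if a == C)
        if cac_normalization == "total":
            cac_prop = cac / (n - 1)
        else:
            cac_prop = cac / prev_coop if prev_coop else np.nan
        rows.append(
            {
                "participant_id": pid,
                "rounds": n,
                "cooperation": overall_cooperation(ch),
                "cac_count": cac,
                "cac_proportion": cac_prop,
                "cad_count": cad,
                "cad_proportion": cad / (n - 1),
            }
        )
    out = pd.DataFrame(rows)
    if participants_df is not None:
        out = out.merge(participants_df, on="participant_id", how="left", validate="1:1")
    return out


#: Default variable order of the rendered correlation table.
CORRELATION_VARIABLES = (
    "cooperation",
    "cac_proportion",
    "sum_psychopathic_traits",
    "self_centred_impulsivity",
    "fearless_dominance",
    "coldheartedness",
    "narcissism",
    "maximise",
)


def correlation_matrix(
    summaries: pd.DataFrame, variables: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson correlations with two-sided p-values and significance stars.

    Returns ``(r, p, stars)`` DataFrames; pairs involving a constant variable
    are flagged NaN (correlation undefined).
    """
    variables = list(variables or CORRELATION_VARIABLES)
    data = summaries[variables].astype(float)
    if len(data) < 3:
        raise InputError("need at least 3 participants for a correlation matrix")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = data.iloc[:, i], data.iloc[:, j]
            if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=variables, columns=variables)
    pdf = pd.DataFrame(p, index=variables, columns=variables)
    sdf = pdf.map(lambda v: "" if np.isnan(v) else significance_stars(v))
    np.fill_diagonal(sdf.values, "")
    return rdf, pdf, sdf


def render_correlation_table(r: pd.DataFrame, stars: pd.DataFrame, digits: int = 2) -> str:
    """Lower-triangular text rendering in the style of a published matrix."""
    lines = ["\t" + "\t".join(r.columns)]
    for i, name in enumerate(r.index):
        cells = []
        for j in range(len(r.columns)):
            if j > i:
                cells.append("—")
            elif j == i:
                cells.append("1")
            else:
                v = r.iloc[i, j]
                cells.append("nan" if np.isnan(v) else f"{v:.{digits}f}{stars.iloc[i, j]}")
        lines.append(name + "\t" + "\t".join(cells))
    return "\n".join(lines)
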