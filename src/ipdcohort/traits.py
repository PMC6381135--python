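"""Psychometric scoring: PPI-R-40 factors, NPI-16 narcissism, IRS-10 exclusion.

The 40-item short form of the Psychopathic Personality Inventory - Revised is
scored on a 4-point ordinal scale into eight 5-item subscales; three of them
(social influence, fearlessness, stress immunity) aggregate to the *fearless
dominance* factor, four (Machiavellian egocentricity, rebellious nonconformity,
blame externalization, carefree nonplanfulness) to *self-centred impulsivity*,
and *coldheartedness* stands alone.  Factor scores are plain item sums after
flipping reverse-keyed items, and the three factors add up to the aggregate
``sum_psychopathic_traits`` measure.

The item->subscale assignment shipped here (:data:`DEFAULT_ITEM_MAP`) is a
synthetic stand-in with the right shape (40 items, 5 per subscale, a fixed
reverse-keyed pattern); the published assignment belongs to the copyrighted
instrument and can be dropped in as a CSV with the same columns.

Participants whose IRS-10 inconsistent-responding score reaches the cutoff
(>= 13, the 95th percentile in the validation sample) are excluded before any
analysis; no missing-item imputation is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

PPI_N_ITEMS = 40
NPI_N_ITEMS = 16
PPI_SCALE_MIN = 1
PPI_SCALE_MAX = 4
IRS_CUTOFF = 13

FD_SUBSCALES = ("social_influence", "fearlessness", "stress_immunity")
SCI_SUBSCALES = (
    "machiavellian_egocentricity",
    "rebellious_nonconformity",
    "blame_externalization",
    "carefree_nonplanfulness",
)
COLD_SUBSCALES = ("coldheartedness",)
FACTOR_OF_SUBSCALE = {
    **{s: "fearless_dominance" for s in FD_SUBSCALES},
    **{s: "self_centred_impulsivity" for s in SCI_SUBSCALES},
    **{s: "coldheartedness" for s in COLD_SUBSCALES},
}


def _default_item_map() -> pd.DataFrame:
    """Synthetic default item map: items 1-40, five per subscale.

    Items are assigned to subscales in blocks of five; within each subscale the
    fourth item is reverse-keyed (a fixed, documented pattern — the published
    keying is instrument-internal).
    """
    subscales = FD_SUBSCALES + SCI_SUBSCALES + COLD_SUBSCALES
    rows = []
    item = 1
    for sub in subscales:
        for j in range(5):
            rows.append(
                {
                    "item_id": item,
                    "subscale": sub,
                    "factor": FACTOR_OF_SUBSCALE[sub],
                    "reverse_keyed": int(j == 3),
                }
            )
            item += 1
    return pd.DataFrame(rows)


DEFAULT_ITEM_MAP = _default_item_map()


@dataclass(frozen=True)
class ItemResponses:
    """Raw questionnaire responses for one participant."""

    ppi_items: tuple[int, ...]
    npi_items: tuple[int, ...]
    irs10_score: int

    def __post_init__(self) -> None:
        if len(self.ppi_items) != PPI_N_ITEMS:
            raise InputError(f"expected {PPI_N_ITEMS} PPI items, got {len(self.ppi_items)}")
        if len(self.npi_items) != NPI_N_ITEMS:
            raise InputError(f"expected {NPI_N_ITEMS} NPI items, got {len(self.npi_items)}")
        bad = [i + 1 for i, r in enumerate(self.ppi_items) if not PPI_SCALE_MIN <= r <= PPI_SCALE_MAX]
        if bad:
            raise InputError(f"PPI responses outside {PPI_SCALE_MIN}-{PPI_SCALE_MAX} at items {bad}")
        if any(r not in (0, 1) for r in self.npi_items):
            raise InputError("NPI-16 responses must be binary 0/1")
        if self.irs10_score < 0:
            raise InputError("IRS-10 score must be non-negative")


@dataclass(frozen=True)
class TraitProfile:
    """Participant-level trait scores used throughout the analysis."""

    fearless_dominance: float
    self_centred_impulsivity: float
    coldheartedness: float
    narcissism: float
    gender: int  # 1 = female, 2 = male
    maximise: int  # 1-5 self-rated profit maximisation

    def __post_init__(self) -> None:
        if self.gender not in (1, 2):
            raise InputError(f"gender code must be 1 (female) or 2 (male), got {self.gender}")
        if not 1 <= self.maximise <= 5:
            raise InputError(f"maximise must be on 1-5, got {self.maximise}")

    @property
    def sum_psychopathic_traits(self) -> float:
        return self.fearless_dominance + self.self_centred_impulsivity + self.coldheartedness


def validate_item_map(item_map: pd.DataFrame) -> pd.DataFrame:
    required = {"item_id", "subscale", "factor", "reverse_keyed"}
    missing = required - set(item_map.columns)
    if missing:
        raise ConfigurationError(f"item map missing columns {sorted(missing)}")
    if sorted(item_map["item_id"]) != list(range(1, PPI_N_ITEMS + 1)):
        raise ConfigurationError("item map must cover items 1..40 exactly once each")
    unknown = set(item_map["factor"]) - {
        "fearless_dominance",
        "self_centred_impulsivity",
        "coldheartedness",
    }
    if unknown:
        raise ConfigurationError(f"unknown factors in item map: {sorted(unknown)}")
    return item_map


def score_ppi(
    responses: ItemResponses | Sequence[int], item_map: pd.DataFrame | None = None
) -> dict[str, float]:
    """Score the three PPI-R-40 factors from the 40 item responses.

    Reverse-keyed items are flipped on the 4-point scale
    (``r -> scale_min + scale_max - r``); each factor is the sum of its items.
    Missing (None/NaN) responses raise, naming the offending items.
    """
    items = responses.ppi_items if isinstance(responses, ItemResponses) else tuple(responses)
    if len(items) != PPI_N_ITEMS:
        raise InputError(f"expected {PPI_N_ITEMS} PPI responses, got {len(items)}")
    missing = [i + 1 for i, r in enumerate(items) if r is None or (isinstance(r, float) and np.isnan(r))]
    if missing:
        raise InputError(f"missing PPI responses at items {missing}; no imputation is performed")
    imap = validate_item_map(item_map if item_map is not None else DEFAULT_ITEM_MAP)
    vals = np.asarray(items, dtype=float)
    scores = {"fearless_dominance": 0.0, "self_centred_impulsivity": 0.0, "coldheartedness": 0.0}
    for _, row in imap.iterrows():
        v = vals[int(row["item_id"]) - 1]
        if row["reverse_keyed"]:
            v = PPI_SCALE_MIN + PPI_SCALE_MAX - v
        scores[row["factor"]] += v
    return scores


def score_npi(responses: ItemResponses | Sequence[int], scale_factor: float = 1.0) -> float:
    """Proportion of narcissism-consistent NPI-16 choices, optionally rescaled."""
    items = responses.npi_items if isinstance(responses, ItemResponses) else tuple(responses)
    if len(items) != NPI_N_ITEMS:
        raise InputError(f"expected {NPI_N_ITEMS} NPI responses, got {len(items)}")
    if any(r not in (0, 1) for r in items):
        raise InputError("NPI-16 responses must be binary 0/1")
    return scale_factor * sum(items) / NPI_N_ITEMS


def apply_irs_exclusion(
    cohort: Sequence, cutoff: int = IRS_CUTOFF, key=None
) -> tuple[list, int]:
    """Drop participants with IRS-10 score >= ``cutoff`` (order preserved).

    ``cohort`` may hold :class:`ItemResponses` or anything else if ``key``
    extracts the IRS-10 score.  Returns (retained, number excluded).
    """
    if cutoff < 0:
        raise InputError("cutoff must be non-negative")
    get = key or (lambda p: p.irs10_score)
    retained = [p for p in cohort if get(p) < cutoff]
    return retained, len(cohort) - len(retained)


def sum_psychopathy(profile: TraitProfile | dict) -> float:
    """Aggregate psychopathy: the sum of the three PPI factor scores."""
    if isinstance(profile, TraitProfile):
        return profile.sum_psychopathic_traits
    return (
        profile["fearless_dominance"]
        + profile["self_centred_impulsivity"]
        + profile["coldheartedness"]
    )


def cronbach_alpha(item_matrix: np.ndarray) -> float:
    """Cronbach's alpha for an (n participants x k items) response matrix.

    Provided as a descriptive utility; internal-consistency values are
    properties of a dataset, not of the scoring procedure.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise InputError("need a 2-D matrix with at least two items")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise InputError("total score is constant; alpha undefined")
    return k / (k - 1) * (1 - item_var / total_var)


def score_cohort(
    responses: Iterable[ItemResponses],
    genders: Sequence[int],
    maximises: Sequence[int],
    item_map: pd.DataFrame | None = None,
    npi_scale_factor: float = 1.0,
    irs_cutoff: int = IRS_CUTOFF,
) -> pd.DataFrame:
    """Score a cohort into the participant-level table.

    Returns one row per participant with factor scores, narcissism, the
    aggregate, the IRS-10 score and a ``retained`` flag (exclusion applied at
    ``irs_cutoff`` but rows kept so attrition is auditable).
    """
    rows = []
    for pid, (resp, g, m) in enumerate(zip(responses, genders, maximises), start=1):
        f = score_ppi(resp, item_map)
        rows.append(
            {
                "participant_id": pid,
                "gender": g,
                "maximise": m,
                "fearless_dominance": f["fearless_dominance"],
                "self_centred_impulsivity": f["self_centred_impulsivity"],
                "coldheartedness": f["coldheartedness"],
                "narcissism": score_npi(resp, npi_scale_factor),
                "irs10": resp.irs10_score,
                "retained": int(resp.irs10_score < irs_cutoff),
            }
        )
    df = pd.DataFrame(rows)
    df["sum_psychopathic_traits"] = (
        df["fearless_dominance"] + df["self_centred_impulsivity"] + df["coldheartedness"]
    )
    return df
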