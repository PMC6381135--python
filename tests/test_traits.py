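"""Psychometric scoring and the inconsistent-responding exclusion."""

import numpy as np
import pandas as pd
import pytest

from ipdcohort.errors import InputError
from ipdcohort.traits import (
    DEFAULT_ITEM_MAP,
    ItemResponses,
    TraitProfile,
    apply_irs_exclusion,
    cronbach_alpha,
    score_cohort,
    score_npi,
    score_ppi,
    sum_psychopathy,
)


def make_responses(ppi=1, npi=0, irs=0):
    return ItemResponses((ppi,) * 40 if isinstance(ppi, int) else tuple(ppi),
                         (npi,) * 16 if isinstance(npi, int) else tuple(npi),
                         irs)


def test_default_item_map_shape():
    assert len(DEFAULT_ITEM_MAP) == 40
    per_factor = DEFAULT_ITEM_MAP.groupby("factor").size()
    assert per_factor["fearless_dominance"] == 15
    assert per_factor["self_centred_impulsivity"] == 20
    assert per_factor["coldheartedness"] == 5
    assert DEFAULT_ITEM_MAP.groupby("subscale").size().eq(5).all()


def test_score_ppi_minimum_without_reverse_keying():
    imap = DEFAULT_ITEM_MAP.assign(reverse_keyed=0)
    scores = score_ppi(make_responses(ppi=1), imap)
    assert scores == {
        "fearless_dominance": 15,
        "self_centred_impulsivity": 20,
        "coldheartedness": 5,
    }


def test_reverse_keyed_items_flip_on_the_scale():
    """A response of 1 on a 1-4 scale scores 4 when the item is reverse-keyed."""
    imap = DEFAULT_ITEM_MAP.assign(reverse_keyed=0)
    imap.loc[imap["item_id"] == 1, "reverse_keyed"] = 1
    responses = [4] + [1] * 39  # item 1 answered 4, reverse-keyed -> 1
    scores = score_ppi(responses, imap)
    assert scores["fearless_dominance"] == 1 + 14  # flipped 4->1 plus 14 ones
    # and a 2-item toy check: (4, 1) with item 2 reverse-keyed scores 4 + 4
    vals = np.zeros(40, int) + 1
    vals[0], vals[1] = 4, 1
    imap2 = DEFAULT_ITEM_MAP.assign(reverse_keyed=0)
    imap2.loc[imap2["item_id"] == 2, "reverse_keyed"] = 1
    s = score_ppi(list(vals), imap2)
    assert s["fearless_dominance"] == 4 + 4 + 13


def test_coldheartedness_reaches_published_maximum():
    """All coldheartedness items at the scale top give the observed max of 20."""
    imap = DEFAULT_ITEM_MAP.assign(reverse_keyed=0)
    cold_items = imap.loc[imap["factor"] == "coldheartedness", "item_id"]
    vals = [4 if i in set(cold_items) else 1 for i in range(1, 41)]
    assert score_ppi(vals, imap)["coldheartedness"] == 20


def test_scoring_is_permutation_invariant_given_the_map(rng):
    vals = rng.integers(1, 5, size=40)
    perm = rng.permutation(40)
    imap = DEFAULT_ITEM_MAP.iloc[perm].reset_index(drop=True)
    assert score_ppi(list(vals), imap) == score_ppi(list(vals), DEFAULT_ITEM_MAP)


def test_missing_items_raise_with_names():
    vals = [1] * 40
    vals[4] = None
    with pytest.raises(InputError, match=r"\[5\]"):
        score_ppi(vals)


def test_npi_proportion():
    assert score_npi([0] * 16) == 0.0
    assert score_npi([1] * 16) == 1.0
    assert score_npi([1] * 4 + [0] * 12) == 0.25
    assert score_npi([1] * 4 + [0] * 12, scale_factor=0.33) == pytest.approx(0.0825)


def test_irs_exclusion_boundary_and_order():
    cohort = [make_responses(irs=s) for s in (12, 13, 5, 14, 0)]
    retained, excluded = apply_irs_exclusion(cohort)
    assert excluded == 2  # scores 13 and 14 removed; 12 retained
    assert [p.irs10_score for p in retained] == [12, 5, 0]


def test_irs_exclusion_reproduces_published_attrition(rng):
    """A 206-participant cohort with 14 scores >= 13 retains 192."""
    scores = [int(s) for s in rng.integers(0, 13, size=192)] + [13, 14, 15, 13, 20, 13, 16, 13, 14, 13, 13, 17, 13, 19]
    cohort = [make_responses(irs=s) for s in scores]
    assert len(cohort) == 206
    retained, excluded = apply_irs_exclusion(cohort, cutoff=13)
    assert (len(retained), excluded) == (192, 14)


def test_exclusion_monotone_in_cutoff(rng):
    cohort = [make_responses(irs=int(s)) for s in rng.integers(0, 25, size=80)]
    sizes = [len(apply_irs_exclusion(cohort, cutoff=c)[0]) for c in range(0, 26)]
    assert sizes == sorted(sizes)


def test_sum_psychopathy():
    assert sum_psychopathy(
        {"fearless_dominance": 0, "self_centred_impulsivity": 0, "coldheartedness": 0}
    ) == 0
    assert sum_psychopathy(
        {"fearless_dominance": 34.67, "self_centred_impulsivity": 30.91, "coldheartedness": 10.78}
    ) == pytest.approx(76.36)
    profile = TraitProfile(17, 16, 5, 0.0, 1, 5)
    assert profile.sum_psychopathic_traits == 38


def test_trait_profile_validation():
    with pytest.raises(InputError):
        TraitProfile(10, 10, 10, 0.1, 3, 4)
    with pytest.raises(InputError):
        TraitProfile(10, 10, 10, 0.1, 1, 6)


def test_score_cohort_roundtrip(tmp_path, rng):
    responses = [
        make_responses(ppi=list(rng.integers(1, 5, size=40)),
                       npi=list(rng.integers(0, 2, size=16)),
                       irs=int(rng.integers(0, 16)))
        for _ in range(20)
    ]
    df = score_cohort(responses, [1] * 10 + [2] * 10, [4] * 20)
    assert (df["sum_psychopathic_traits"] ==
            df[["fearless_dominance", "self_centred_impulsivity", "coldheartedness"]].sum(axis=1)).all()
    assert set(df.loc[df["irs10"] >= 13, "retained"]) <= {0}
    path = tmp_path / "scored.csv"
    df.to_csv(path, index=False)
    back = pd.read_csv(path)
    pd.testing.assert_frame_equal(back, df, check_dtype=False)


def test_cronbach_alpha_known_value():
    # parallel items with shared signal: alpha from the closed form
    rng = np.random.default_rng(5)
    signal = rng.normal(size=(500, 1))
    items = signal + rng.normal(scale=1.0, size=(500, 4))
    alpha = cronbach_alpha(items)
    # theoretical alpha = k*rho / (1 + (k-1)*rho) with rho = 0.5
    assert alpha == pytest.approx(4 * 0.5 / (1 + 3 * 0.5), abs=0.08)
    with pytest.raises(InputError):
        cronbach_alpha(np.ones((10, 3)))
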