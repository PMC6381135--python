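"""Tremble-likelihood strategy inference: subject fits, cohort aggregation,
bootstrap uncertainty, trait correlations, and the population mixture."""

import numpy as np
import pandas as pd
import pytest

from ipdcohort.actions import JointHistory
from ipdcohort.automata import build_strategy_set
from ipdcohort.cohort import CohortSpec, generate_cohort
from ipdcohort.errors import InputError
from ipdcohort.inference import (
    GAMMA_BOUNDS,
    beta_from_gamma,
    bootstrap_se,
    cohort_estimates,
    fit_cohort,
    fit_subject,
    gamma_from_beta,
    match_counts,
    render_strategy_table,
    sequence_likelihood,
    sfem_population,
    trait_strategy_correlations,
)

from oracles import all_joint_histories, grid_fit_oracle


def jh(own, opp):
    return JointHistory(tuple(own), tuple(opp), rounds_total=max(len(own), 1))


def test_gamma_beta_mapping():
    assert beta_from_gamma(1.0) == pytest.approx(1 / (1 + np.exp(-1)))
    assert beta_from_gamma(0.001) == pytest.approx(1.0)
    for beta in (0.6, 0.75, 0.9, 0.99):
        assert beta_from_gamma(gamma_from_beta(beta)) == pytest.approx(beta)
    # gamma < 1 corresponds to compliance above ~0.73 ("good approximation")
    assert beta_from_gamma(1.0) > 0.73


def test_sequence_likelihood():
    assert sequence_likelihood("CCC", "CCC", 1.0) == 1.0
    assert sequence_likelihood("CDC", "CCC", 0.5) == 0.5**3
    assert sequence_likelihood("CDC", "CDC", 0.5) == 0.5**3
    assert sequence_likelihood("CDC", "CCC", 0.8) == pytest.approx(0.8 * 0.2 * 0.8)
    with pytest.raises(InputError):
        sequence_likelihood("CC", "C", 0.9)


def test_fit_subject_dominant_strategy():
    """A pure ALLD sequence: ALLD weight ~1 and gamma at the no-error end."""
    own = ("D",) * 30
    opp = ("C", "C") + ("D",) * 28
    fit = fit_subject(jh(own, opp), ["ALLD", "ALLC"])
    assert fit.weights[0] > 0.99
    assert fit.best_strategy == "ALLD"
    assert beta_from_gamma(fit.gamma_hat) > 0.999


def test_identical_prescriptions_split_weights_equally():
    # ALLC and TF3T prescribe identically when the opponent never defects thrice
    own = ("C",) * 10
    opp = ("C",) * 10
    fit = fit_subject(jh(own, opp), ["ALLC", "TF3T"])
    assert fit.weights == pytest.approx([0.5, 0.5])


def test_weights_are_a_simplex_point(small_cohort):
    strategies = build_strategy_set("table6")
    fits = fit_cohort(small_cohort["rounds_df"], strategies)
    for f in fits:
        assert f.weights.min() >= 0
        assert f.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert GAMMA_BOUNDS[0] <= f.gamma_hat <= GAMMA_BOUNDS[1]


def test_fit_matches_grid_oracle_on_tiny_instances():
    """Bounded-search fits equal an exhaustive gamma-grid oracle (T=3, 2 strategies)."""
    strategies = build_strategy_set(["Grim", "ALLD"])
    for own, opp in all_joint_histories(3, min_len=3):
        h = jh(own, opp)
        fit = fit_subject(h, strategies)
        m = match_counts(h, strategies)
        _, w_oracle = grid_fit_oracle(m, 3)
        assert np.allclose(fit.weights, w_oracle, atol=1e-3), (own, opp)


def test_adding_a_matching_round_never_lowers_relative_weight():
    """Appending a round that matches strategy s and mismatches strategy t
    cannot decrease s's weight."""
    strategies = build_strategy_set(["ALLD", "ALLC"])
    own = ("D", "C", "D")
    opp = ("C", "C", "D")
    before = fit_subject(jh(own, opp), strategies)
    after = fit_subject(jh(own + ("D",), opp + ("D",)), strategies)
    assert after.weights[0] >= before.weights[0]


def test_cohort_estimates_are_weight_means():
    own1, opp1 = ("D",) * 30, ("C", "C") + ("D",) * 28
    own2, opp2 = ("C",) * 30, ("C",) * 28 + ("D", "D")
    strategies = build_strategy_set(["ALLD", "ALLC"])
    f1 = fit_subject(jh(own1, opp1), strategies, participant_id=1)
    f2 = fit_subject(jh(own2, opp2), strategies, participant_id=2)
    est = cohort_estimates([f1, f2])
    expected = (f1.weights + f2.weights) / 2
    assert est.frequencies == pytest.approx(expected)
    assert est.mean_gamma == pytest.approx((f1.gamma_hat + f2.gamma_hat) / 2)


def test_bootstrap_degenerate_cohort_has_zero_se():
    strategies = build_strategy_set(["ALLD", "ALLC"])
    fit = fit_subject(jh(("D",) * 30, ("C", "C") + ("D",) * 28), strategies, 1)
    fits = [fit] * 25
    est = bootstrap_se(fits, B=200, seed=0)
    assert np.allclose(est.se, 0.0)
    assert est.pvalues[0] == 0.0  # positive frequency, zero variance
    assert est.pvalues[1] == 1.0  # zero frequency never significant


def test_bootstrap_seed_stability(small_cohort):
    strategies = build_strategy_set("table6")
    fits = fit_cohort(small_cohort["rounds_df"], strategies)
    e1 = bootstrap_se(fits, B=1000, seed=1)
    e2 = bootstrap_se(fits, B=1000, seed=2)
    mask = e1.se > 0.005
    assert np.all(np.abs(e1.se[mask] - e2.se[mask]) / e1.se[mask] < 0.10)


def test_trait_strategy_correlation_perfect_proportionality():
    strategies = build_strategy_set(["ALLD", "ALLC"])
    fits = []
    rows = []
    rng = np.random.default_rng(0)
    for pid in range(30):
        n_defect = int(rng.integers(0, 31))
        own = ("D",) * n_defect + ("C",) * (30 - n_defect)
        records = jh(own, ("C",) * 30)
        f = fit_subject(records, strategies, participant_id=pid)
        fits.append(f)
        rows.append(
            {
                "participant_id": pid,
                "fearless_dominance": f.weights[0],  # trait == ALLD weight
                "self_centred_impulsivity": rng.normal(),
                "coldheartedness": rng.normal(),
            }
        )
    corr = trait_strategy_correlations(fits, pd.DataFrame(rows))
    row = corr[(corr.trait == "fearless_dominance") & (corr.strategy == "ALLD")].iloc[0]
    assert row.r == pytest.approx(1.0)
    assert row.stars == "***"


def test_trait_strategy_null_correlations_are_small():
    """Weights independent of traits by construction: |r| stays near zero."""
    spec = CohortSpec(n_participants=150, rng_seed=21)
    _, pdf, rdf, _ = generate_cohort(spec)
    fits = fit_cohort(rdf, build_strategy_set("table6"))
    corr = trait_strategy_correlations(fits, pdf)
    assert corr.r.abs().max() < 0.25  # null at n=150: 3/sqrt(150) ~ 0.24


def test_trait_linked_generation_yields_positive_correlation():
    spec = CohortSpec(
        n_participants=400,
        rng_seed=8,
        strategy_mix={"ALLD": 0.5, "TF3T": 0.5},
        trait_strategy_link={"TF3T": {"coldheartedness": 1.5}},
    )
    _, pdf, rdf, _ = generate_cohort(spec)
    fits = fit_cohort(rdf, build_strategy_set(["ALLD", "TF3T"]))
    corr = trait_strategy_correlations(fits, pdf)
    row = corr[(corr.trait == "coldheartedness") & (corr.strategy == "TF3T")].iloc[0]
    assert row.r > 0.2


def test_sfem_single_strategy_trivial(small_cohort):
    pop = sfem_population(small_cohort["rounds_df"], ["ALLD"])
    assert pop.phi == pytest.approx([1.0])


def test_sfem_two_strategy_recovery():
    """Population mixture of ALLD and ALLC players is recovered by SFEM."""
    spec = CohortSpec(
        n_participants=200,
        rng_seed=17,
        strategy_mix={"ALLD": 0.7, "ALLC": 0.3},
        tremble_beta=0.9,
    )
    _, _, rdf, _ = generate_cohort(spec)
    pop = sfem_population(rdf, ["ALLD", "ALLC"], seed=0)
    assert pop.phi[0] == pytest.approx(0.7, abs=0.07)
    assert beta_from_gamma(pop.gamma) == pytest.approx(0.9, abs=0.02)


def test_sfem_agrees_with_subject_average_on_separable_mix():
    spec = CohortSpec(
        n_participants=200,
        rng_seed=29,
        strategy_mix={"ALLD": 0.6, "ALLC": 0.4},
        tremble_beta=0.92,
    )
    _, _, rdf, _ = generate_cohort(spec)
    fits = fit_cohort(rdf, build_strategy_set(["ALLD", "ALLC"]))
    est = cohort_estimates(fits)
    pop = sfem_population(fits, seed=0)
    assert np.all(np.abs(est.frequencies - pop.phi) < 0.10)


def test_render_strategy_table(small_cohort):
    fits = fit_cohort(small_cohort["rounds_df"], build_strategy_set("table6"))
    est = bootstrap_se(fits, B=200, seed=0)
    text = render_strategy_table(est)
    assert "Gamma" in text and "ALLD" in text and "(" in text
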