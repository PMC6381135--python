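import numpy as np
import pandas as pd
import pytest

from ipdcohort.cohort import CohortSpec, generate_cohort
from ipdcohort.metrics import summarize_participants


@pytest.fixture(scope="session")
def small_cohort():
    """A 48-participant synthetic cohort (divisible by 8, fast to fit)."""
    spec = CohortSpec(n_participants=48, rng_seed=123)
    participants, participants_df, rounds_df, manifest = generate_cohort(spec)
    return {
        "spec": spec,
        "participants": participants,
        "participants_df": participants_df,
        "rounds_df": rounds_df,
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def small_summaries(small_cohort):
    df = summarize_participants(
        small_cohort["rounds_df"], small_cohort["participants_df"]
    )
    df["rounds_for_dv"] = df["rounds"]
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
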