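import numpy as np
import pandas as pd
import pytest

from acuitywm import observers
from acuitywm.acuity import aggregate_cells


@pytest.fixture(scope="session")
def change_schedule():
    return observers.make_change_schedule(seed=11)


@pytest.fixture(scope="session")
def dot_schedule():
    return observers.make_dot_schedule(seed=12)


@pytest.fixture(scope="session")
def small_cohort_trials():
    """12-subject null cohort with full trial logs (shared across tests)."""
    spec = observers.CohortSpec(n_subjects=12, seed=7)
    change, dot, change_obs, acuity_obs = observers.simulate_cohort_trials(spec)
    return {
        "change": change,
        "dot": dot,
        "change_obs": change_obs,
        "acuity_obs": acuity_obs,
    }


def make_cells(omega, n_per_cell=100_000, rng=None, refs=(16, 32)):
    """Psychometric cells with (nearly) noiseless or binomial response counts."""
    from acuitywm.acuity import p_larger

    rows = []
    for ref in refs:
        for comp in observers.DOT_COMPARISONS[ref]:
            p = p_larger(comp, ref, omega)
            if rng is None:
                chose = int(round(p * n_per_cell))
            else:
                chose = int(rng.binomial(n_per_cell, p))
            rows.append(
                {"ref_num": ref, "n_comp": comp, "n_trials": n_per_cell, "n_chose_comp": chose}
            )
    return pd.DataFrame(rows)
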