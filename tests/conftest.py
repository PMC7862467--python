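from fractions import Fraction
from itertools import product

import pytest

from cogedkit import WORKING_MEMORY, run_cell, score_records


def scripted_agent(choices):
    """Agent that plays back a fixed 5-choice sequence."""
    it = iter(choices)
    return lambda pair: next(it)


def enumerate_all_records(bases=(2, 3, 4)):
    """Every possible cell outcome: 2^5 choice paths x bases.

    The first choice fixes the titrated side (and the first_choice branch of
    the scoring rule); paths starting with 'easy' and 'hard' together cover
    both branches.
    """
    records = []
    for base in bases:
        for path in product(("easy", "hard"), repeat=5):
            records.append(
                run_cell(scripted_agent(path), WORKING_MEMORY, "2back", base)
            )
    return records


@pytest.fixture(scope="session")
def all_cell_records():
    return enumerate_all_records()


@pytest.fixture(scope="session")
def small_cohort_results():
    """One small simulated study reused by read-only tests."""
    from cogedkit import AnalysisConfig, CohortConfig, run_pipeline

    cfg = AnalysisConfig(cohort=CohortConfig(n_participants=60, seed=11), seed=4)
    return run_pipeline(cfg)
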