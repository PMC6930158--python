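import dataclasses

import numpy as np
import pandas as pd
import pytest

from immunoscreen import (
    ClinicalTable,
    ExpressionMatrix,
    SurvivalData,
    derive_responder_labels,
    reference_scenarios,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def recovery_cohort():
    """One combo-recovery cohort (4 planted genes among 10, n=164)."""
    cfg = dataclasses.replace(reference_scenarios()["combo-recovery"], seed=11)
    expr, clin = simulate_cohort(cfg)
    return expr, clin


@pytest.fixture(scope="session")
def recovery_labels(recovery_cohort):
    _, clin = recovery_cohort
    return derive_responder_labels(clin.survival())


@pytest.fixture
def tiny_expression():
    return ExpressionMatrix(
        pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], [2.5, 2.5, 2.5, 3.0]],
            index=["G1", "G2", "G3"],
            columns=["A", "B", "C", "D"],
        )
    )


@pytest.fixture
def tiny_clinical():
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": ["A", "B", "C", "D"],
                "rfs_time": [12.0, 70.0, 45.0, 80.0],
                "rfs_event": [1, 0, 0, 1],
                "pcr": [1, 0, np.nan, 0],
                "subtype": ["TNBC", "TNBC", "HER2", "TNBC"],
                "treatment": ["neoadjuvant-chemo"] * 4,
                "nodal_status": [0, 1, 0, 1],
                "grade": [3, 2, 3, 1],
                "age": [50, 61, 47, 55],
            }
        )
    )


def make_survival(time, event):
    return SurvivalData(np.asarray(time, float), np.asarray(event, float))
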