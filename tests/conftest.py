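import numpy as np
import pandas as pd
import pytest

from maternome.datatypes import ExpressionMatrix, SampleTable
from maternome.simulate import SimulationConfig, simulate_expression, simulate_ga_schedule


@pytest.fixture(scope="session")
def small_sim():
    """A small planted study: 30 subjects, 40 genes (10 per trajectory class)."""
    config = SimulationConfig(
        n_subjects=30, n_genes=40,
        class_assignment=tuple(["null"] * 10 + ["increasing"] * 10
                               + ["decreasing"] * 10 + ["u_shape"] * 10),
        amplitude_log2=1.0, sd_subject=0.5, sd_resid=0.25,
        n_batches=1, batch_effect_sd=0.0, absent_fraction=0.0,
        n_labor_subjects=0, seed=42)
    schedule = simulate_ga_schedule(config)
    expr, truth = simulate_expression(config, schedule)
    return {"config": config, "schedule": schedule, "expr": expr, "truth": truth}


@pytest.fixture()
def tiny_expr():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 2.5, 3.0, 3.5], [5.0, 5.0, 5.0, 5.0]],
        index=["G1", "G2", "G3"], columns=["S1", "S2", "S3", "S4"])
    return ExpressionMatrix(data)


@pytest.fixture()
def tiny_meta():
    return SampleTable(pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4"],
        "subject_id": ["A", "A", "B", "B"],
        "ga_weeks": [10.0, 38.0, 12.0, 39.0],
        "batch": ["B1", "B1", "B1", "B1"],
        "labor_at_draw": [False, False, False, True],
    }))
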