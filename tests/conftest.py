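import numpy as np
import pandas as pd
import pytest

from omnifiber import ExpressionMatrix, SimulationConfig, StudyDesign, generate_study


@pytest.fixture(scope="session")
def study():
    """A small synthetic study with every planted class present."""
    cfg = SimulationConfig(n_genes=400, seed=42)
    return generate_study(cfg)


@pytest.fixture
def two_stage_design():
    """One region, two stages, three replicates — minimal presence design."""
    rows = []
    for stage in ("S1", "S2"):
        for rep in (1, 2, 3):
            rows.append(
                {"sample_id": f"LD_{stage}_r{rep}", "region": "LD", "stage": stage,
                 "replicate": rep}
            )
    return StudyDesign(pd.DataFrame(rows), stages=("S1", "S2"), regions=("LD",))


def make_matrix(rows: dict, sample_ids, modality="protein", scale="linear"):
    """Build an ExpressionMatrix from {feature_id: list_of_values}."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(sample_ids)).astype(float)
    return ExpressionMatrix(df, modality=modality, scale=scale)
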