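import numpy as np
import pandas as pd
import pytest

from subjectds.io import CellAnnotation, CellCounts, SubjectDesign
from subjectds.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def tiny_counts():
    """2 genes x 3 cells, cells c1,c2 -> S1 and c3 -> S2."""
    return CellCounts(["g1", "g2"], ["c1", "c2", "c3"], np.array([[1, 2, 3], [0, 0, 5]]))


@pytest.fixture
def tiny_annotation():
    return CellAnnotation(
        pd.DataFrame(
            {
                "cell_id": ["c1", "c2", "c3"],
                "subject_id": ["S1", "S1", "S2"],
                "cell_type": ["secretory"] * 3,
            }
        )
    )


@pytest.fixture
def tiny_design():
    return SubjectDesign.from_groups(["S1", "S2"], ["ctrl", "treat"])


@pytest.fixture(scope="session")
def medium_dataset():
    """One modest simulated replicate shared by pipeline-level tests."""
    cfg = SimulationConfig(n_genes=300, cells_per_subject=60, p_de=0.3, tau=1.2, seed=42)
    counts, annotation, design, truth, params = simulate_dataset(cfg, 0)
    return counts, annotation, design, truth, params
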