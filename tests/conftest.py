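import numpy as np
import pandas as pd
import pytest

from ipondtmt import synthetic_data as sd
from ipondtmt.preprocess import NormalizedMatrix


def make_design(treatments=("DMSO", "TPL", "DRB"),
                time_points=("Nascent", "1h", "2h"), n_batches=2) -> pd.DataFrame:
    rows = []
    for t in treatments:
        for tp in time_points:
            for b in range(1, n_batches + 1):
                rows.append({"sample_id": f"{t}_{tp}_b{b}", "treatment": t,
                             "time_point": tp, "batch": f"b{b}"})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_sim():
    """A 400-protein simulation with one planted TPL depletion."""
    cfg = sd.SimConfig(n_proteins=400, n_batches=3, n_decoys=10,
                       n_contaminants=5, missing_rate_at_low=0.05,
                       missing_rate_at_high=0.0, seed=11)
    genes = [f"G{i:05d}" for i in range(1, 401)]
    sets = [sd.GeneSet.of("remodellers", genes[:25], "remodeller_family")]
    effects = [sd.PlantedEffect("remodellers", "treatment", "TPL", -0.5)]
    table, design, truth = sd.simulate_dataset(cfg, effects, sets)
    return {"config": cfg, "sets": sets, "effects": effects, "table": table,
            "design": design, "truth": truth}


@pytest.fixture
def random_matrix():
    """Small complete log2 matrix + balanced 12-sample design."""
    design = make_design(treatments=("DMSO", "TPL"),
                         time_points=("Nascent", "2h"), n_batches=3)
    rng = np.random.default_rng(5)
    values = rng.normal(0.0, 0.5, (40, len(design)))
    matrix = NormalizedMatrix(
        values=pd.DataFrame(values,
                            index=pd.Index([f"P{i:03d}" for i in range(40)],
                                           name="protein_id"),
                            columns=design["sample_id"]),
        log_base=2,
    )
    return matrix, design
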