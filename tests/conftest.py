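import numpy as np
import pandas as pd
import pytest

from mirten import TargetCollection, SimTruth, simulate_collection, simulate_dea


@pytest.fixture
def tiny_collection() -> TargetCollection:
    """Two regulators over three genes, with scores, site types and UTRs."""
    rec = pd.DataFrame(
        {
            "regulator": ["miR-1", "miR-1", "miR-2"],
            "feature": ["G1", "G2", "G1"],
            "sites": [2, 1, 1],
            "score": [-0.4, -0.1, -0.2],
            "site_type": ["8mer", "7mer-A1", "7mer-m8"],
        }
    )
    meta = pd.DataFrame(
        {"utr_length": [1000.0, 500.0, 1500.0]},
        index=pd.Index(["G1", "G2", "G3"], name="feature"),
    )
    return TargetCollection(rec, feature_meta=meta)


def make_dea(features, logfc, fdr, pvalue=None, mean_expr=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "feature": list(features),
            "logFC": np.asarray(logfc, dtype=float),
            "pvalue": np.asarray(pvalue if pvalue is not None else fdr, dtype=float),
            "fdr": np.asarray(fdr, dtype=float),
        }
    )
    if mean_expr is not None:
        df["mean_expr"] = np.asarray(mean_expr, dtype=float)
    return df


@pytest.fixture(scope="session")
def sim_collection() -> TargetCollection:
    return simulate_collection(n_genes=2000, n_regulators=50, seed=0)


@pytest.fixture(scope="session")
def sim_active(sim_collection):
    """Perturbation DEA with mir-7 active at beta = 1."""
    truth = SimTruth(active={"mir-7": 1.0}, noise_sd=0.3, n_genes=2000, seed=0)
    return simulate_dea(sim_collection, truth), "mir-7"
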