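import logging

import numpy as np
import pandas as pd
import pytest

from misonet.datamodel import MultiOmicsDataset, OmicsMatrix, PriorNetwork
from misonet.synthetic import generate_ground_truth, simulate_dataset

logging.getLogger("misonet").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_gt():
    return generate_ground_truth(30, 6, 8, mean_degree=3, seed=7)


@pytest.fixture(scope="session")
def small_ds(small_gt):
    return simulate_dataset(small_gt, 80, seed=8)


@pytest.fixture()
def toy_dataset():
    """Hand-built 6-sample dataset with three layers and covariates."""
    rng = np.random.default_rng(0)
    samples = [f"s{i}" for i in range(6)]
    expr = pd.DataFrame(rng.normal(size=(6, 3)), index=samples, columns=["g1", "g2", "g3"])
    cnv = pd.DataFrame(rng.normal(size=(6, 2)), index=samples, columns=["c1", "c2"])
    meth = pd.DataFrame(rng.uniform(0.1, 0.9, size=(6, 2)), index=samples, columns=["m1", "m2"])
    cov = pd.DataFrame({"age": rng.normal(60, 5, 6), "sex": [0, 1, 0, 1, 0, 1]}, index=samples)
    return MultiOmicsDataset(
        {
            "expression": OmicsMatrix("expression", expr),
            "cnv": OmicsMatrix("cnv", cnv),
            "methylation": OmicsMatrix("methylation", meth),
        },
        OmicsMatrix("covariate", cov),
    )


@pytest.fixture()
def toy_prior():
    layer_of = {
        "g1": "expression", "g2": "expression", "g3": "expression",
        "c1": "cnv", "c2": "cnv", "m1": "methylation", "m2": "methylation",
    }
    edges = {("g1", "g2"), ("g2", "g3"), ("c1", "g1"), ("m1", "g2"), ("m2", "g2")}
    return PriorNetwork(edges, layer_of)
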