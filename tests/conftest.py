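import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import batchbench as bb

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_sheet(batches, groups, extra=None, ids=None):
    n = len(batches)
    ids = ids or [f"S{i + 1:03d}" for i in range(n)]
    data = {"batch": list(batches), "group": list(groups)}
    if extra:
        data.update(extra)
    return bb.SampleSheet(pd.DataFrame(data, index=pd.Index(ids, name="sample_id")))


def make_expr(values, ids=None, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    ids = ids or [f"S{i + 1:03d}" for i in range(values.shape[1])]
    return bb.ExpressionMatrix(genes, ids, values)


@pytest.fixture
def toy_two_batch():
    """2 genes x 4 samples, batches {S1,S2} and {S3,S4}."""
    expr = make_expr([[1.0, 3.0, 5.0, 7.0], [2.0, 2.0, 8.0, 4.0]])
    sheet = make_sheet(["B1", "B1", "B2", "B2"],
                      ["control", "case", "control", "case"])
    return expr, sheet


@pytest.fixture(scope="session")
def small_ls_dataset():
    """60 genes x 20 samples with known injected batch effects."""
    rng = np.random.default_rng(7)
    g = 60
    ids = [f"S{i:02d}" for i in range(20)]
    sheet = make_sheet(["B1"] * 10 + ["B2"] * 10,
                      ["control", "case"] * 10, ids=ids)
    params = bb.LSModelParams(
        alpha=rng.normal(7, 2, g),
        beta=rng.normal(0, 0.8, g),
        sigma=np.full(g, 0.6),
        gamma={"B1": rng.normal(0, 0.8, g), "B2": rng.normal(0, 0.8, g)},
        delta={"B1": np.exp(rng.normal(0, 0.2, g)),
               "B2": np.exp(rng.normal(0, 0.2, g))},
        treatment_group="case",
    )
    expr = bb.sample_ls_model(params, sheet, rng)
    return expr, sheet, params
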