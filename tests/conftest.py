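import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from hlik.data import GLMMData, LongTable, TableSchema


def glmm_data_from_arrays(y, X, group_indices, offset=None, family="poisson"):
    """Assemble a GLMMData from raw arrays.

    ``group_indices``: dict factor name -> integer level index per row.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.asarray(X, dtype=float)
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    blocks, group_blocks, group_levels = [], {}, {}
    col0 = 0
    for name, idx in group_indices.items():
        idx = np.asarray(idx)
        q_k = int(idx.max()) + 1
        blocks.append(sparse.csc_matrix((np.ones(n), (np.arange(n), idx)), shape=(n, q_k)))
        group_blocks[name] = (col0, col0 + q_k)
        group_levels[name] = [f"{name}{j}" for j in range(q_k)]
        col0 += q_k
    Z = sparse.hstack(blocks, format="csc")
    return GLMMData(
        y=y, X=X, Z=Z, offset=offset, family_tag=family,
        x_names=[f"x{j}" for j in range(X.shape[1])],
        group_blocks=group_blocks, group_levels=group_levels,
    )


@pytest.fixture
def balanced_oneway_gaussian():
    """y = (1,2,3,4), groups (A,A,B,B), intercept only.

    Closed forms: REML gives beta=2.5, sigma_u^2=(MSB-MSW)/k=(4-0.5)/2=1.75,
    phi=MSW=0.5.
    """
    return glmm_data_from_arrays(
        [1.0, 2.0, 3.0, 4.0], np.ones((4, 1)), {"g": [0, 0, 1, 1]}, family="gaussian"
    )


@pytest.fixture
def single_obs_poisson():
    """y=[1], intercept design, one random intercept."""
    return glmm_data_from_arrays([1.0], [[1.0]], {"g": [0]}, family="poisson")


def random_poisson_instance(rng, n_groups=8, obs_per_group=4, p=2, sigma=0.7):
    """A small random Poisson GLMM dataset with a single grouping factor."""
    n = n_groups * obs_per_group
    idx = np.repeat(np.arange(n_groups), obs_per_group)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))]) if p > 1 else np.ones((n, 1))
    beta = rng.normal(scale=0.5, size=p)
    u = rng.normal(scale=sigma, size=n_groups)
    eta = X @ beta + u[idx] - 1.0
    y = rng.poisson(np.exp(eta)).astype(float)
    data = glmm_data_from_arrays(y, X, {"g": idx}, family="poisson")
    return data, beta, sigma


def long_table_3rows():
    frame = pd.DataFrame(
        {
            "patient_id": ["p1", "p1", "p2"],
            "facility_id": ["f1", "f2", "f1"],
            "event": [0.0, 1.0, 0.0],
            "duration_days": [10.0, 3.0, 7.5],
            "age": [60.0, 60.5, 72.0],
        }
    )
    schema = TableSchema(numeric_covariates=("age",))
    return LongTable(frame=frame, schema=schema)
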