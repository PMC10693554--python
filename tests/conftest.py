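import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ch4pred.dataset_io import ModelingMatrix, prepare_matrix, standardize_train_apply_test
from ch4pred.synthetic import SyntheticConfig, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_matrix(
    X,
    y,
    group,
    columns=None,
    family="ANIM-B",
    kinds=None,
    standardized=False,
) -> ModelingMatrix:
    """Assemble a ModelingMatrix directly for unit tests."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    p = X.shape[1]
    columns = tuple(columns) if columns is not None else tuple(f"x{j}" for j in range(p))
    kinds = tuple(kinds) if kinds is not None else ("microbial",) * p
    mm = ModelingMatrix(
        y=y, X=X, columns=columns, column_kind=kinds, group=group,
        family=family, response="ch4_production",
    )
    if standardized:
        mm, _ = standardize_train_apply_test(mm)
    return mm


@pytest.fixture
def toy_csv(tmp_path):
    """Two animals (one with 2 rounds, one with 1), two genus columns."""
    df = pd.DataFrame(
        {
            "animal_id": ["A1", "A1", "A2"],
            "round_index": [1, 2, 1],
            "ch4_production": [21.0, 22.5, 19.0],
            "ch4_yield": [15.0, 15.5, 14.0],
            "dmi": [1.4, 1.5, 1.3],
            "bw": [42.0, 43.0, 39.0],
            "ap_ratio": [3.1, 3.0, 2.8],
            "sex": ["F", "F", "M"],
            "breed": ["Romney", "Romney", "Texel"],
            "bacteria__Prevotella": [0.42, 0.40, 0.45],
            "archaea__Methanobrevibacter": [0.30, 0.28, 0.33],
        }
    )
    path = tmp_path / "toy.csv"
    df.to_csv(path, index=False)
    return path


SMALL_CONFIG = SyntheticConfig(
    n_animals=24,
    n_single_record_animals=4,
    n_bacteria=30,
    n_archaea=4,
    n_protozoa=3,
    n_fungi=3,
    n_causal_genera=3,
    seed=7,
)


@pytest.fixture(scope="session")
def small_data():
    return generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def study_data():
    """Study-shaped dataset (218 records, 330 genera) with ground truth."""
    return generate(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def study_matrix(study_data):
    table, truth = study_data
    mm = prepare_matrix(table, "ANIM-B")
    full_s, _ = standardize_train_apply_test(mm)
    return full_s, truth
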