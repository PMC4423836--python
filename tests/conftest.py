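import numpy as np
import pandas as pd
import pytest

from cohortnet.datamodel import CohortTable, VariableSpec


@pytest.fixture
def toy_cohort() -> CohortTable:
    """5 individuals, one continuous + one genotype variable, 3 cases."""
    values = pd.DataFrame(
        {
            "bmi": [21.0, 24.0, 27.0, 30.0, 33.0],
            "LIPC": [0, 1, 2, 1, 0],
        }
    )
    return CohortTable(
        individuals=[f"i{k}" for k in range(5)],
        variables=[VariableSpec("bmi", "continuous"), VariableSpec("LIPC", "genotype3")],
        values=values,
        outcome=np.array([1, 1, 1, 0, 0]),
    )


@pytest.fixture
def toy_csv(tmp_path):
    """Writes a small cohort CSV + schema and returns (csv, schema) paths."""
    import yaml

    csv = tmp_path / "cohort.csv"
    csv.write_text(
        "id,bmi,LIPC,outcome\n"
        "a,21.0,0,1\nb,24.0,1,1\nc,27.0,2,1\nd,30.0,1,0\ne,33.0,0,0\n"
    )
    schema = tmp_path / "schema.yaml"
    schema.write_text(
        yaml.safe_dump(
            {
                "outcome": "outcome",
                "variables": [
                    {"name": "bmi", "kind": "continuous"},
                    {"name": "LIPC", "kind": "genotype3"},
                ],
            }
        )
    )
    return csv, schema


def random_binary_matrix(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    """Random 0/1 matrix with no constant column."""
    X = (rng.random((n, d)) < rng.uniform(0.2, 0.8)).astype(float)
    for j in range(d):
        if X[:, j].min() == X[:, j].max():
            X[0, j] = 1 - X[0, j]
    return X
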