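import numpy as np
import pytest

from reode.model import ExpressionMatrix, IDEProfile, PairedCohort
from reode.pairs import find_stable_pairs
from reode.simulate import SimulationConfig, generate_dataset


@pytest.fixture
def toy_normals():
    """3-gene / 4-sample reference with the orderings used across tests.

    g1 = [10, 9, 8, 10], g2 = [5, 5, 4, 6], g3 = [7, 8, 9, 7]:
    support(g1 > g2) = 1.0, support(g1 > g3) = 3/4, support(g3 > g2) = 1.0.
    """
    return ExpressionMatrix(
        ["g1", "g2", "g3"],
        ["n1", "n2", "n3", "n4"],
        np.array([[10, 9, 8, 10], [5, 5, 4, 6], [7, 8, 9, 7]], dtype=float),
    )


@pytest.fixture
def profile_small():
    """4-gene / 4-sample ternary profile with known call counts."""
    calls = np.array([
        [1, 0, -1, -1],
        [0, 0, 0, 0],
        [1, 1, 0, 0],
        [-1, -1, -1, 0],
    ], dtype=np.int8)
    shape = calls.shape
    return IDEProfile(["g1", "g2", "g3", "g4"], ["s1", "s2", "s3", "s4"],
                      calls, np.full(shape, np.nan), np.full(shape, np.nan))


@pytest.fixture(scope="session")
def small_dataset():
    """Session-wide small synthetic dataset exercising every coupling."""
    cfg = SimulationConfig(n_genes=120, n_normals=30, n_tumors=80,
                           n_subtypes=2, subtype_genes_per_subtype=3,
                           n_prognostic_genes=4, n_drug_genes=2, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_pairs(small_dataset):
    return find_stable_pairs(small_dataset.normals, 0.99)


def make_cohort(gene_ids, normal_values, tumor_values):
    """Paired cohort helper: sample j of tumors pairs with sample j of normals."""
    normal_values = np.asarray(normal_values, dtype=float)
    tumor_values = np.asarray(tumor_values, dtype=float)
    n_n = normal_values.shape[1]
    n_t = tumor_values.shape[1]
    normals = ExpressionMatrix(gene_ids, [f"n{j}" for j in range(n_n)], normal_values)
    tumors = ExpressionMatrix(gene_ids, [f"t{j}" for j in range(n_t)], tumor_values)
    pairing = {f"t{j}": f"n{j}" for j in range(min(n_n, n_t))}
    return PairedCohort(normals, tumors, pairing)
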