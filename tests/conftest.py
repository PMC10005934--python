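import numpy as np
import pytest

from netcontrol.connectome import BinaryAdjacency, StructuralConnectome
from netcontrol.simulate import GeneratorConfig, generate_cohort


def make_connectome(counts, subject_id="sub", fa=None, rng=None):
    """Build a valid StructuralConnectome from a symmetric count matrix."""
    counts = np.asarray(counts, dtype=np.int64)
    n = counts.shape[0]
    if fa is None:
        rng = rng or np.random.default_rng(0)
        fa = np.zeros_like(counts, dtype=float)
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0.2, 0.8, len(iu[0]))
        fa[iu] = np.where(counts[iu] > 0, vals, 0.0)
        fa = fa + fa.T
    labels = tuple(f"r{i}" for i in range(n))
    return StructuralConnectome(subject_id, labels, counts, fa)


def random_adjacency(n, density, rng) -> BinaryAdjacency:
    iu = np.triu_indices(n, 1)
    upper = (rng.random(len(iu[0])) < density).astype(float)
    A = np.zeros((n, n))
    A[iu] = upper
    A = A + A.T
    return BinaryAdjacency(A=A, edge_count=int(upper.sum()), source_threshold=3)


@pytest.fixture(scope="session")
def ring2():
    """2-node single-edge graph: the closed-form reference system."""
    return BinaryAdjacency(
        A=np.array([[0.0, 1.0], [1.0, 0.0]]), edge_count=1, source_threshold=3
    )


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject, 30-node synthetic cohort shared by I/O and QC tests."""
    cfg = GeneratorConfig(n_nodes=30, n_hc=30, n_mdd=30, seed=11)
    return generate_cohort(cfg)
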