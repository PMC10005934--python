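"""Linear network controllability: average and modal, per node and whole brain.

The brain is modeled as a discrete, noise-free, linear time-invariant system

    x(k+1) = A x(k) + B u(k)

with A the (binary, symmetric) structural adjacency matrix, x the regional
activity vector and u the control input injected through B.  Controllability
from a node set K is certified by invertibility of the Gramian

    W_K = sum_{i>=0} A^i B_K B_K^T (A^T)^i ,

which converges only for Schur-stable A; the adjacency is therefore scaled by
1/(1 + sigma_max(A)) before any Gramian computation, the convention of the
structural-brain-controllability literature.  The recorded scaling factor is
per subject.

Two per-node metrics are computed with single-node input B = e_j:

* average controllability  AC_j = Tr(W_j): the node's capacity to push the
  network into many nearby states at low energy;
* modal controllability    MC_j = sum_n (1 - xi_n^2) v_nj^2 over the
  eigenpairs (xi_n, v_n) of the scaled A: the node's grip on fast-decaying,
  hard-to-reach modes.

For symmetric Schur-stable A both have closed forms through one
eigendecomposition (AC_j = sum_n v_nj^2 / (1 - xi_n^2)), which is what the
production path uses; the Lyapunov-equation solve and a truncated-series /
impulse-response simulator are kept as independent oracles.  Whole-brain
values are arithmetic means of the node vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .connectome import BinaryAdjacency

__all__ = [
    "LinearSystem",
    "StateTrajectory",
    "ControllabilityProfile",
    "normalize_system",
    "controllability_gramian",
    "gramian_series",
    "average_controllability",
    "modal_controllability",
    "whole_brain_controllability",
    "node_controllability",
    "simulate_dynamics",
    "controllability_table",
]


@dataclass(frozen=True)
class LinearSystem:
    """Schur-stable normalized system matrix with its scaling factor."""

    A_norm: np.ndarray
    normalization_factor: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "A_norm", np.asarray(self.A_norm, dtype=float))

    @property
    def N(self) -> int:
        return self.A_norm.shape[0]


@dataclass(frozen=True)
class StateTrajectory:
    """Exact rollout of x(k+1) = A x(k) + B u(k)."""

    states: np.ndarray  # (K+1, N)
    inputs: np.ndarray  # (K, m)
    input_matrix: np.ndarray  # (N, m)


@dataclass(frozen=True)
class ControllabilityProfile:
    """Per-node and whole-brain controllability for one subject."""

    subject_id: str
    avg_ctrl: np.ndarray
    modal_ctrl: np.ndarray
    whole_brain_avg: float
    whole_brain_modal: float
    edge_count: int
    normalization_factor: float


def normalize_system(adj: BinaryAdjacency) -> LinearSystem:
    """Scale the adjacency by 1/(1 + sigma_max) to guarantee Schur stability.

    sigma_max/(1 + sigma_max) < 1, so the spectral radius of the result is
    strictly below one for any input, including the empty graph (factor 1).
    """
    A = adj.A
    if adj.edge_count == 0:
        sigma = 0.0
    else:
        # symmetric matrix: largest singular value = max |eigenvalue|
        sigma = float(np.max(np.abs(scipy.linalg.eigvalsh(A))))
    factor = 1.0 + sigma
    return LinearSystem(A_norm=A / factor, normalization_factor=factor)


def controllability_gramian(sys: LinearSystem, j: int) -> np.ndarray:
    """Infinite-horizon Gramian for single-node input B = e_j.

    Solves the discrete Lyapunov equation W = A W A^T + e_j e_j^T exactly
    rather than truncating the series.
    """
    if not 0 <= j < sys.N:
        raise IndexError(f"node index {j} out of range for N={sys.N}")
    Q = np.zeros((sys.N, sys.N))
    Q[j, j] = 1.0
    return scipy.linalg.solve_discrete_lyapunov(sys.A_norm, Q)


def gramian_series(sys: LinearSystem, j: int, K: int) -> np.ndarray:
    """K-truncated Gramian series sum_{i=0..K} A^i e_j e_j^T (A^T)^i.

    Test oracle only; converges geometrically at rate rho(A_norm)^2.
    """
    N = sys.A_norm.shape[0]
    W = np.zeros((N, N))
    v = np.zeros(N)
    v[j] = 1.0
    for _ in range(K + 1):
        W += np.outer(v, v)
        v = sys.A_norm @ v
    return W


def _eig(sys: LinearSystem) -> tuple[np.ndarray, np.ndarray]:
    A = sys.A_norm
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("closed-form controllability requires symmetric A_norm")
    xi, V = np.linalg.eigh(A)
    if np.max(np.abs(xi)) >= 1.0:
        raise ValueError("system is not Schur stable")
    return xi, V


def average_controllability(sys: LinearSystem) -> np.ndarray:
    """AC_j = Tr(W_j) = sum_n v_nj^2 / (1 - xi_n^2) for every node j.

    Always >= 1 (the i=0 series term alone contributes 1); equals 1 exactly
    for isolated nodes.
    """
    xi, V = _eig(sys)
    return (V**2 / (1.0 - xi**2)).sum(axis=1)


def modal_controllability(sys: LinearSystem) -> np.ndarray:
    """MC_j = sum_n (1 - xi_n^2) v_nj^2 for every node j.

    Lies in (0, 1] for a symmetric Schur-stable system; eigenvector sign
    ambiguity is irrelevant because only v_nj^2 enters.
    """
    xi, V = _eig(sys)
    return (V**2 * (1.0 - xi**2)).sum(axis=1)


def whole_brain_controllability(
    avg_ctrl: np.ndarray, modal_ctrl: np.ndarray
) -> tuple[float, float]:
    """Whole-brain values: arithmetic means of the per-node vectors."""
    return float(np.mean(avg_ctrl)), float(np.mean(modal_ctrl))


def node_controllability(
    adj: BinaryAdjacency, subject_id: str = ""
) -> ControllabilityProfile:
    """Full per-subject profile: normalize, both node vectors, whole-brain."""
    sys = normalize_system(adj)
    ac = average_controllability(sys)
    mc = modal_controllability(sys)
    wb_avg, wb_modal = whole_brain_controllability(ac, mc)
    return ControllabilityProfile(
        subject_id=subject_id,
        avg_ctrl=ac,
        modal_ctrl=mc,
        whole_brain_avg=wb_avg,
        whole_brain_modal=wb_modal,
        edge_count=adj.edge_count,
        normalization_factor=sys.normalization_factor,
    )


def simulate_dynamics(
    sys: LinearSystem,
    B: np.ndarray,
    u: np.ndarray,
    x0: np.ndarray,
    K: int | None = None,
) -> StateTrajectory:
    """Roll out the recursion exactly for K steps (oracle, not pipeline)."""
    B = np.atleast_2d(np.asarray(B, dtype=float))
    u = np.atleast_2d(np.asarray(u, dtype=float))
    x0 = np.asarray(x0, dtype=float)
    if K is None:
        K = u.shape[0]
    if B.shape[0] != sys.N or x0.shape != (sys.N,):
        raise ValueError("B or x0 dimension does not match the system")
    if u.shape != (K, B.shape[1]):
        raise ValueError(f"input sequence must be ({K}, {B.shape[1]}), got {u.shape}")
    states = np.empty((K + 1, sys.N))
    states[0] = x0
    for k in range(K):
        states[k + 1] = sys.A_norm @ states[k] + B @ u[k]
    return StateTrajectory(states=states, inputs=u, input_matrix=B)


def controllability_table(
    profiles: list[ControllabilityProfile], node_labels: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """One row per subject: avg_ctrl_<region>, modal_ctrl_<region>, wb_*, ..."""
    rows = []
    for p in profiles:
        row: dict[str, float] = {}
        for lbl, v in zip(node_labels, p.avg_ctrl):
            row[f"avg_ctrl_{lbl}"] = v
        for lbl, v in zip(node_labels, p.modal_ctrl):
            row[f"modal_ctrl_{lbl}"] = v
        row["wb_avg"] = p.whole_brain_avg
        row["wb_modal"] = p.whole_brain_modal
        row["edge_count"] = p.edge_count
        row["norm_factor"] = p.normalization_factor
        rows.append(row)
    df = pd.DataFrame(rows, index=[p.subject_id for p in profiles])
    df.index.name = "subject_id"
    return df
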