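"""Subject-level structural connectome data model and I/O.

A structural connectome pairs two symmetric matrices over a fixed
parcellation: integer streamline counts from deterministic tractography and
fractional-anisotropy (FA) edge weights in [0, 1].  The system matrix used
for controllability analysis is the *binary* adjacency obtained by keeping
edges supported by at least ``min_streamlines`` streamlines (default 3).

Matrices travel either as plain delimited text (one file per subject per
weight type, comma or tab autodetected) or inside a single HDF5 container
with datasets ``counts/<subject_id>`` and ``fa/<subject_id>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np

__all__ = [
    "StructuralConnectome",
    "BinaryAdjacency",
    "load_connectome",
    "load_labels",
    "binarize",
    "edge_count",
    "save_cohort_h5",
    "load_cohort_h5",
    "DEFAULT_MIN_STREAMLINES",
]

#: Edge-inclusion rule: a connection must be supported by at least this many
#: tractography streamlines to count as present.
DEFAULT_MIN_STREAMLINES = 3

#: FA matrices are floating point; symmetry is checked to this tolerance.
FA_SYMMETRY_TOL = 1e-9


class ConnectomeError(ValueError):
    """Raised when a connectome violates its structural invariants."""


@dataclass(frozen=True)
class StructuralConnectome:
    """One subject's streamline-count and FA matrices over named nodes.

    Invariants (enforced by :meth:`validate`, called on construction):

    * both matrices are square, symmetric, with zero diagonal;
    * streamline counts are non-negative integers;
    * FA weights lie in [0, 1] and are nonzero only where counts are nonzero.
    """

    subject_id: str
    node_labels: tuple[str, ...]
    streamline_counts: np.ndarray
    fa_weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "streamline_counts", np.asarray(self.streamline_counts)
        )
        object.__setattr__(self, "fa_weights", np.asarray(self.fa_weights, dtype=float))
        object.__setattr__(self, "node_labels", tuple(self.node_labels))
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def validate(self) -> None:
        sc, fa = self.streamline_counts, self.fa_weights
        n = self.n_nodes
        if sc.shape != (n, n) or fa.shape != (n, n):
            raise ConnectomeError(
                f"{self.subject_id}: matrix shapes {sc.shape}/{fa.shape} "
                f"do not match {n} node labels"
            )
        if np.any(sc < 0):
            raise ConnectomeError(f"{self.subject_id}: negative streamline counts")
        if not np.array_equal(sc, np.round(sc)):
            raise ConnectomeError(f"{self.subject_id}: non-integer streamline counts")
        if not np.array_equal(sc, sc.T):
            raise ConnectomeError(f"{self.subject_id}: streamline matrix not symmetric")
        if np.any(np.diag(sc) != 0):
            raise ConnectomeError(f"{self.subject_id}: nonzero diagonal in counts")
        if not np.allclose(fa, fa.T, rtol=0.0, atol=FA_SYMMETRY_TOL):
            raise ConnectomeError(f"{self.subject_id}: FA matrix not symmetric")
        if np.any(np.diag(fa) != 0):
            raise ConnectomeError(f"{self.subject_id}: nonzero diagonal in FA")
        if np.any(fa < 0) or np.any(fa > 1):
            raise ConnectomeError(f"{self.subject_id}: FA outside [0, 1]")
        if np.any((fa != 0) & (sc == 0)):
            raise ConnectomeError(
                f"{self.subject_id}: FA nonzero where streamline count is zero"
            )


@dataclass(frozen=True)
class BinaryAdjacency:
    """Unweighted system matrix A after streamline-count thresholding."""

    A: np.ndarray
    edge_count: int
    source_threshold: int
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        if not np.isin(A, (0.0, 1.0)).all():
            raise ConnectomeError("adjacency entries must be 0 or 1")
        if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
            raise ConnectomeError("adjacency must be symmetric with zero diagonal")
        expected = int(np.triu(A, k=1).sum())
        if self.edge_count != expected:
            raise ConnectomeError(
                f"edge_count {self.edge_count} != upper-triangular sum {expected}"
            )

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


# ---------------------------------------------------------------------------
# I/O


def _read_matrix(path: str | Path) -> np.ndarray:
    """Read a square numeric matrix from delimited text (',' or whitespace)."""
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0] if path.stat().st_size else ""
    delim = "," if "," in first else None
    mat = np.loadtxt(path, delimiter=delim, ndmin=2)
    if mat.shape[0] != mat.shape[1]:
        raise ConnectomeError(f"{path}: matrix is {mat.shape}, expected square")
    return mat


def load_labels(path: str | Path) -> tuple[str, ...]:
    """Read node labels, one per line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return tuple(ln for ln in lines if ln)


def load_connectome(
    count_path: str | Path,
    fa_path: str | Path,
    labels: Sequence[str],
    subject_id: str | None = None,
) -> StructuralConnectome:
    """Load and validate one subject's connectome from delimited-text files.

    Symmetry and consistency are *checked*, never silently repaired: an
    asymmetric input is a data error upstream, not a formatting nuisance.
    """
    counts = _read_matrix(count_path)
    fa = _read_matrix(fa_path)
    if counts.shape != fa.shape:
        raise ConnectomeError(
            f"count matrix {counts.shape} and FA matrix {fa.shape} differ"
        )
    if counts.shape[0] != len(labels):
        raise ConnectomeError(
            f"matrix dimension {counts.shape[0]} does not match "
            f"{len(labels)} node labels"
        )
    sid = subject_id or Path(count_path).stem
    return StructuralConnectome(sid, tuple(labels), counts.astype(np.int64), fa)


def save_cohort_h5(
    path: str | Path,
    cohort: Iterable[StructuralConnectome],
    labels: Sequence[str] | None = None,
) -> None:
    """Write a cohort into one HDF5 container (datasets counts/<id>, fa/<id>)."""
    cohort = list(cohort)
    with h5py.File(path, "w") as f:
        if cohort:
            lbl = labels if labels is not None else cohort[0].node_labels
            f.create_dataset(
                "node_labels", data=np.array([s.encode() for s in lbl])
            )
        for sc in cohort:
            f.create_dataset(f"counts/{sc.subject_id}", data=sc.streamline_counts)
            f.create_dataset(f"fa/{sc.subject_id}", data=sc.fa_weights)


def load_cohort_h5(path: str | Path) -> list[StructuralConnectome]:
    """Load every subject from an HDF5 cohort container."""
    out: list[StructuralConnectome] = []
    with h5py.File(path, "r") as f:
        labels = tuple(s.decode() for s in f["node_labels"][()])
        for sid in f["counts"]:
            out.append(
                StructuralConnectome(
                    sid,
                    labels,
                    f[f"counts/{sid}"][()].astype(np.int64),
                    f[f"fa/{sid}"][()],
                )
            )
    return out


# ---------------------------------------------------------------------------
# Binarization


def binarize(
    sc: StructuralConnectome, min_streamlines: int = DEFAULT_MIN_STREAMLINES
) -> BinaryAdjacency:
    """Threshold streamline counts into the unweighted system matrix.

    An edge is present iff its streamline count is at least
    ``min_streamlines``; presence/absence is all the downstream dynamics see.
    """
    if min_streamlines < 1:
        raise ValueError(f"min_streamlines must be >= 1, got {min_streamlines}")
    A = (sc.streamline_counts >= min_streamlines).astype(float)
    np.fill_diagonal(A, 0.0)
    return BinaryAdjacency(
        A=A,
        edge_count=int(np.triu(A, k=1).sum()),
        source_threshold=int(min_streamlines),
        node_labels=sc.node_labels,
    )


def edge_count(adj: BinaryAdjacency) -> int:
    """Number of present (undirected) edges: 1-entries above the diagonal."""
    return int(np.triu(adj.A, k=1).sum())
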