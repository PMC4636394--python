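"""Spectral analysis of cluster adjacency matrices.

The dominant eigenvalue λ₁ of the adjacency matrix A measures the
interconnectedness of the lattice and sets the stability threshold of the
linearized contact-network dynamics (growth iff βλ₁ > δ). The dominant
eigenvector v̄₁ is the eigenvector-centrality map of the lattice: for a
connected cluster its entries are strictly positive and give each
channel's share of long lattice walks. Because every channel has at most
four neighbors, λ₁ < 4 for any cluster lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.csgraph

from .cluster_lattice import (
    AdjacencyMatrix,
    LatticeCluster,
    build_adjacency,
    connected_components,
    remove_channel,
)
from .errors import DisconnectedClusterError

__all__ = [
    "EigenDecomposition",
    "PerturbationScan",
    "eigendecompose",
    "dominant_eigenvalue",
    "walk_count",
    "perturbation_scan",
]

#: Two eigenvalues closer than this are treated as a degenerate block.
DEGENERACY_TOL = 1e-8


def _check_connected(a: np.ndarray) -> None:
    n_comp, _ = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(a), directed=False
    )
    if n_comp != 1:
        raise DisconnectedClusterError(
            f"adjacency matrix has {n_comp} components; analyze the largest "
            "component (connected_components(cluster)[0]) instead"
        )


@dataclass(frozen=True)
class EigenDecomposition:
    """Full symmetric eigendecomposition A = V D Vᵀ, eigenvalues descending.

    Column ``i`` of ``eigenvectors`` is the orthonormal eigenvector v̄_i of
    eigenvalue ``eigenvalues[i]``. Signs are fixed so each vector's entry
    sum is positive (first nonzero entry positive for zero-sum vectors),
    making centrality maps reproducible across platforms. ``degenerate[i]``
    flags membership in a repeated-eigenvalue block, within which
    individual eigenvectors are solver-dependent (their span is not).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    source_label: str = ""
    degenerate: np.ndarray = field(default=None)

    @property
    def n(self) -> int:
        return self.eigenvalues.size

    @property
    def lambda1(self) -> float:
        """Dominant eigenvalue λ₁ (spectral radius for connected clusters)."""
        return float(self.eigenvalues[0])

    @property
    def v1(self) -> np.ndarray:
        """Dominant eigenvector v̄₁ (eigenvector centrality)."""
        return self.eigenvectors[:, 0]

    def mode_overlaps(self) -> np.ndarray:
        """ūᵀv̄_i for every mode (ū the all-one vector)."""
        return self.eigenvectors.sum(axis=0)


def eigendecompose(a: AdjacencyMatrix) -> EigenDecomposition:
    """Eigendecompose a connected cluster's adjacency matrix.

    Raises
    ------
    DisconnectedClusterError
        If the matrix describes more than one component.
    """
    m = np.asarray(a.entries, dtype=float)
    _check_connected(m)
    vals, vecs = np.linalg.eigh(m)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # Sign convention: entry-sum positive; zero-sum -> first nonzero positive.
    for i in range(vals.size):
        s = vecs[:, i].sum()
        if abs(s) > 1e-9:
            if s < 0:
                vecs[:, i] = -vecs[:, i]
        else:
            nz = np.flatnonzero(np.abs(vecs[:, i]) > 1e-12)
            if nz.size and vecs[nz[0], i] < 0:
                vecs[:, i] = -vecs[:, i]
    degen = np.zeros(vals.size, dtype=bool)
    close = np.abs(np.diff(vals)) < DEGENERACY_TOL
    degen[:-1] |= close
    degen[1:] |= close
    return EigenDecomposition(
        eigenvalues=vals,
        eigenvectors=vecs,
        source_label=a.source_label,
        degenerate=degen,
    )


def dominant_eigenvalue(a: AdjacencyMatrix) -> float:
    """λ₁ of a connected cluster's adjacency matrix (< max degree ≤ 4)."""
    return eigendecompose(a).lambda1


def walk_count(a: AdjacencyMatrix, k: int) -> int:
    """Exact number of length-k walks on the lattice, W_k = ūᵀ A^k ū.

    Computed in arbitrary-precision integer arithmetic; for large k,
    W_k ≈ n λ₁^k up to the centrality factor (ūᵀv̄₁)²/n.
    """
    if k < 0:
        raise ValueError("walk length k must be >= 0")
    m = a.entries.astype(object)
    v = np.ones(a.n, dtype=object)
    for _ in range(k):
        v = m @ v
    return int(v.sum())


@dataclass(frozen=True)
class PerturbationScan:
    """Per-channel sensitivity of λ₁ to single-channel removal.

    ``records`` has one row per channel j of the baseline cluster with
    columns ``j, row, col, delta_lambda1, centrality, disconnects``:
    Δλ₁ = λ₁(cluster minus j) − λ₁(cluster) (strictly negative), the
    baseline centrality (v̄₁)_j, and whether the removal disconnects the
    lattice (Δλ₁ then refers to the largest remaining component).
    """

    records: pd.DataFrame
    lambda1_baseline: float
    source_label: str = ""

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def perturbation_scan(cluster: LatticeCluster) -> PerturbationScan:
    """Remove each channel in turn and record the change in λ₁."""
    if cluster.n < 3:
        raise ValueError("perturbation scan requires n >= 3")
    a = build_adjacency(cluster)
    base = eigendecompose(a)
    rows = []
    for j in range(cluster.n):
        reduced, disconnected = remove_channel(cluster, j)
        if disconnected:
            reduced = connected_components(reduced)[0]
        lam = dominant_eigenvalue(build_adjacency(reduced))
        rows.append(
            {
                "j": j,
                "row": cluster.sites[j][0],
                "col": cluster.sites[j][1],
                "delta_lambda1": lam - base.lambda1,
                "centrality": base.v1[j],
                "disconnects": disconnected,
            }
        )
    return PerturbationScan(
        records=pd.DataFrame(rows),
        lambda1_baseline=base.lambda1,
        source_label=cluster.label,
    )
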