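"""Two-dimensional channel cluster lattices and their adjacency matrices.

A cluster is a set of channels occupying distinct sites of an integer grid
(one channel per site, ~31 nm center-to-center spacing for RyR2). Channels
interact only with their four nearest lattice neighbors; diagonal contacts
are deliberately excluded, so every channel has degree at most 4. The
ordered site list fixes the channel indexing used by every downstream
matrix and vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import scipy.io
import scipy.sparse

from .errors import (
    ClusterFormatError,
    DuplicateSiteError,
    EmptyClusterError,
)

__all__ = [
    "LatticeCluster",
    "AdjacencyMatrix",
    "RemovalResult",
    "ThresholdResult",
    "load_cluster",
    "save_cluster",
    "build_adjacency",
    "connected_components",
    "remove_channel",
    "generate_rect_lattice",
    "generate_random_cluster",
    "generate_dumbbell_cluster",
    "threshold_image_to_lattice",
]

#: The four nearest-neighbor offsets of the square lattice.
NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))

DEFAULT_SPACING_NM = 31.0


@dataclass(frozen=True)
class LatticeCluster:
    """A connected-or-not set of channels on an integer grid.

    Parameters
    ----------
    sites
        Ordered ``(row, col)`` integer coordinates, one per channel. The
        order defines channel indices ``0..n-1`` for all derived matrices.
    spacing_nm
        Center-to-center channel spacing in nanometers (default 31, the
        packed RyR2 lattice constant).
    label
        Free-text identifier carried through to derived objects.
    """

    sites: tuple[tuple[int, int], ...]
    spacing_nm: float = DEFAULT_SPACING_NM
    label: str = ""

    def __post_init__(self):
        sites = tuple((int(r), int(c)) for r, c in self.sites)
        object.__setattr__(self, "sites", sites)
        if len(sites) == 0:
            raise EmptyClusterError("a cluster must contain at least one channel")
        seen = set()
        for s in sites:
            if s in seen:
                raise DuplicateSiteError(s)
            seen.add(s)
        if self.spacing_nm <= 0:
            raise ValueError("spacing_nm must be positive")

    @property
    def n(self) -> int:
        """Number of channels."""
        return len(self.sites)

    def site_index(self) -> dict[tuple[int, int], int]:
        """Map site -> channel index."""
        return {s: i for i, s in enumerate(self.sites)}

    def as_array(self) -> np.ndarray:
        """(n, 2) integer array of (row, col) coordinates."""
        return np.asarray(self.sites, dtype=np.int64)

    def degrees(self) -> np.ndarray:
        """4-neighborhood degree of every channel."""
        occupied = set(self.sites)
        return np.array(
            [
                sum((r + dr, c + dc) in occupied for dr, dc in NEIGHBOR_OFFSETS)
                for r, c in self.sites
            ],
            dtype=np.int64,
        )

    def with_label(self, label: str) -> "LatticeCluster":
        return replace(self, label=label)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric 0/1 nearest-neighbor contact matrix of a cluster."""

    entries: np.ndarray
    source_label: str = ""

    def __post_init__(self):
        a = np.asarray(self.entries, dtype=np.int8)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency matrix must be square")
        object.__setattr__(self, "entries", a)

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def degrees(self) -> np.ndarray:
        return self.entries.sum(axis=1)

    def neighbor_lists(self) -> tuple[tuple[int, ...], ...]:
        """Per-channel tuples of neighbor indices (for simulation loops)."""
        return tuple(
            tuple(int(j) for j in np.flatnonzero(row)) for row in self.entries
        )

    def to_matrix_market(self, path) -> None:
        """Write the matrix in Matrix Market coordinate format."""
        scipy.io.mmwrite(
            str(path),
            scipy.sparse.coo_matrix(self.entries),
            comment=f"adjacency of {self.source_label}" if self.source_label else "",
            field="integer",
        )


class RemovalResult(NamedTuple):
    """Result of deleting one channel from a cluster."""

    cluster: LatticeCluster
    disconnected: bool


class ThresholdResult(NamedTuple):
    """Result of reconstructing a lattice from an intensity image."""

    cluster: LatticeCluster          # largest connected component
    n_components: int                # number of components found
    n_occupied: int                  # occupied bins before component extraction


# ---------------------------------------------------------------------------
# construction & I/O

def build_adjacency(cluster: LatticeCluster) -> AdjacencyMatrix:
    """Build the n x n 0/1 adjacency matrix under the 4-neighborhood rule.

    ``A[i, j] = 1`` iff sites i and j differ by exactly one grid step
    horizontally or vertically. Diagonal neighbors are not connected.
    """
    n = cluster.n
    index = cluster.site_index()
    a = np.zeros((n, n), dtype=np.int8)
    for i, (r, c) in enumerate(cluster.sites):
        for dr, dc in NEIGHBOR_OFFSETS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                a[i, j] = 1
    return AdjacencyMatrix(a, source_label=cluster.label)


def load_cluster(
    path,
    dialect: str = "csv-rowcol",
    units: str = "lattice",
    spacing_nm: float = DEFAULT_SPACING_NM,
    label: str | None = None,
) -> LatticeCluster:
    """Read a cluster from a CSV coordinate file.

    The dialect is one channel per line, ``row,col``, with an optional
    ``row,col`` header. Record order defines channel index order.

    Parameters
    ----------
    units
        ``"lattice"`` (default): coordinates are integer lattice sites.
        ``"nm"``: coordinates are physical positions in nanometers and are
        mapped to lattice sites by dividing by ``spacing_nm`` and rounding.
    """
    if dialect != "csv-rowcol":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if lines and lines[0].replace(" ", "").lower() == "row,col":
        lines = lines[1:]
    if not lines:
        raise EmptyClusterError(f"{path}: no coordinate records")
    sites = []
    for lineno, ln in enumerate(lines, start=1):
        parts = ln.split(",")
        if len(parts) != 2:
            raise ClusterFormatError(f"{path}:{lineno}: expected 'row,col', got {ln!r}")
        try:
            if units == "lattice":
                r, c = int(parts[0]), int(parts[1])
            elif units == "nm":
                r = int(round(float(parts[0]) / spacing_nm))
                c = int(round(float(parts[1]) / spacing_nm))
            else:
                raise ValueError(f"unknown units {units!r}")
        except ValueError as exc:
            raise ClusterFormatError(f"{path}:{lineno}: {exc}") from exc
        site = (r, c)
        if site in set(sites):
            raise DuplicateSiteError(site)
        sites.append(site)

    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return LatticeCluster(
        sites=tuple(sites),
        spacing_nm=float(meta.get("spacing_nm", spacing_nm)),
        label=label if label is not None else meta.get("label", path.stem),
    )


def save_cluster(cluster: LatticeCluster, path, sidecar: bool = True) -> None:
    """Write a cluster as a ``row,col`` CSV plus a JSON metadata sidecar."""
    path = Path(path)
    lines = ["row,col"] + [f"{r},{c}" for r, c in cluster.sites]
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        meta = {"label": cluster.label, "spacing_nm": cluster.spacing_nm}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# topology

def _component_labels(cluster: LatticeCluster) -> np.ndarray:
    a = build_adjacency(cluster).entries
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        scipy.sparse.csr_matrix(a), directed=False
    )
    return labels


def is_connected(cluster: LatticeCluster) -> bool:
    return cluster.n == 1 or len(set(_component_labels(cluster))) == 1


def connected_components(cluster: LatticeCluster) -> list[LatticeCluster]:
    """Partition a cluster into maximal 4-connected components.

    Components are ordered largest first; ties broken by the smallest
    member site in row-major order. Within each component the original
    relative site order (hence channel-index order) is preserved.
    """
    labels = _component_labels(cluster)
    groups: dict[int, list[tuple[int, int]]] = {}
    for site, lab in zip(cluster.sites, labels):
        groups.setdefault(int(lab), []).append(site)
    comps = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    return [
        LatticeCluster(tuple(g), cluster.spacing_nm, f"{cluster.label}#{k}")
        for k, g in enumerate(comps)
    ]


def remove_channel(cluster: LatticeCluster, j: int) -> RemovalResult:
    """Delete channel ``j``; report whether the remainder is disconnected.

    Indices above ``j`` shift down by one in the returned cluster.
    """
    if cluster.n < 2:
        raise EmptyClusterError("cannot remove the only channel of a cluster")
    if not 0 <= j < cluster.n:
        raise IndexError(f"channel index {j} out of range for n={cluster.n}")
    sites = cluster.sites[:j] + cluster.sites[j + 1 :]
    out = LatticeCluster(sites, cluster.spacing_nm, cluster.label)
    return RemovalResult(out, disconnected=not is_connected(out))


# ---------------------------------------------------------------------------
# generators

def generate_rect_lattice(
    rows: int, cols: int, spacing_nm: float = DEFAULT_SPACING_NM, label: str | None = None
) -> LatticeCluster:
    """Full rows x cols block in row-major channel order."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    sites = tuple((r, c) for r in range(rows) for c in range(cols))
    return LatticeCluster(sites, spacing_nm, label or f"rect{rows}x{cols}")


def generate_random_cluster(
    n: int,
    seed,
    spacing_nm: float = DEFAULT_SPACING_NM,
    label: str | None = None,
) -> LatticeCluster:
    """Connected random cluster of exactly ``n`` sites by seeded accretion.

    Starting at the origin, repeatedly add a uniformly random empty site
    adjacent to the current cluster. Bit-reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sites = [(0, 0)]
    occupied = {(0, 0)}
    # Insertion-ordered frontier of empty neighbor sites.
    frontier: dict[tuple[int, int], None] = {}

    def extend_frontier(site):
        r, c = site
        for dr, dc in NEIGHBOR_OFFSETS:
            s = (r + dr, c + dc)
            if s not in occupied:
                frontier[s] = None

    extend_frontier((0, 0))
    while len(sites) < n:
        keys = list(frontier)
        pick = keys[int(rng.integers(len(keys)))]
        del frontier[pick]
        occupied.add(pick)
        sites.append(pick)
        extend_frontier(pick)
    return LatticeCluster(
        tuple(sites), spacing_nm, label or f"random-n{n}-seed{seed}"
    )


def generate_dumbbell_cluster(
    block: int,
    bridge_len: int,
    bridge_width: int,
    block2: int | None = None,
    spacing_nm: float = DEFAULT_SPACING_NM,
    label: str | None = None,
) -> LatticeCluster:
    """Two square blocks joined by a narrow neck.

    Emulates dumbbell-like cluster morphologies in which a bottleneck
    separates two functional subdomains. ``block2`` sets the second
    lobe's side (default: same as ``block``). Total size is
    ``block**2 + block2**2 + bridge_len*bridge_width``.

    Note that with equal lobes the cluster has a mirror symmetry, which
    forces the subdomain-splitting eigenmode to be odd (zero overlap
    with the all-one vector): its contribution to the open-channel
    expectation then vanishes exactly. Unequal lobes break the symmetry,
    localize the two leading eigenmodes on the two lobes, and give both
    a finite contribution — the regime in which subdomains are visible
    in the eigenmode weights.
    """
    if block2 is None:
        block2 = block
    if block < 2 or block2 < 2:
        raise ValueError("block sides must be >= 2")
    if bridge_len < 1 or bridge_width < 1:
        raise ValueError("bridge dimensions must be >= 1")
    if bridge_width > min(block, block2):
        raise ValueError("bridge_width cannot exceed the smaller block")
    sites = []
    for r in range(block):
        for c in range(block):
            sites.append((r, c))
    r0 = (block - bridge_width) // 2
    for r in range(r0, r0 + bridge_width):
        for c in range(block, block + bridge_len):
            sites.append((r, c))
    for r in range(block2):
        for c in range(block + bridge_len, block + bridge_len + block2):
            sites.append((r, c))
    return LatticeCluster(
        tuple(sites),
        spacing_nm,
        label or f"dumbbell{block}-{block2}-{bridge_len}x{bridge_width}",
    )


# ---------------------------------------------------------------------------
# image reconstruction

def threshold_image_to_lattice(
    image,
    percentile: float = 95.0,
    spacing_px: int = 1,
    pooling: str = "max",
    spacing_nm: float = DEFAULT_SPACING_NM,
    label: str = "image",
) -> ThresholdResult:
    """Reconstruct a channel lattice from a 2-D intensity image.

    The percentile threshold is computed uniformly over *all* pixels of
    the image (background included). The image is partitioned into
    ``spacing_px x spacing_px`` bins; a bin becomes an occupied lattice
    site iff its pooled intensity is at or above the threshold ("at or
    above": ties are occupied). The largest 4-connected component is
    returned along with a component count.

    Parameters
    ----------
    pooling
        ``"max"`` (default, robust to sub-bin point placement) or
        ``"mean"``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    if spacing_px < 1:
        raise ValueError("spacing_px must be >= 1")
    thresh = np.percentile(img, percentile)

    nr = -(-img.shape[0] // spacing_px)
    nc = -(-img.shape[1] // spacing_px)
    pad_r = nr * spacing_px - img.shape[0]
    pad_c = nc * spacing_px - img.shape[1]
    pad_value = -np.inf if pooling == "max" else np.nan
    padded = np.pad(img, ((0, pad_r), (0, pad_c)), constant_values=pad_value)
    blocks = padded.reshape(nr, spacing_px, nc, spacing_px)
    if pooling == "max":
        pooled = blocks.max(axis=(1, 3))
    elif pooling == "mean":
        pooled = np.nanmean(blocks, axis=(1, 3))
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    rows, cols = np.nonzero(pooled >= thresh)
    if rows.size == 0:
        raise EmptyClusterError("no image bin at or above the threshold")
    occupied = LatticeCluster(
        tuple(zip(rows.tolist(), cols.tolist())), spacing_nm, label
    )
    comps = connected_components(occupied)
    return ThresholdResult(
        cluster=comps[0].with_label(label),
        n_components=len(comps),
        n_occupied=occupied.n,
    )
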