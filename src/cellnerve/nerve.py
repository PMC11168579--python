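"""The nerve simplicial complex of a labeled segmentation.

The nerve encodes how a tessellated object is assembled from its cells: each
cell is a vertex, and every set of k+1 cells with a non-empty common
intersection is a (k)-simplex — two intersecting cells form an edge, three a
triangle, four a tetrahedron, and so on.  The 1-skeleton of the nerve is the
unweighted region adjacency graph; the higher simplices add the lower-
dimensional face information needed to describe the polyhedral structure of
each cell.  For a Voronoi tessellation of generic points the nerve is the
Delaunay triangulation.

On a hard voxel segmentation each voxel carries exactly one label, so "cells
with a common intersection" is read on the dual grid: every 2×2×2 block of
voxels (2×2 for single-slice volumes) samples a point where up to eight cell
closures meet, and the set of distinct labels in the block spans a simplex.
This block construction reproduces the Delaunay triangulation on voxelized
Voronoi tessellations whose features are coarser than the voxel size.
"""

from __future__ import annotations

import itertools
import json
from collections.abc import Iterable, Iterator
from pathlib import Path

import networkx as nx
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import LabeledVolume

__all__ = [
    "Nerve",
    "build_nerve",
    "adjacency_graph",
    "vertex_star",
    "face_vector",
    "simplex_counts",
]

Simplex = frozenset  # frozenset[int]: a set of k+1 cell labels is a k-simplex


class Nerve:
    """A finite abstract simplicial complex over integer cell labels.

    The constructor takes any iterable of label sets and closes it downward,
    so every non-empty subset of a simplex is itself a simplex.
    """

    def __init__(self, simplices: Iterable[Iterable[int]]):
        closed: set[frozenset[int]] = set()
        for s in simplices:
            fs = frozenset(int(x) for x in s)
            if not fs:
                raise ValueError("empty simplex")
            if fs in closed:
                continue
            t = tuple(sorted(fs))
            for k in range(1, len(t) + 1):
                for comb in itertools.combinations(t, k):
                    closed.add(frozenset(comb))
        self._simplices: frozenset[frozenset[int]] = frozenset(closed)
        self._stars: dict[int, frozenset[frozenset[int]]] | None = None

    # -- basic accessors -------------------------------------------------

    @property
    def simplices(self) -> frozenset[frozenset[int]]:
        return self._simplices

    @property
    def vertices(self) -> frozenset[int]:
        return frozenset(next(iter(s)) for s in self._simplices if len(s) == 1)

    @property
    def dim(self) -> int:
        return max(len(s) for s in self._simplices) - 1

    def __len__(self) -> int:
        return len(self._simplices)

    def __contains__(self, s: Iterable[int]) -> bool:
        return frozenset(s) in self._simplices

    def __iter__(self) -> Iterator[frozenset[int]]:
        return iter(self._simplices)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Nerve) and self._simplices == other._simplices

    def __hash__(self) -> int:
        return hash(self._simplices)

    def __repr__(self) -> str:
        return f"Nerve({self.simplex_counts()})"

    # -- stars and face-vectors ------------------------------------------

    def _star_index(self) -> dict[int, frozenset[frozenset[int]]]:
        if self._stars is None:
            acc: dict[int, list[frozenset[int]]] = {}
            for s in self._simplices:
                for v in s:
                    acc.setdefault(v, []).append(s)
            self._stars = {v: frozenset(ss) for v, ss in acc.items()}
        return self._stars

    def vertex_star(self, cell: int) -> frozenset[frozenset[int]]:
        """All simplices containing ``cell`` (including the vertex itself)."""
        stars = self._star_index()
        if cell not in stars:
            raise KeyError(f"cell {cell} is not a vertex of this nerve")
        return stars[cell]

    def face_vector(self, cell: int) -> tuple[int, ...]:
        """Counts of k-simplices in the vertex star of ``cell``, per k.

        For a simple polyhedral cell the vector reads (1, faces, edges,
        vertices) of its polyhedron; trailing zeros are trimmed.
        """
        star = self.vertex_star(cell)
        counts = [0] * (max(len(s) for s in star))
        for s in star:
            counts[len(s) - 1] += 1
        while len(counts) > 1 and counts[-1] == 0:
            counts.pop()
        return tuple(counts)

    def simplex_counts(self) -> tuple[int, ...]:
        """Number of k-simplices for each k = 0 .. dim."""
        counts = [0] * (self.dim + 1)
        for s in self._simplices:
            counts[len(s) - 1] += 1
        return tuple(counts)

    def edges(self) -> frozenset[frozenset[int]]:
        return frozenset(s for s in self._simplices if len(s) == 2)

    # -- derived structures ----------------------------------------------

    def restrict(self, cells: Iterable[int]) -> "Nerve":
        """Full subcomplex on the given cells."""
        keep = frozenset(int(c) for c in cells)
        sub = [s for s in self._simplices if s <= keep]
        if not sub:
            raise ValueError("restriction is empty")
        return Nerve(sub)

    def relabel(self, mapping: dict[int, int]) -> "Nerve":
        """Apply a label bijection to every simplex."""
        return Nerve([frozenset(mapping[v] for v in s) for s in self._simplices])

    def to_networkx(self) -> nx.Graph:
        """The region adjacency graph (1-skeleton) as a networkx graph."""
        g = nx.Graph()
        g.add_nodes_from(sorted(self.vertices))
        g.add_edges_from(tuple(sorted(e)) for e in self.edges())
        return g

    # -- serialization ----------------------------------------------------

    def to_list(self) -> list[list[int]]:
        """Deterministic listing: by dimension, then lexicographically."""
        return sorted((sorted(s) for s in self._simplices), key=lambda t: (len(t), t))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"simplices": self.to_list()}))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Nerve":
        data = json.loads(Path(path).read_text())
        return cls(data["simplices"])


def _block_label_sets(labels: np.ndarray, background: frozenset[int]) -> set[frozenset[int]]:
    """Distinct label sets of all 2-windows of the grid (dual-grid sampling).

    Axes of extent 1 use window length 1, so single-slice volumes reduce to
    the planar 2×2 construction.
    """
    window = tuple(min(2, s) for s in labels.shape)
    flat = sliding_window_view(labels, window).reshape(-1, int(np.prod(window)))
    flat = np.sort(flat, axis=1)
    uniq = np.unique(flat, axis=0)
    out: set[frozenset[int]] = set()
    for row in uniq:
        s = frozenset(int(x) for x in row) - background
        if s:
            out.add(s)
    return out


def _face_adjacent_pairs(labels: np.ndarray, background: frozenset[int]) -> set[frozenset[int]]:
    """Unordered pairs of distinct non-background labels sharing a voxel face."""
    bg = np.asarray(sorted(background), dtype=labels.dtype)
    pairs: set[frozenset[int]] = set()
    for ax in range(labels.ndim):
        a = labels[tuple(slice(None, -1) if i == ax else slice(None) for i in range(labels.ndim))]
        b = labels[tuple(slice(1, None) if i == ax else slice(None) for i in range(labels.ndim))]
        mask = (a != b) & ~np.isin(a, bg) & ~np.isin(b, bg)
        if not mask.any():
            continue
        stacked = np.sort(np.stack([a[mask], b[mask]], axis=1), axis=1)
        for row in np.unique(stacked, axis=0):
            pairs.add(frozenset(int(x) for x in row))
    return pairs


def build_nerve(vol: LabeledVolume, scheme: str = "block2") -> Nerve:
    """Build the nerve of a labeled volume.

    Parameters
    ----------
    vol
        The segmentation.  Voxel spacing is irrelevant: the nerve is an
        abstract complex and anisotropy does not change which cells meet.
    scheme
        ``"block2"`` (default): every 2×2×2 voxel block contributes the
        simplex spanned by its distinct non-background labels, capturing all
        higher-order intersections.  Note that two cells meeting only at a
        grid corner do count as intersecting under this scheme.
        ``"pairwise_face"``: only vertices plus edges between cells sharing
        a voxel face (6-connectivity) — the unweighted region adjacency
        graph, with no simplices above dimension 1.
    """
    labels = vol.labels
    cells = vol.cell_labels()
    if cells.size == 0:
        raise ValueError("volume is entirely background; the nerve is empty")
    if scheme == "block2":
        maximal = _block_label_sets(labels, vol.background)
    elif scheme == "pairwise_face":
        maximal = _face_adjacent_pairs(labels, vol.background)
        maximal |= {frozenset((int(c),)) for c in cells}
    else:
        raise ValueError(f"unknown nerve scheme {scheme!r}")
    return Nerve(maximal)


def adjacency_graph(nerve: Nerve) -> frozenset[frozenset[int]]:
    """The edge set (1-simplices) of the nerve: the region adjacency graph."""
    return nerve.edges()


def vertex_star(nerve: Nerve, cell: int) -> frozenset[frozenset[int]]:
    """All simplices of ``nerve`` containing ``cell``."""
    return nerve.vertex_star(cell)


def face_vector(nerve: Nerve, cell: int) -> tuple[int, ...]:
    """The face-vector of ``cell``: per-dimension simplex counts of its star."""
    return nerve.face_vector(cell)


def simplex_counts(nerve: Nerve) -> tuple[int, ...]:
    """Per-dimension simplex counts of the whole complex."""
    return nerve.simplex_counts()
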