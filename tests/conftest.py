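"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: walk
enumeration is a literal recursive traversal, and liminal volumes are counted
by expanding voxel coordinate sets step by step in pure Python.
"""

from __future__ import annotations

import itertools
from typing import Dict, Set, Tuple

import numpy as np
import pytest

from sementropy import LabeledVolume, PhantomSpec, TaggedGraph, generate_phantom

# ---------------------------------------------------------------------------
# graphs


@pytest.fixture
def triangle_graph() -> TaggedGraph:
    return TaggedGraph([1, 2, 3], [(1, 2), (2, 3), (1, 3)], {1: "a", 2: "a", 3: "b"})


@pytest.fixture
def single_edge_graph() -> TaggedGraph:
    return TaggedGraph([1, 2], [(1, 2)], {1: "a", 2: "b"})


def brute_force_walk_distribution(graph: TaggedGraph, n: int) -> Dict[Tuple, float]:
    """Literal recursive enumeration of all ordered walks of n edges."""
    adj: Dict = {v: sorted(graph.neighbours(v), key=repr) for v in graph.vertices}
    sequences: Dict[Tuple, int] = {}
    total = 0

    def walk(v, remaining: int, seq: Tuple) -> None:
        nonlocal total
        if remaining == 0:
            sequences[seq] = sequences.get(seq, 0) + 1
            total += 1
            return
        for u in adj[v]:
            walk(u, remaining - 1, seq + (graph.tag_of[u],))

    for v in sorted(graph.vertices, key=repr):
        walk(v, n, (graph.tag_of[v],))
    if total == 0:
        raise ValueError("no walks")
    return {s: c / total for s, c in sequences.items()}


def random_tagged_graph(rng: np.random.Generator, max_vertices: int = 8) -> TaggedGraph:
    n = int(rng.integers(2, max_vertices + 1))
    verts = list(range(n))
    pairs = list(itertools.combinations(verts, 2))
    keep = [p for p in pairs if rng.random() < 0.5]
    if not keep:  # ensure at least one edge so walks exist
        keep = [pairs[int(rng.integers(len(pairs)))]]
    tags = ["a", "b", "c"]
    tag_of = {v: tags[int(rng.integers(3))] for v in verts}
    return TaggedGraph(verts, keep, tag_of)


# ---------------------------------------------------------------------------
# volumes


@pytest.fixture
def slab_volume() -> LabeledVolume:
    """4x4x4 unit cube split into two 2-voxel slabs A|B along x."""
    return generate_phantom(PhantomSpec(kind="halves", shape=(4, 4, 4)))


@pytest.fixture
def thin_plane_volume() -> LabeledVolume:
    """4x4x4 cube with A = the x=0 plane (16 voxels) and B = the rest (48)."""
    labels = np.full((4, 4, 4), 2, dtype=np.int32)
    labels[:, :, 0] = 1
    return LabeledVolume(labels, tag_map={1: "A", 2: "B"})


@pytest.fixture
def two_island_volume() -> LabeledVolume:
    """Two tags separated by background: disconnected adjacency graph."""
    labels = np.zeros((4, 4, 8), dtype=np.int32)
    labels[:, :, 0:2] = 1
    labels[:, :, 6:8] = 2
    return LabeledVolume(labels, tag_map={1: "A", 2: "B"})


@pytest.fixture
def stripe3_volume() -> LabeledVolume:
    """Three 1-voxel stripes A|B|C along x (B adjacent to both, A-C not)."""
    labels = np.zeros((2, 2, 3), dtype=np.int32)
    labels[:, :, 0], labels[:, :, 1], labels[:, :, 2] = 1, 2, 3
    return LabeledVolume(labels, tag_map={1: "A", 2: "B", 3: "C"})


_OFFSETS = {
    "face": [o for o in itertools.product((-1, 0, 1), repeat=3)
             if sum(map(abs, o)) == 1],
    "edge": [o for o in itertools.product((-1, 0, 1), repeat=3)
             if 1 <= sum(map(abs, o)) <= 2],
    "vertex": [o for o in itertools.product((-1, 0, 1), repeat=3)
               if any(o)],
}


def brute_force_liminal(
    vol: LabeledVolume, k: int = 1, connectivity: str = "face"
) -> Tuple[list, np.ndarray]:
    """Liminal volumes by explicit voxel-set expansion (no scipy).

    Returns (tags, v) on retained tags, with the same diagonal rule as the
    library (volume minus off-diagonal sum, clamped at 0).
    """
    vv = vol.voxel_volume
    counts: Dict[str, int] = {}
    coords: Dict[str, Set[Tuple[int, int, int]]] = {}
    for label, tag in vol.tag_map.items():
        where = np.argwhere(vol.labels == label)
        coords.setdefault(tag, set()).update(map(tuple, where))
        counts[tag] = counts.get(tag, 0) + len(where)
    tags = [t for t in counts if counts[t] > 0]
    shape = vol.labels.shape
    offsets = _OFFSETS[connectivity]

    def dilate(cells: Set[Tuple[int, int, int]], steps: int) -> Set:
        out = set(cells)
        frontier = set(cells)
        for _ in range(steps):
            new = set()
            for (z, y, x) in frontier:
                for dz, dy, dx in offsets:
                    c = (z + dz, y + dy, x + dx)
                    if (0 <= c[0] < shape[0] and 0 <= c[1] < shape[1]
                            and 0 <= c[2] < shape[2] and c not in out):
                        new.add(c)
            out |= new
            frontier = new
        return out

    m = len(tags)
    v = np.zeros((m, m))
    for j, tj in enumerate(tags):
        dil = dilate(coords[tj], k)
        for i, ti in enumerate(tags):
            if i != j:
                v[i, j] = len(coords[ti] & dil) * vv
    for i, ti in enumerate(tags):
        v[i, i] = max(counts[ti] * vv - v[i].sum(), 0.0)
    return tags, v
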