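"""Path Entropy on tagged graphs.

A tagged graph G = (V, E, C, chi) carries a tag (tissue identity, colour) on
every vertex.  The order-n Path Entropy is the Shannon entropy of the
distribution of tag sequences read off all walks of n edges; at n = 0 it
reduces to the standard entropy of the tag histogram (image entropy when the
graph is a pixel lattice).  Walks are ordered and may revisit vertices:
every undirected edge yields two directed steps, and immediate back-tracking
(u -> v -> u) counts as a distinct walk.

Enumeration is exact and intended for small graphs and small orders; a guard
refuses instances whose total walk count exceeds a configurable cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Set, Tuple

import numpy as np

from sementropy.errors import EmptyGraphError, InstanceTooLargeError, NoPathsError

#: Default maximum number of walks an exact enumeration will attempt.
DEFAULT_WALK_CAP = 10**7


@dataclass(frozen=True)
class TaggedGraph:
    """Undirected graph with a total tag assignment on its vertices.

    Parameters
    ----------
    vertices :
        Vertex identifiers (hashable; typically ints or strings).
    edges :
        Unordered vertex pairs. Self-edges are rejected unless
        ``allow_self_loops`` is set.
    tag_of :
        Map from every vertex to its tag name (the function chi).
    allow_self_loops :
        Permit edges (v, v). Off by default.
    """

    vertices: FrozenSet
    edges: FrozenSet[FrozenSet]
    tag_of: Mapping
    allow_self_loops: bool = False

    def __init__(
        self,
        vertices: Iterable,
        edges: Iterable[Tuple],
        tag_of: Mapping,
        allow_self_loops: bool = False,
    ) -> None:
        vs = frozenset(vertices)
        es = set()
        for u, v in edges:
            if u == v and not allow_self_loops:
                raise ValueError(f"self-edge at vertex {u!r} (allow_self_loops=False)")
            if u not in vs or v not in vs:
                raise ValueError(f"edge ({u!r}, {v!r}) has an endpoint that is not a vertex")
            es.add(frozenset((u, v)))
        missing = vs - set(tag_of)
        if missing:
            raise ValueError(f"tag_of is not total: missing {sorted(map(repr, missing))}")
        object.__setattr__(self, "vertices", vs)
        object.__setattr__(self, "edges", frozenset(es))
        object.__setattr__(self, "tag_of", dict(tag_of))
        object.__setattr__(self, "allow_self_loops", allow_self_loops)

    @property
    def tags(self) -> Set:
        """The tag set C (tags actually carried by vertices)."""
        return {self.tag_of[v] for v in self.vertices}

    def neighbours(self, v) -> Set:
        out = set()
        for e in self.edges:
            pair = tuple(e)
            if len(pair) == 1:  # self-loop
                if pair[0] == v:
                    out.add(v)
            elif v in pair:
                out.add(pair[0] if pair[1] == v else pair[1])
        return out


@dataclass
class TagSequenceDistribution:
    """Distribution of tag sequences over all walks of a fixed length.

    ``probs`` maps each length-(order+1) tuple of tags to the fraction of
    walks realising it; fractions sum to 1 whenever any walk exists.
    """

    order: int
    probs: Dict[Tuple, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.probs:
            if len(s) != self.order + 1:
                raise ValueError(f"key {s!r} has length {len(s)}, expected {self.order + 1}")

    def entropy(self, log_base: float = 2.0) -> float:
        return _shannon(list(self.probs.values()), log_base)


def _shannon(probs, log_base: float) -> float:
    p = np.asarray(probs, dtype=float)
    p = p[p > 0]
    return float(-(p * (np.log(p) / math.log(log_base))).sum()) if p.size else 0.0


def tag_distribution(graph: TaggedGraph) -> Dict:
    """Fraction of vertices carrying each tag (the order-0 distribution)."""
    if not graph.vertices:
        raise EmptyGraphError("empty graph")
    n = len(graph.vertices)
    counts: Dict = {}
    for v in graph.vertices:
        t = graph.tag_of[v]
        counts[t] = counts.get(t, 0) + 1
    return {t: c / n for t, c in counts.items()}


def _adjacency(graph: TaggedGraph):
    verts = sorted(graph.vertices, key=repr)
    index = {v: i for i, v in enumerate(verts)}
    a = np.zeros((len(verts), len(verts)), dtype=np.int64)
    for e in graph.edges:
        pair = tuple(e)
        if len(pair) == 1:
            a[index[pair[0]], index[pair[0]]] = 1
        else:
            a[index[pair[0]], index[pair[1]]] = 1
            a[index[pair[1]], index[pair[0]]] = 1
    return verts, a


def count_walks(graph: TaggedGraph, n: int) -> int:
    """Total number of ordered walks of n edges (exact integer count)."""
    if not graph.vertices:
        raise EmptyGraphError("empty graph")
    _, a = _adjacency(graph)
    total = np.ones(len(a), dtype=object)
    for _ in range(n):
        total = a.astype(object) @ total
    return int(total.sum())


def enumerate_path_distribution(
    graph: TaggedGraph, n: int, walk_cap: int = DEFAULT_WALK_CAP
) -> TagSequenceDistribution:
    """Exact distribution of tag sequences over all walks of ``n`` edges.

    Walks are ordered sequences of n+1 vertices joined by edges; vertices may
    repeat. The order-0 result equals :func:`tag_distribution`.

    Raises
    ------
    NoPathsError
        If no walk of length ``n`` exists (e.g. edgeless graph, n >= 1).
    InstanceTooLargeError
        If the exact walk count would exceed ``walk_cap``.
    """
    if n < 0:
        raise ValueError("order n must be >= 0")
    if not graph.vertices:
        raise EmptyGraphError("empty graph")
    total_walks = count_walks(graph, n)
    if total_walks == 0:
        raise NoPathsError("no paths of requested length")
    if total_walks > walk_cap:
        raise InstanceTooLargeError(
            f"instance too large: {total_walks} walks exceeds cap {walk_cap}"
        )

    verts, a = _adjacency(graph)
    tags = [graph.tag_of[v] for v in verts]
    # DP over (tag sequence, ending vertex) -> exact walk count.
    state: Dict[Tuple, np.ndarray] = {}
    for i, t in enumerate(tags):
        vec = state.setdefault((t,), np.zeros(len(verts), dtype=object))
        vec[i] = 1
    for _ in range(n):
        nxt: Dict[Tuple, np.ndarray] = {}
        for seq, vec in state.items():
            ext = vec @ a.astype(object)  # walks ending at each vertex after one more step
            for j in np.nonzero(ext)[0]:
                key = seq + (tags[j],)
                tgt = nxt.setdefault(key, np.zeros(len(verts), dtype=object))
                tgt[j] += ext[j]
        state = nxt
    probs = {seq: int(vec.sum()) / total_walks for seq, vec in state.items() if vec.sum() > 0}
    return TagSequenceDistribution(order=n, probs=probs)


def path_entropy(
    graph: TaggedGraph,
    n: int,
    log_base: float = 2.0,
    walk_cap: int = DEFAULT_WALK_CAP,
) -> float:
    """Order-n Path Entropy: Shannon entropy of the tag-sequence distribution.

    E_n = -sum_s p_n(s) log p_n(s), with 0 log 0 = 0. Non-negative, bounded by
    (n+1) log|C|, invariant under tag renaming.
    """
    return enumerate_path_distribution(graph, n, walk_cap=walk_cap).entropy(log_base)
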