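"""Geometry layer: per-tag volumes, liminal volumes, transition matrix.

A :class:`LabeledVolume` is a 3D integer label array (0 = background, never a
region) with per-axis voxel spacing and a tag map.  The notional particle's
transition probabilities between tags are estimated from *liminal volumes*:
the part of region i reachable by a particle crossing from region j, computed
as the intersection of region i with the k-step morphological dilation of
region j.  Rows of the resulting table, normalized, give a row-stochastic
matrix Q with q_ij = P(tag i -> tag j per step); the volume fractions give
the initial distribution p0.

Conventions (documented contract):

- arrays are indexed (z, y, x), 0-based; volumes on disk are taken as-is;
- volumes are physical (voxel count x product of spacings); dilation is
  lattice-step-based regardless of anisotropy;
- background voxels never contribute: dilations are intersected with tagged
  regions only, so a particle cannot step into background;
- tags with zero volume are dropped (with a warning) before any matrix is
  built -- zero-volume elements indicate defective input data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy import ndimage

from sementropy.errors import NoTaggedVoxelsError

#: connectivity name -> scipy connectivity rank for generate_binary_structure
_CONNECTIVITY_RANK = {"face": 1, "edge": 2, "vertex": 3}


@dataclass
class LabeledVolume:
    """3D voxel grid of non-negative integer labels with spacing and tag map.

    Parameters
    ----------
    labels :
        (z, y, x) array of non-negative integers; 0 is background.
    spacing :
        Per-axis voxel edge lengths, all > 0. Default isotropic 1.0.
    tag_map :
        Map label id -> tag name; must cover every non-zero label present.
    """

    labels: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    tag_map: Dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths")
        self.tag_map = {int(k): str(v) for k, v in self.tag_map.items()}
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.tag_map)
        if missing:
            raise ValueError(f"labels without tag_map entry: {sorted(missing)}")

    @property
    def voxel_volume(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(self.labels.copy(), self.spacing, dict(self.tag_map))


@dataclass
class LiminalVolumeTable:
    """Matrix v of region self/liminal volumes.

    ``v[i, j]`` for i != j is the liminal volume of tag i toward tag j (the
    part of region i inside the k-dilation of region j); ``v[i, i]`` is the
    retained interior volume. For thin regions the off-diagonal sum can exceed
    the region volume (liminal zones toward different neighbours overlap); the
    diagonal is then clamped at 0 and the tag recorded in ``clamped``.
    """

    tags: List[str]
    v: np.ndarray
    clamped: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (len(self.tags), len(self.tags)):
            raise ValueError("v must be square with one row per tag")
        if (self.v < 0).any():
            raise ValueError("liminal volumes must be non-negative")


@dataclass
class TransitionModel:
    """Row-stochastic tag-to-tag transition matrix with initial distribution.

    ``Q[i, j]`` is the probability that the notional particle steps from tag
    ``tags[i]`` to tag ``tags[j]``; ``p0`` holds the volume fractions of the
    same (retained, positive-volume) tags. Distributions propagate as
    ``p_n = p0 @ Q**n``.
    """

    tags: List[str]
    Q: np.ndarray
    p0: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        m = len(self.tags)
        if self.Q.shape != (m, m):
            raise ValueError("Q must be square with one row per tag")
        if self.p0.shape != (m,):
            raise ValueError("p0 must have one entry per tag")
        if (self.Q < 0).any() or (self.p0 < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each row of Q must sum to 1")
        if not np.isclose(self.p0.sum(), 1.0, atol=1e-12):
            raise ValueError("p0 must sum to 1")

    @property
    def m(self) -> int:
        return len(self.tags)


def structuring_element(connectivity: str = "face") -> np.ndarray:
    """3x3x3 structuring element: face (6), edge (18) or vertex (26) neighbours."""
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError(
            f"unknown connectivity {connectivity!r}; expected face|edge|vertex"
        ) from None
    return ndimage.generate_binary_structure(3, rank)


def region_volumes(vol: LabeledVolume) -> Dict[str, float]:
    """Physical volume of each tag (voxel count x voxel volume).

    Tags listed in the tag map but absent from the array are reported with
    volume 0.0 and a warning.
    """
    if not (vol.labels > 0).any():
        raise NoTaggedVoxelsError("no tagged voxels")
    vv = vol.voxel_volume
    counts = np.bincount(vol.labels.ravel())
    out: Dict[str, float] = {}
    for label, tag in vol.tag_map.items():
        n = int(counts[label]) if label < counts.size else 0
        if n == 0:
            warnings.warn(f"tag {tag!r} (label {label}) has zero volume", stacklevel=2)
        out[tag] = out.get(tag, 0.0) + n * vv
    return out


def initial_distribution(volumes: Mapping[str, float]) -> Tuple[List[str], np.ndarray]:
    """Volume-fraction distribution over tags, dropping zero-volume tags.

    Returns the retained tag list (input order) and their fractions. Dropped
    tags are reported via a warning; zero-volume elements indicate a defect in
    the underlying data rather than real anatomy.
    """
    retained = [t for t, v in volumes.items() if v > 0]
    dropped = [t for t, v in volumes.items() if v <= 0]
    if not retained:
        raise NoTaggedVoxelsError("no tag has positive volume")
    if dropped:
        warnings.warn(f"dropping zero-volume tags: {dropped}", stacklevel=2)
    p = np.array([volumes[t] for t in retained], dtype=float)
    return retained, p / p.sum()


def liminal_volumes(
    vol: LabeledVolume, k: int = 1, connectivity: str = "face"
) -> LiminalVolumeTable:
    """Liminal-volume table v_ij from k-step dilation of each region.

    For each ordered pair i != j, v_ij is the physical volume of
    region_i intersected with the k-step dilation of region_j using the chosen
    structuring element; v_ii is volume(i) minus the off-diagonal row sum,
    clamped at 0 (clamped tags recorded). Zero-volume tags are dropped first.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise ValueError("dilation amount k must be an integer")
    if k < 1:
        raise ValueError("dilation amount k must be >= 1")
    vols = region_volumes(vol)
    tags, _ = initial_distribution(vols)
    struct = structuring_element(connectivity)
    vv = vol.voxel_volume
    label_of = {}
    for label, tag in vol.tag_map.items():
        label_of.setdefault(tag, []).append(label)

    masks = {t: np.isin(vol.labels, label_of[t]) for t in tags}
    m = len(tags)
    v = np.zeros((m, m), dtype=float)
    clamped: Set[str] = set()
    dilated = {
        t: ndimage.binary_dilation(masks[t], structure=struct, iterations=k) for t in tags
    }
    for i, ti in enumerate(tags):
        for j, tj in enumerate(tags):
            if i == j:
                continue
            v[i, j] = int(np.count_nonzero(masks[ti] & dilated[tj])) * vv
        interior = vols[ti] - v[i].sum()
        if interior < 0:
            clamped.add(ti)
            warnings.warn(
                f"tag {ti!r}: liminal volumes exceed region volume; "
                "interior clamped to 0",
                stacklevel=2,
            )
            interior = 0.0
        v[i, i] = interior
    return LiminalVolumeTable(tags=tags, v=v, clamped=clamped)


def transition_matrix(
    table: LiminalVolumeTable, volumes: Mapping[str, float] | None = None
) -> TransitionModel:
    """Row-normalize the liminal-volume table into a stochastic matrix.

    q_ij = v_ij / sum_j v_ij. ``p0`` holds the volume fractions of the same
    tags; if per-tag volumes are not supplied they are reconstructed from the
    row sums of unclamped rows (exact whenever no tag was clamped) -- callers
    with access to the volume should pass ``volumes``.
    """
    row_sums = table.v.sum(axis=1)
    for tag, s in zip(table.tags, row_sums):
        if s <= 0:
            raise ValueError(f"row for tag {tag!r} sums to 0; cannot normalize")
    q = table.v / row_sums[:, None]
    if volumes is not None:
        p = np.array([volumes[t] for t in table.tags], dtype=float)
    else:
        p = row_sums.astype(float)
    return TransitionModel(tags=list(table.tags), Q=q, p0=p / p.sum())


def adjacency_components(model: TransitionModel) -> List[Set[str]]:
    """Strongly connected components of the positive-entry digraph of Q.

    The chain is irreducible (a necessary condition for ergodicity) exactly
    when there is a single component; disconnected anatomical islands show up
    as multiple components.
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(model.m))
    for i in range(model.m):
        for j in range(model.m):
            if i != j and model.Q[i, j] > 0:
                g.add_edge(i, j)
    return [
        {model.tags[i] for i in comp} for comp in nx.strongly_connected_components(g)
    ]


def _positive_digraph(model: TransitionModel) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(model.m))
    for i in range(model.m):
        for j in range(model.m):
            if model.Q[i, j] > 0:
                g.add_edge(i, j)
    return g


def is_aperiodic(model: TransitionModel) -> bool:
    """True when the chain's period is 1 (positive diagonal suffices)."""
    if np.any(np.diag(model.Q) > 0):
        return True
    return nx.is_aperiodic(_positive_digraph(model))


def merge_tags(
    vol: LabeledVolume, groups: Sequence[Iterable[str]]
) -> LabeledVolume:
    """Merge each group of tags into a single freshly labeled region.

    Voxels of all tags in a group receive one new label whose tag name is the
    '+'-joined sorted member names (spatial union of the member regions).
    Tags in no group are preserved. Groups must be disjoint and name existing
    tags.
    """
    group_sets: List[FrozenSet[str]] = [frozenset(g) for g in groups]
    seen: Set[str] = set()
    known = set(vol.tag_map.values())
    for g in group_sets:
        unknown = g - known
        if unknown:
            raise ValueError(f"unknown tags in merge group: {sorted(unknown)}")
        if g & seen:
            raise ValueError(f"overlapping merge groups at {sorted(g & seen)}")
        seen |= g
    tag_labels: Dict[str, List[int]] = {}
    for label, tag in vol.tag_map.items():
        tag_labels.setdefault(tag, []).append(label)

    new_labels = np.zeros_like(vol.labels)
    new_map: Dict[int, str] = {}
    next_label = 1
    for g in group_sets:
        members = sorted(g)
        src = [l for t in members for l in tag_labels[t]]
        new_labels[np.isin(vol.labels, src)] = next_label
        new_map[next_label] = "+".join(members)
        next_label += 1
    for tag in sorted(known - seen):
        src = tag_labels[tag]
        new_labels[np.isin(vol.labels, src)] = next_label
        new_map[next_label] = tag
        next_label += 1
    return LabeledVolume(new_labels, vol.spacing, new_map)
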