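"""Synthetic labeled-volume phantoms and a Monte-Carlo walker oracle.

Phantoms emulate tagged anatomical volumes with known geometry: two half
slabs, striped or checkerboard 50/50 interdigitations, a thin shell around a
core, and seeded Voronoi tessellations (the stand-in for a many-tissue
embryo model). The walker ensemble samples the tag-level chain (p0, Q)
directly, giving an estimate of the occupancy distribution that is
independent of any eigen-solver and so serves as an oracle for the matrix
computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from sementropy.geometry import (
    LabeledVolume,
    TransitionModel,
    liminal_volumes,
    region_volumes,
    transition_matrix,
)

_KINDS = ("halves", "stripes", "checkerboard", "thin_shell", "voronoi")


@dataclass
class PhantomSpec:
    """Specification of a synthetic phantom.

    kind-specific ``params``: ``period`` (stripes/checkerboard, default 1),
    ``m`` (voronoi seed count), ``thickness`` (thin_shell, default 1).
    ``seed`` only matters for voronoi.
    """

    kind: str
    shape: Tuple[int, int, int] = (8, 8, 8)
    params: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; expected one of {_KINDS}")
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 2 for s in self.shape):
            raise ValueError("shape must be three extents, all >= 2")


def generate_phantom(spec: PhantomSpec) -> LabeledVolume:
    """Deterministically build the phantom described by ``spec``."""
    z, y, x = spec.shape
    if spec.kind == "halves":
        labels = np.ones(spec.shape, dtype=np.int32)
        labels[:, :, x // 2 :] = 2
        return LabeledVolume(labels, tag_map={1: "A", 2: "B"})
    if spec.kind == "stripes":
        period = int(spec.params.get("period", 1))
        if period < 1 or 2 * period > x:
            raise ValueError("stripe period infeasible for shape")
        xs = np.arange(x)
        labels = np.broadcast_to((xs // period) % 2 + 1, spec.shape).astype(np.int32).copy()
        return LabeledVolume(labels, tag_map={1: "A", 2: "B"})
    if spec.kind == "checkerboard":
        period = int(spec.params.get("period", 1))
        if period < 1:
            raise ValueError("checkerboard period must be >= 1")
        zz, yy, xx = np.meshgrid(
            np.arange(z) // period, np.arange(y) // period, np.arange(x) // period,
            indexing="ij",
        )
        labels = ((zz + yy + xx) % 2 + 1).astype(np.int32)
        return LabeledVolume(labels, tag_map={1: "A", 2: "B"})
    if spec.kind == "thin_shell":
        t = int(spec.params.get("thickness", 1))
        if 2 * t >= min(spec.shape):
            raise ValueError("shell thickness infeasible for shape")
        labels = np.ones(spec.shape, dtype=np.int32)  # shell
        labels[t : z - t, t : y - t, t : x - t] = 2  # core
        return LabeledVolume(labels, tag_map={1: "shell", 2: "core"})
    # voronoi
    m = int(spec.params.get("m", 8))
    n_vox = z * y * x
    if m < 2 or m > n_vox:
        raise ValueError("voronoi m must be >= 2 and <= total voxels")
    rng = np.random.default_rng(spec.seed)
    grid = np.stack(
        np.meshgrid(np.arange(z), np.arange(y), np.arange(x), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    for _ in range(100):
        flat = rng.choice(n_vox, size=m, replace=False)
        seeds = grid[flat]
        d2 = ((grid[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        if len(np.unique(assign)) == m:
            labels = (assign + 1).reshape(spec.shape).astype(np.int32)
            return LabeledVolume(labels, tag_map={i + 1: f"T{i + 1:03d}" for i in range(m)})
    raise ValueError("could not seed a voronoi phantom with all tags non-empty")


def equal_slabs(m: int, shape: Tuple[int, int, int]) -> LabeledVolume:
    """m equal-volume slabs along the first axis (shape[0] must divide by m)."""
    z = shape[0]
    if m < 1 or z % m:
        raise ValueError("first extent must be a positive multiple of m")
    labels = np.zeros(shape, dtype=np.int32)
    step = z // m
    for i in range(m):
        labels[i * step : (i + 1) * step] = i + 1
    return LabeledVolume(labels, tag_map={i + 1: chr(ord("A") + i) for i in range(m)})


@dataclass
class WalkerEnsemble:
    """Occupancy history of an ensemble of tag-level random walkers.

    ``occupancy[n]`` maps tag -> fraction of walkers in that tag after n
    steps (n = 0 is the empirical draw from p0); each row sums to 1.
    """

    tags: List[str]
    n_walkers: int
    n_steps: int
    seed: int
    occupancy: List[Dict[str, float]]
    sequences: Optional[np.ndarray] = None


def simulate_walkers(
    vol: LabeledVolume,
    k: int = 1,
    connectivity: str = "face",
    n_walkers: int = 10**5,
    n_steps: int = 16,
    seed: int = 0,
    model: Optional[TransitionModel] = None,
    keep_sequences: int = 0,
) -> WalkerEnsemble:
    """Sample ``n_walkers`` independent walkers on the tag-level chain.

    Walkers start in tags drawn from p0 and step i -> j with probability
    Q[i, j]; the per-step occupancy histogram estimates p0 @ Q^n with binomial
    standard error sqrt(p(1-p)/n_walkers) per tag. Fully reproducible given
    ``seed``. Pass ``model`` to reuse a prebuilt transition model.
    """
    if n_walkers < 1:
        raise ValueError("n_walkers must be >= 1")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if model is None:
        volumes = region_volumes(vol)
        model = transition_matrix(
            liminal_volumes(vol, k=k, connectivity=connectivity), volumes=volumes
        )
    rng = np.random.default_rng(seed)
    m = model.m
    states = rng.choice(m, size=n_walkers, p=model.p0)
    cum_q = np.cumsum(model.Q, axis=1)
    cum_q[:, -1] = 1.0  # guard against float shortfall in the last column

    history = np.empty((n_steps + 1, n_walkers), dtype=np.int64) if keep_sequences else None
    occupancy: List[Dict[str, float]] = []

    def record(s: np.ndarray, step: int) -> None:
        frac = np.bincount(s, minlength=m) / n_walkers
        occupancy.append({t: float(f) for t, f in zip(model.tags, frac)})
        if history is not None:
            history[step] = s

    record(states, 0)
    for step in range(1, n_steps + 1):
        u = rng.random(n_walkers)
        states = (u[:, None] > cum_q[states]).sum(axis=1)
        record(states, step)

    sequences = None
    if keep_sequences:
        sequences = history[:, : min(keep_sequences, n_walkers)].T.copy()
    return WalkerEnsemble(
        tags=list(model.tags),
        n_walkers=n_walkers,
        n_steps=n_steps,
        seed=seed,
        occupancy=occupancy,
        sequences=sequences,
    )
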