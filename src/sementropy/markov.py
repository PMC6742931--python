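"""Entropy of a tag-level Markov chain: order-n, stationary, normalized.

The order-n Structural Entropy is the Shannon entropy of the particle's
tag-occupancy distribution after n steps, p_n = p0 @ Q^n; at n = 0 this is the
entropy of the volume fractions alone.  For an ergodic chain (irreducible and
aperiodic) the occupancy converges to the unique stationary distribution pi
solving pi = pi Q, whose entropy is the Stationary Structural Entropy.
Entropies are normalized by E_max = log(m), m the number of retained
(positive-volume) tags, mapping all values into [0, 1]: 0 is maximal
structure, 1 maximal disorder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.linalg

from sementropy.errors import NonErgodicError
from sementropy.geometry import (
    LabeledVolume,
    TransitionModel,
    adjacency_components,
    is_aperiodic,
    liminal_volumes,
    region_volumes,
    transition_matrix,
)

DEFAULT_ORDERS = (0, 1, 2, 4, 8)


def _shannon(p: np.ndarray, log_base: float) -> float:
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-(p * (np.log(p) / math.log(log_base))).sum()) if p.size else 0.0


@dataclass
class EntropyReport:
    """All entropy values for one model: per-order, stationary, normalized.

    ``stationary`` is None when the chain is not ergodic (disconnected or
    periodic adjacency), mirroring the exclusion of such models rather than
    silently failing. ``normalized`` maps 'E0', 'E1', ... and 'Epi' to values
    in [0, 1]; the normalizing constant is ``e_max = log(m)``.
    """

    tags: List[str]
    m: int
    orders: Dict[int, float]
    stationary: Optional[float]
    e_max: float
    normalized: Dict[str, float]
    log_base: float
    non_ergodic_reason: Optional[str] = None
    dropped_tags: List[str] = field(default_factory=list)
    clamped_tags: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tags": self.tags,
            "m": self.m,
            "orders": {str(n): e for n, e in self.orders.items()},
            "stationary": self.stationary,
            "e_max": self.e_max,
            "normalized": dict(self.normalized),
            "log_base": self.log_base,
            "non_ergodic_reason": self.non_ergodic_reason,
            "dropped_tags": self.dropped_tags,
            "clamped_tags": self.clamped_tags,
        }


def structural_entropy(model: TransitionModel, n: int, log_base: float = 2.0) -> float:
    """Order-n Structural Entropy: entropy of the occupancy after n steps.

    E_n = H(p0 @ Q^n); E_0 is the entropy of the volume-fraction distribution.
    """
    if n < 0:
        raise ValueError("order n must be >= 0")
    d = model.p0 @ np.linalg.matrix_power(model.Q, n)
    return _shannon(d, log_base)


def stationary_distribution(
    model: TransitionModel, tol: float = 1e-12, max_iter: int = 10**6
) -> np.ndarray:
    """Unique stationary distribution pi with pi = pi Q, for ergodic chains.

    Solved via the dominant left eigenvector of Q, with deterministic power
    iteration from p0 as a fallback; the result satisfies
    ``norm(pi @ Q - pi, 1) <= tol``.

    Raises
    ------
    NonErgodicError
        'non-ergodic: disconnected regions' when the positive-entry digraph
        has multiple strongly connected components, or
        'non-ergodic: periodic' when the single component has period > 1.
    """
    comps = adjacency_components(model)
    if len(comps) != 1:
        raise NonErgodicError("non-ergodic: disconnected regions")
    if not is_aperiodic(model):
        raise NonErgodicError("non-ergodic: periodic")

    w, vl = scipy.linalg.eig(model.Q, left=True, right=False)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.abs(np.real(vl[:, idx]))
    if pi.sum() == 0:
        pi = model.p0.copy()
    else:
        pi = pi / pi.sum()
    # polish with power iterations: contracts any eigen-solver residue onto
    # the fixed point (bit-exact on symmetric worked phantoms)
    for _ in range(max_iter):
        nxt = pi @ model.Q
        done = np.array_equal(nxt, pi) or np.linalg.norm(nxt - pi, 1) <= tol
        pi = nxt
        if done:
            s = pi.sum()
            if s != 1.0:
                pi = pi / s
            return pi
    raise NonErgodicError(
        f"power iteration did not converge within {max_iter} iterations"
    )


def stationary_entropy(pi: np.ndarray, log_base: float = 2.0) -> float:
    """Stationary Structural Entropy E_pi = -sum_i pi_i log pi_i."""
    pi = np.asarray(pi, dtype=float)
    if (pi < 0).any() or not np.isclose(pi.sum(), 1.0, atol=1e-9):
        raise ValueError("pi must be a probability distribution")
    return _shannon(pi, log_base)


def max_entropy(m: int, log_base: float = 2.0) -> float:
    """E_max = log(m): entropy of m tags in an arbitrarily fine random jumble."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return math.log(m) / math.log(log_base)


def normalized_entropy(e: float, e_max: float) -> float:
    """Normalized entropy e / e_max in [0, 1]; 0 = maximal structure.

    A single-tag model has e_max = 0 and returns 0 by convention (with a
    warning). Values exceeding e_max by more than float slop (1e-9) indicate
    a bug and raise.
    """
    if e < 0 or e_max < 0:
        raise ValueError("entropies must be non-negative")
    if e_max == 0:
        if e > 1e-9:
            raise ValueError(f"entropy {e} > e_max 0")
        warnings.warn(
            "single-tag model: normalized entropy is 0 by convention", stacklevel=2
        )
        return 0.0
    r = e / e_max
    if r > 1.0 + 1e-9:
        raise ValueError(f"normalized entropy {r} exceeds 1 beyond tolerance")
    return min(r, 1.0)


def full_report(
    vol: LabeledVolume,
    k: int = 1,
    connectivity: str = "face",
    orders: Sequence[int] = DEFAULT_ORDERS,
    log_base: float = 2.0,
    tol: float = 1e-12,
    max_iter: int = 10**6,
) -> EntropyReport:
    """End-to-end entropy report for a labeled volume.

    Drops zero-volume tags, builds the liminal-volume table and transition
    model, computes E_n for the requested orders, attempts the stationary
    entropy (absent with a recorded reason when the chain is not ergodic),
    and normalizes everything by log(m) where m counts retained tags.
    """
    volumes = region_volumes(vol)
    dropped = [t for t, v in volumes.items() if v <= 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = liminal_volumes(vol, k=k, connectivity=connectivity)
        model = transition_matrix(table, volumes=volumes)
    e_orders = {int(n): structural_entropy(model, int(n), log_base) for n in orders}
    non_ergodic_reason = None
    e_pi: Optional[float] = None
    try:
        pi = stationary_distribution(model, tol=tol, max_iter=max_iter)
        e_pi = stationary_entropy(pi, log_base)
    except NonErgodicError as exc:
        non_ergodic_reason = str(exc)
    e_max = max_entropy(model.m, log_base)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalized = {f"E{n}": normalized_entropy(e, e_max) for n, e in e_orders.items()}
        if e_pi is not None:
            normalized["Epi"] = normalized_entropy(e_pi, e_max)
    return EntropyReport(
        tags=list(model.tags),
        m=model.m,
        orders=e_orders,
        stationary=e_pi,
        e_max=e_max,
        normalized=normalized,
        log_base=log_base,
        non_ergodic_reason=non_ergodic_reason,
        dropped_tags=dropped,
        clamped_tags=sorted(table.clamped),
    )
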