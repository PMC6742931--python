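"""Random-merge robustness experiment.

To check how strongly the entropy measures depend on the absolute number of
tagged elements, adjacent elements are merged at random -- in pairs, triples
or quadruples ("depth" 2, 3, 4) -- and the normalized entropies of each merged
model are recomputed. Trials are binned by resulting element count and the
Pearson correlation between entropy and element count is reported; a weak
correlation indicates the measure is robust to the granularity of tagging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from sementropy.geometry import (
    LabeledVolume,
    TransitionModel,
    liminal_volumes,
    merge_tags,
    region_volumes,
    transition_matrix,
)
from sementropy.markov import full_report


@dataclass
class MergeTrialResult:
    """Outcome of one random merge + entropy recomputation."""

    depth: int
    replicate: int
    seed: int
    element_count: int
    e0_norm: float
    epi_norm: Optional[float]  # None when the merged model is non-ergodic


@dataclass
class MergeExperimentSummary:
    """Binned statistics and entropy-vs-element-count correlations.

    ``bins`` rows are (lo, hi, n_trials, mean_e0, sd_e0, mean_epi, sd_epi)
    over disjoint element-count intervals [lo, hi) of fixed width aligned to
    multiples of the width. Correlations are Pearson r across all trials
    (None, with a warning, when degenerate).
    """

    bin_width: int
    bins: List[Dict] = field(default_factory=list)
    correlation_e0: Optional[float] = None
    correlation_epi: Optional[float] = None


def random_merge(
    vol: LabeledVolume, model: TransitionModel, depth: int, seed: int
) -> LabeledVolume:
    """One seeded sweep of random merges of adjacent tags.

    Iterates the tags in a seeded-shuffled order; each not-yet-consumed tag
    draws up to ``depth - 1`` of its adjacent (positive off-diagonal Q entry,
    either direction), not-yet-consumed neighbours uniformly at random and the
    group is merged. Groups never chain within a sweep; tags with no free
    neighbour remain singletons. Deterministic given ``seed``.
    """
    if depth not in (2, 3, 4):
        raise ValueError("depth must be 2, 3 or 4")
    rng = np.random.default_rng(seed)
    tags = list(model.tags)
    adj = {
        t: {
            tags[j]
            for j in range(model.m)
            if j != i and (model.Q[i, j] > 0 or model.Q[j, i] > 0)
        }
        for i, t in enumerate(tags)
    }
    order = list(tags)
    rng.shuffle(order)
    consumed: set = set()
    groups: List[List[str]] = []
    for t in order:
        if t in consumed:
            continue
        consumed.add(t)
        free = sorted(adj[t] - consumed)
        n_pick = min(depth - 1, len(free))
        group = [t]
        if n_pick:
            picks = rng.choice(len(free), size=n_pick, replace=False)
            group += [free[i] for i in picks]
            consumed.update(group)
        groups.append(group)
    merge_groups = [g for g in groups if len(g) > 1]
    if not merge_groups:
        return vol.copy()
    return merge_tags(vol, merge_groups)


def _binned(
    counts: np.ndarray, e0: np.ndarray, epi: np.ndarray, width: int
) -> List[Dict]:
    lo = int(width * np.floor(counts.min() / width))
    hi = int(width * np.floor(counts.max() / width)) + width
    out = []
    for start in range(lo, hi, width):
        sel = (counts >= start) & (counts < start + width)
        if not sel.any():
            continue
        epi_sel = epi[sel]
        epi_ok = epi_sel[~np.isnan(epi_sel)]
        out.append(
            {
                "lo": start,
                "hi": start + width,
                "n_trials": int(sel.sum()),
                "mean_e0": float(e0[sel].mean()),
                "sd_e0": float(e0[sel].std(ddof=1)) if sel.sum() > 1 else 0.0,
                "mean_epi": float(epi_ok.mean()) if epi_ok.size else None,
                "sd_epi": float(epi_ok.std(ddof=1)) if epi_ok.size > 1 else 0.0,
            }
        )
    return out


def _pearson(x: np.ndarray, y: np.ndarray, label: str) -> Optional[float]:
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"correlation for {label} undefined (degenerate data)", stacklevel=3)
        return None
    return float(stats.pearsonr(x, y).statistic)


def run_merge_experiment(
    vol: LabeledVolume,
    depths: Sequence[int] = (2, 3, 4),
    replicates: int = 25,
    k: int = 1,
    connectivity: str = "face",
    base_seed: int = 0,
    bin_width: int = 5,
    log_base: float = 2.0,
) -> Tuple[MergeExperimentSummary, List[MergeTrialResult]]:
    """Run ``replicates`` random merges per depth and summarize the entropies.

    Each trial (seed = base_seed + running counter) merges the volume,
    recomputes the full entropy report at the given dilation settings and
    records the retained element count with the normalized entropies.
    Non-ergodic trials keep ``epi_norm = None`` and are excluded from the
    stationary-entropy statistics.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = transition_matrix(
            liminal_volumes(vol, k=k, connectivity=connectivity),
            volumes=region_volumes(vol),
        )
    trials: List[MergeTrialResult] = []
    counter = 0
    for depth in depths:
        for rep in range(replicates):
            seed = base_seed + counter
            counter += 1
            merged = random_merge(vol, model, depth=depth, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep_out = full_report(
                    merged, k=k, connectivity=connectivity, orders=(0,), log_base=log_base
                )
            trials.append(
                MergeTrialResult(
                    depth=int(depth),
                    replicate=rep,
                    seed=seed,
                    element_count=rep_out.m,
                    e0_norm=rep_out.normalized["E0"],
                    epi_norm=rep_out.normalized.get("Epi"),
                )
            )
    counts = np.array([t.element_count for t in trials], dtype=float)
    e0 = np.array([t.e0_norm for t in trials], dtype=float)
    epi = np.array(
        [t.epi_norm if t.epi_norm is not None else np.nan for t in trials], dtype=float
    )
    summary = MergeExperimentSummary(bin_width=bin_width)
    summary.bins = _binned(counts.astype(int), e0, epi, bin_width)
    summary.correlation_e0 = _pearson(counts, e0, "E0")
    ok = ~np.isnan(epi)
    summary.correlation_epi = _pearson(counts[ok], epi[ok], "Epi")
    return summary, trials
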