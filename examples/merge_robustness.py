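"""Robustness of the entropy measures to the granularity of tagging.

Randomly merges adjacent cells of a 73-cell Voronoi tessellation (pairs,
triples, quadruples; 25 replicates each), recomputes the normalized entropies
and reports their correlation with the surviving element count. A weak
correlation would mean the measure reflects arrangement rather than simply
how many elements the annotator happened to delineate.
"""

from sementropy import PhantomSpec, generate_phantom
from sementropy.merge import run_merge_experiment

vol = generate_phantom(PhantomSpec(kind="voronoi", shape=(32, 32, 32),
                                   params={"m": 73}, seed=42))
summary, trials = run_merge_experiment(vol, depths=(2, 3, 4), replicates=25,
                                       base_seed=42)

print(f"{len(trials)} trials; element counts "
      f"{min(t.element_count for t in trials)}"
      f"-{max(t.element_count for t in trials)} (original 73)")
print(f"{'elements':>10} {'trials':>6} {'E0_norm':>18} {'Epi_norm':>18}")
for b in summary.bins:
    epi = "absent" if b["mean_epi"] is None else f"{b['mean_epi']:.3f} ± {b['sd_epi']:.3f}"
    print(f"{b['lo']:>4}-{b['hi']:<5} {b['n_trials']:>6} "
          f"{b['mean_e0']:>10.3f} ± {b['sd_e0']:.3f} {epi:>18}")
print(f"correlation(entropy, element count): "
      f"E0 {summary.correlation_e0:.3f}, Epi {summary.correlation_epi:.3f}")
# On near-equal-size Voronoi cells the correlation is moderate: merging equal
# cells changes the volume distribution itself. Real anatomical models, with
# strongly heterogeneous tissue sizes, sit lower.
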