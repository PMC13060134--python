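"""Repository-level statistics over a curated library.

Rarefaction (how modification discovery accumulates with datasets),
the presence/absence matrix behind UpSet summaries, and elemental
composition-class frequencies.
"""

from carnlib import (
    SimConfig,
    composition_frequencies,
    intersection_counts,
    presence_matrix,
    rarefaction_curve,
    run_pipeline,
)
from carnlib.synthetic_data import simulate_repository

spectra, truth = simulate_repository(SimConfig(seed=13))
result = run_pipeline(spectra, truth.annotations())
by_id = {s.spectrum_id: s for s in spectra}

# dataset -> set of delta keys, from the curated library's cluster members
dataset_to_deltas: dict[str, set] = {}
rep_members = {
    result.assignment.representatives[cid]: ids
    for cid, ids in result.assignment.members.items()
}
for entry in result.library:
    for member in rep_members[entry.spectrum_id]:
        dataset_to_deltas.setdefault(by_id[member].dataset_id, set()).add(entry.delta_key)

curve = rarefaction_curve(dataset_to_deltas, n_permutations=1000, seed=0)
print("rarefaction (datasets sampled -> mean unique deltas [95% band]):")
for n, mean, lo, hi in zip(curve.n_sampled, curve.mean_unique, curve.ci_low, curve.ci_high):
    print(f"  {n}: {mean:6.2f}  [{lo:.0f}, {hi:.0f}]")
# a flattening curve means additional datasets contribute few new deltas.

groups = {k: {ds for ds, deltas in dataset_to_deltas.items() if k in deltas}
          for k in result.library_delta_keys}
matrix = presence_matrix(groups.keys(), groups)
print(f"\npresence matrix: {matrix.shape[0]} deltas x {matrix.shape[1]} datasets")
print("top intersections (exact membership patterns):")
print(intersection_counts(matrix, top_k=5).to_string())

classes, cho, hetero = composition_frequencies(result.library)
print("\ncomposition classes over unique deltas (no formulas attached here):")
print(classes.to_string())
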