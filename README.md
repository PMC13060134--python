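# carnlib

Desk-scale mining of acylcarnitine MS/MS spectra: diagnostic-ion
filtering, spectral clustering, molecular networking, delta-mass library
curation, cosine / reverse-cosine searching, and the repository- and
study-level statistics built on top.

## The problem

Acylcarnitines — esters of L-carnitine (C7H15NO3) with an acyl group —
are central readouts of fatty-acid β-oxidation and gut-microbial
metabolism. In positive-mode MS/MS they share three diagnostic product
ions (*m/z* 60.0808, 85.0284, 144.1019) regardless of the conjugated
moiety, so the compound class can be mined from heterogeneous tandem-MS
collections by fragment pattern alone. Each retrieved precursor then
carries a **delta mass**

Δm = *m/z*([M+H]⁺) − *m/z*([carnitine+H]⁺),  *m/z*([carnitine+H]⁺) = 162.1125,

which identifies the modification independent of structure: Δm = 42.01
is an acetylation, Δm = 79.96 a sulfation, and a CHO-only delta formula
with C = x, H = 2x − 2y − 2 and O = z + 1 maps to the lipid label
**CAR Cx:y;Oz** (x-carbon acyl chain, y unsaturations, z extra oxygens).

`carnlib` implements that whole workflow as a tested Python library for
method development and reanalysis at desk scale, with a
synthetic-repository generator (planted delta-mass series, three decoy
classes, known ground truth) standing in for public repositories, so
every stage — including its failure modes — is measurable.

## Pipeline

1. **diagnostic_query** — AND-queries over product ions (target m/z, ppm
   tolerance, % of base peak); collection filtering with DIA exclusion;
   FDR estimation against labeled references.
2. **clustering** — single-linkage clustering within precursor windows
   (20 ppm precursor, 0.02 Da fragment, cosine distance ≤ 0.1), medoid
   representatives.
3. **networking** — modified-cosine molecular network; components
   containing any non-carnitine annotation are purged wholesale.
4. **curation** — formula arithmetic, canonical 2-decimal Δm keys, mass
   defect, bounded elemental decomposition, CAR nomenclature, and the
   ≥ 2-independent-datasets support filter that turns clusters into a
   library.
5. **spectral_search** — cosine search (score ≥ 0.7, ≥ 4 matched ions,
   0.02 Da windows), secondary re-scoring on unfiltered spectra, and
   reference-normalized reverse cosine (score ≥ 0.7, ≥ 3 matched peaks)
   for conjugate discovery.
6. **repo_stats / downstream** — rarefaction with permutation bands,
   presence/UpSet matrices, composition frequencies, blank/RT filters,
   within-tissue relative abundance, log2 fold-changes, synchronized
   time-course groups (Pearson r ≥ 0.95, ≥ 3 shared timepoints).

## Worked example

```python
from carnlib import SimConfig, run_pipeline
from carnlib.synthetic_data import simulate_repository

spectra, truth = simulate_repository(SimConfig(seed=11))
result = run_pipeline(spectra, truth.annotations())
print(len(result.retained), result.assignment.n_clusters,
      len(result.library), sorted(result.library_delta_keys)[:3])
```

prints

```
258 25 20 [42.01, 70.04, 84.06]
```

— of 520 simulated spectra, 258 pass the three-ion query (the weak-85
and missing-ion decoys fail it), they collapse into 25 clusters whose
representatives are networked and purged of the 5 components carrying
non-carnitine annotations, and the surviving clusters yield a library of
20 delta masses, starting with acetylation at Δm 42.01. Against ground
truth that is 20/20 planted modifications recovered and zero decoy
entries; the query-stage FDR on this run is 1.89 % (the planted
chance-pass rate is 2 %).

The `examples/` scripts walk each capability the same way
(`python examples/03_build_library.py` prints the full library table),
and a thin CLI chains the stages from a shell:

```bash
carnlib simulate --out repo.mgf --truth-out truth.tsv --seed 5
carnlib curate --mgf repo.mgf --library-out library.tsv
carnlib stats --library library.tsv --rarefaction-out rarefaction.tsv
```

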