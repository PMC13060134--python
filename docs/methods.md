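# Methods

## Scope and model

`carnlib` implements a class-directed repository-mining workflow for
acylcarnitines. The underlying chemical model is minimal and explicit:

- An acylcarnitine ionizes as [M+H]⁺ (the quaternary ammonium gives a
  permanent positive charge), so only positive mode and charge 1 are in
  scope; other charges are rejected rather than guessed.
- The carnitine core (C7H15NO3) fragments into three diagnostic product
  ions at *m/z* 60.0808 (protonated trimethylamine fragment, C3H10N⁺),
  85.0284 (C4H5O2⁺) and 144.1019 (C7H14NO2⁺) regardless of the acyl
  group, so class membership is testable from the peak list alone.
- The **delta mass** Δm = precursor *m/z* − 162.1125 identifies the
  modification. Its canonical identity for all curation and statistics is
  Δm rounded (half-even) to two decimals; the full-precision value is
  retained alongside. Two decimals resolve ~10 mDa, comfortably above
  the few-mDa accuracy of modern instruments and below the spacing of
  distinct biological modifications.
- Ion m/z arithmetic uses monoisotopic atomic masses with an explicit
  proton mass (1.00727647 Da, i.e. the electron is accounted for): the
  electron's 0.55 mDa matters at the fourth decimal of the printed
  diagnostic ions.
- The mass defect of a delta is Δm minus its nearest integer, mapped to
  (−0.5, 0.5] with half-integer ties assigned to +0.5.

## The diagnostic query

A query is an AND-list of conditions (target m/z, ppm tolerance, minimum
intensity as % of base peak). The default is the three-ion carnitine
query at 20 ppm with thresholds 1% / 50% / 1%; the 85.0284 threshold is
a first-class knob because weakening it to 5–10% trades recall for
precision (hydroxylated acyl chains fragment internally and suppress the
canonical ions). Semantics, fixed deliberately:

- the intensity reference is the spectrum base peak;
- the ppm window is symmetric and computed on the target m/z;
- the most intense in-window peak is the condition's witness;
- an empty spectrum fails all conditions (it is not an error).

Lowering any threshold or widening any tolerance can never turn a pass
into a fail (tested as a property). DIA spectra are excluded from
collection filtering on metadata only — chimeric DIA scans defeat
relative-intensity logic, and no heuristic detection is attempted.
The query FDR over a labeled reference collection is simply
(# non-target retained)/(# retained), undefined (error) at zero retained.

## Similarity scores

All three scores share one matching engine: candidate peak pairs within
the fragment tolerance of an allowed shift are sorted by descending
product of intensity weights (w = intensity^p, p = 0.5 by default — the
square-root convention of molecular networking) and assigned greedily,
each peak used once.

- **cosine**: zero shift only; score = Σ matched wᵃwᵇ / (‖wᵃ‖‖wᵇ‖).
- **modified cosine**: shifts {0, Δprecursor}, same normalization; it
  therefore dominates the plain cosine on every pair, and equals it at
  equal precursors.
- **reverse cosine**: zero shift, but normalized by the reference norm
  and the norm of the *matched subset* of query peaks, so query-only
  peaks carry no penalty. This makes it the conjugate-discovery score: a
  spectrum embedding a reference's full pattern scores 1.0 regardless of
  extra fragments. It dominates the plain cosine by construction.

Greedy assignment is the field convention, not an optimum. On random
pairs with well-separated peaks it coincides with the exhaustive optimal
matching (asserted over 1,000 seeded trials for all three scores); when
several peaks crowd one tolerance window, greedy can deviate — the
acceptance script reports the measured agreement rate rather than
assuming 100%.

## Clustering

Redundancy reduction uses single-linkage union-find within a sorted
precursor sweep: a pair links when both |Δprecursor| ≤ 20 ppm (computed
on the pair mean) and cosine distance ≤ eps. Defaults mirror common
repository-clustering settings: 0.02 Da fragment tolerance, eps 0.1,
≥ 3 peaks after removing fragments below m/z 50. Clusters seen in fewer
than 2 distinct files are flagged, never dropped, so the ≥ 2-dataset
curation filter stays the single support gate. The published clustering
tools describe eps as a "minimum cosine similarity" while their
density-clustering internals treat it as a cosine *distance*; both
interpretations are selectable (`ClusterParams.eps_semantics`), distance
being the default. The representative is the medoid (maximal summed
cosine to co-members), ties broken by total intensity then id, which
makes clustering deterministic given input order.

Under-merging is deliberately tolerated: library support for a delta is
tallied on canonical Δm keys across the whole retained set, so two
clusters of the same modification still pool their dataset support.
(Whether support should be tallied pre- or post-merge of identical keys
was an open choice; pooling across the whole set is implemented.)

## Networking and the purge

The molecular network connects representatives whose modified cosine is
≥ 0.7 with ≥ 6 matched peaks, keeping an edge only when each endpoint
ranks the other in its top-10 neighbors (the standard anti-hub topology
filter). These defaults are explicit configuration: classical-networking
deployments vary, and nothing downstream depends on their exact values.
Any connected component containing one or more nodes annotated as a
non-target compound is removed entirely (guilt by association);
unannotated components survive. The target predicate is a
case-insensitive "carnitine" substring with allow/deny overrides. The
purge is idempotent and logged per component.

## Curation

`build_library` takes cluster representatives with member provenance,
computes each entry's Δm, pools supporting datasets per canonical key,
and drops keys supported by fewer than 2 independent datasets — a
confidence filter that trades unique single-study chemistry for
reproducibility. Optional delta formulas attach a composition class
(CHO, CHNO, CHOS, …) and, for CHO-only deltas, the CAR name via
y = C − H/2 − 1, z = O − 1. The ester carbonyl is not counted as a chain
unsaturation (acetyl → CAR C2:0); non-integer or negative y yields no
name — amide or otherwise unusual chemistry is left unlabeled rather
than mislabeled.

`decompose_delta` is a bounded brute-force enumerator: all compositions
within per-element bounds whose mass lies within a ppm tolerance of the
implied precursor (tolerance scaled to the precursor, matching how
instruments specify accuracy), filtered by ring-and-double-bond
equivalents of the full precursor formula, sorted by |error|. It stands
in for external formula predictors at desk scale and is verified against
an independent nested-loop enumeration.

## Statistics

- **Rarefaction**: cumulative unique canonical Δm keys over random
  permutations of dataset order (default 1,000; an exhaustive mode
  enumerates all N! orderings for small N). The band is the 2.5/97.5
  percentile across permutations — percentile rather than a parametric
  interval because per-step counts are small, discrete and skewed.
- **Presence matrices**: binary Δm × group membership with exact-pattern
  intersection counts (the numbers an UpSet plot displays).
- **Downstream feature-table recipes**: blank rule (a feature survives if
  its max sample abundance is ≥ 5× its max blank abundance, or it is
  absent from blanks — max-vs-max is one reading of an ambiguous rule
  and is flagged as such), RT window [0.2, 8] min, within-tissue
  relative abundance (per-feature max → 1.0), log2 fold-changes of
  per-group medians with a pseudocount defaulting to half the smallest
  nonzero value (zero handling is otherwise unspecified), and
  synchronized groups: replicates are collapsed to per-timepoint means,
  pairs with ≥ 3 shared non-missing timepoints and Pearson r ≥ 0.95 form
  a graph, groups are its connected components with ≥ 2 members —
  the minimal-assumption reading of "synchronized groups", in place of
  any stronger clustering rule.

## The synthetic repository

The generator emulates the statistical structure of multi-dataset public
collections, not their chemistry in full:

- 20 planted acyl deltas (a saturated chain series plus unsaturated and
  hydroxylated members), each observed in 2–4 of 6 datasets with 3–5
  spectra per dataset, one file per spectrum.
- Each carnitine spectrum carries the three diagnostic ions, an
  acylium-like fragment at mass(delta)+proton (so analogs form shifted
  modified-cosine matches), a trimethylamine neutral-loss fragment, a
  residual precursor peak, and 5 uniform noise peaks. Fragment
  intensities follow a per-analyte profile (drawn once per delta from
  configured ranges, stable via a CRC32-keyed RNG stream) with 8%
  relative jitter — fragmentation patterns are analyte properties, and
  this is what makes same-delta spectra cluster and analog spectra
  network.
- Mass accuracy is 3 ppm (1 σ), a realistic Orbitrap-class figure.
  The planted delta set is chosen so every delta lies > 2.5 mDa from a
  two-decimal rounding boundary; a delta sitting *on* a boundary has an
  intrinsically ambiguous canonical key at this accuracy, which would
  make the ground truth itself ill-defined rather than test the
  pipeline.
- Decoys (equal in number to carnitines by default) come in three
  classes: (a) missing ≥ 1 diagnostic ion, (b) all ions present but the
  85.0284 ion at 5–45% of base (the internal-fragmentation failure
  mode; they fail the 50% query and pass at 5% by construction), and
  (c) constructed chance-passes at a fixed count of 2% of decoys, so the
  query-stage FDR is exactly known (~2% when decoys and carnitines are
  equinumerous). Annotation tables label all decoys with non-carnitine
  compound classes and every fifth carnitine as an acylcarnitine,
  mimicking partial reference-library coverage.

What the generator does **not** model: isotope envelopes, adducts beyond
[M+H]⁺, chimeric/DIA spectra (acquisition labels are metadata only),
retention-time structure in spectra, and realistic decoy chemistry —
decoy classes are constructed to exercise specific filters. Passing
tests on this simulation therefore demonstrate the correctness of the
filtering/clustering/curation logic under known truth, not recall on
real repositories.

The time-course generator plants groups sharing a template curve up to a
positive affine rescaling plus additive noise (Pearson-invariant by
design); other features follow independent smoothed random walks.
All generation is deterministic under a fixed seed (numpy Generator
seeded through SeedSequence).

## Problem sizes and numerical choices

The default simulated repository is ~500 spectra; the full pipeline runs
in about a second, and the whole test suite plus the acceptance script
in well under a minute. Scores are floats in [0, 1] clipped at 1 to
absorb rounding; deterministic tie-breaks are fixed everywhere a sort
feeds a decision (matching order, representative choice, neighbor
ranking, result ordering). Degenerate inputs have defined behavior:
empty spectra fail queries but error in similarity scores; an empty
retained set makes the FDR an error, not 0; empty inputs to clustering
and presence matrices yield empty outputs.

## Known limitations

- MGF and feature-table I/O go through pyteomics/pandas; the mzML reader
  is deliberately narrow (centroided spectra, standard float encodings,
  no chromatograms, profile mode rejected).
- The reverse-cosine normalization convention (reference norm × matched
  query-subset norm) is declared, since external implementations vary.
- Greedy matching can underestimate the optimal matched cosine when
  multiple peaks share a tolerance window (measured, rare on realistic
  spectra).
- The ≥ 2-dataset filter keys on 2-decimal Δm; modifications closer than
  10 mDa merge, and a delta within instrument error of a rounding
  boundary can split its support across two keys.
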