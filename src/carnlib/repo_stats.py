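"""Library- and repository-level statistics.

Covers the descriptive layer over a curated delta-mass library: rarefaction
of modification discovery as datasets accumulate (permutation mean with a
95% percentile band), presence/absence matrices for UpSet-style summaries
of which repositories or tissues share which delta masses, elemental
composition-class frequencies, and joins of search matches onto file-level
metadata.  Delta-mass identity everywhere is the canonical two-decimal key.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import LibraryEntry, composition_class, formula_string

__all__ = [
    "RarefactionResult",
    "rarefaction_curve",
    "presence_matrix",
    "intersection_counts",
    "composition_frequencies",
    "metadata_join",
]


@dataclass
class RarefactionResult:
    n_sampled: np.ndarray  # 1..N datasets
    mean_unique: np.ndarray
    ci_low: np.ndarray  # 2.5th percentile across permutations
    ci_high: np.ndarray  # 97.5th percentile
    n_permutations: int

    @property
    def total_unique(self) -> float:
        return float(self.mean_unique[-1])


def _cumulative_unique(order: Sequence[str], sets: Mapping[str, set]) -> list[int]:
    seen: set = set()
    out = []
    for ds in order:
        seen |= sets[ds]
        out.append(len(seen))
    return out


def rarefaction_curve(
    dataset_to_deltas: Mapping[str, Iterable[float]],
    n_permutations: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> RarefactionResult:
    """Rarefaction of unique delta masses over random dataset orderings.

    For each permutation of dataset order, the cumulative number of unique
    delta keys is recorded after each added dataset; the curve reports the
    per-step mean and the 2.5/97.5 percentile band.  ``exhaustive=True``
    enumerates all N! orderings instead of sampling (only sensible for a
    handful of datasets).
    """
    sets = {ds: set(vals) for ds, vals in dataset_to_deltas.items()}
    if not sets or all(len(v) == 0 for v in sets.values()):
        raise ValueError("need at least one dataset with at least one delta mass")
    names = sorted(sets)
    n = len(names)
    if exhaustive:
        orders = [list(p) for p in itertools.permutations(names)]
    else:
        rng = np.random.default_rng(seed)
        orders = [list(rng.permutation(names)) for _ in range(n_permutations)]
    curves = np.array([_cumulative_unique(order, sets) for order in orders], dtype=float)
    return RarefactionResult(
        n_sampled=np.arange(1, n + 1),
        mean_unique=curves.mean(axis=0),
        ci_low=np.percentile(curves, 2.5, axis=0),
        ci_high=np.percentile(curves, 97.5, axis=0),
        n_permutations=len(orders),
    )


def presence_matrix(
    entries: Iterable[float],
    group_of: Mapping[float, Iterable[str]] | Callable[[float], Iterable[str]],
) -> pd.DataFrame:
    """Binary delta-key x group matrix: 1 iff the delta was seen in the group."""
    keys = sorted(set(entries))
    lookup = group_of if callable(group_of) else (lambda k: group_of.get(k, ()))
    groups = sorted({g for k in keys for g in lookup(k)})
    data = np.zeros((len(keys), len(groups)), dtype=int)
    gidx = {g: j for j, g in enumerate(groups)}
    for i, k in enumerate(keys):
        for g in lookup(k):
            data[i, gidx[g]] = 1
    return pd.DataFrame(data, index=keys, columns=groups)


def intersection_counts(matrix: pd.DataFrame, top_k: int | None = None) -> pd.Series:
    """Exact-membership intersection sizes, UpSet style.

    Each delta is assigned to the exact set of groups it occupies; counts
    are returned per membership pattern (group names joined with '&' in
    column order), largest first, optionally truncated to the top_k
    intersections.
    """
    patterns: dict[str, int] = {}
    for _, row in matrix.iterrows():
        pattern = "&".join(col for col in matrix.columns if row[col])
        if pattern:
            patterns[pattern] = patterns.get(pattern, 0) + 1
    series = pd.Series(patterns, dtype=int).sort_values(ascending=False)
    return series.head(top_k) if top_k else series


def composition_frequencies(
    entries: Sequence[LibraryEntry],
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Composition-class and per-formula frequencies over unique delta keys.

    Returns (class counts over all entries, CHO-only formula counts,
    heteroatom formula counts); entries without a formula count as
    'unassigned'.  Counts are over unique delta keys, not raw entries.
    """
    seen: dict[float, LibraryEntry] = {}
    for e in entries:
        seen.setdefault(e.delta_key, e)
    classes: dict[str, int] = {}
    cho: dict[str, int] = {}
    hetero: dict[str, int] = {}
    for e in seen.values():
        cls = e.composition_class or composition_class(e.delta_formula)
        classes[cls] = classes.get(cls, 0) + 1
        if e.delta_formula is not None:
            name = formula_string(e.delta_formula)
            if cls == "CHO" or cls in ("C", "CH", "CO", "HO", "H", "O"):
                cho[name] = cho.get(name, 0) + 1
            else:
                hetero[name] = hetero.get(name, 0) + 1
    as_series = lambda d: pd.Series(d, dtype=int).sort_values(ascending=False)
    return as_series(classes), as_series(cho), as_series(hetero)


def metadata_join(
    matches: Sequence,
    file_metadata: Mapping[str, tuple[str, str]],
    delta_of_library_id: Mapping[str, float],
    file_of_query: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-(organism, tissue) match counts and unique delta-mass counts.

    ``matches`` carry ``query_id`` and ``library_id``; the query's source
    file resolves through ``file_of_query`` (or is the query id itself),
    and files map to (organism, tissue) through ``file_metadata``.  Files
    without metadata land in the ('unannotated', 'unannotated') bucket.
    """
    rows = []
    for m in matches:
        fid = file_of_query.get(m.query_id, m.query_id) if file_of_query else m.query_id
        organism, tissue = file_metadata.get(fid, ("unannotated", "unannotated"))
        rows.append(
            {
                "organism": organism,
                "tissue": tissue,
                "delta_key": delta_of_library_id.get(m.library_id, math.nan),
            }
        )
    df = pd.DataFrame(rows, columns=["organism", "tissue", "delta_key"])
    if df.empty:
        return pd.DataFrame(columns=["organism", "tissue", "n_matches", "n_unique_deltas"])
    grouped = df.groupby(["organism", "tissue"], as_index=False).agg(
        n_matches=("delta_key", "size"),
        n_unique_deltas=("delta_key", "nunique"),
    )
    return grouped.sort_values(["organism", "tissue"]).reset_index(drop=True)
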