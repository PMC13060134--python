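"""Searching a curated spectral library against query spectra.

Three search contracts live here: (1) identity-level cosine search with a
precursor window, a minimum score and a minimum matched-peak count; (2) a
secondary re-scoring pass that recomputes the cosine on the *original,
unfiltered* spectra and drops matches that no longer clear the threshold —
a guard against matches manufactured by upstream peak filtering; and
(3) reverse cosine, normalized against the reference spectrum only, so
extra query-side peaks (for example from an unknown conjugate moiety) do
not dilute the score.  Reverse cosine is the discovery score for spectra
that *contain* a known reference pattern plus something more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from ._matching import greedy_match
from .clustering import cosine_similarity
from .spectra_io import Spectrum

__all__ = [
    "MatchResult",
    "search_library",
    "recompute_unfiltered_cosine",
    "reverse_cosine",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchResult:
    query_id: str
    library_id: str
    cosine: float
    n_matched: int
    reverse_cosine: float | None = None
    unfiltered_cosine: float | None = None
    unresolvable: bool = False


def search_library(
    queries: Sequence[Spectrum],
    library: Sequence[Spectrum],
    min_cosine: float = 0.7,
    min_matched: int = 4,
    precursor_tol_da: float = 0.02,
    fragment_tol_da: float = 0.02,
    intensity_power: float = 0.5,
    analog: bool = False,
) -> list[MatchResult]:
    """Identity-level cosine search of queries against a library.

    Candidate pairs are limited to |precursor difference| <=
    ``precursor_tol_da`` unless ``analog`` opens the precursor window.  All
    qualifying pairs are returned (cosine >= min_cosine and matched peaks
    >= min_matched), sorted by descending score then ids — consumers take
    the per-query top hit if they want best-only.
    """
    if not library:
        raise ValueError("empty library")
    lib = sorted(library, key=lambda s: (s.precursor_mz, s.spectrum_id))
    lib_mz = np.array([s.precursor_mz for s in lib])
    results: list[MatchResult] = []
    for q in queries:
        if analog:
            candidates = lib
        else:
            lo = np.searchsorted(lib_mz, q.precursor_mz - precursor_tol_da, "left")
            hi = np.searchsorted(lib_mz, q.precursor_mz + precursor_tol_da, "right")
            candidates = lib[lo:hi]
        for ref in candidates:
            score, n_matched = cosine_similarity(
                q, ref, fragment_tol_da, intensity_power
            )
            if score >= min_cosine and n_matched >= min_matched:
                results.append(MatchResult(q.spectrum_id, ref.spectrum_id, score, n_matched))
    results.sort(key=lambda m: (-m.cosine, m.query_id, m.library_id))
    return results


def recompute_unfiltered_cosine(
    matches: Sequence[MatchResult],
    raw_queries: Mapping[str, Spectrum],
    raw_library: Mapping[str, Spectrum],
    retain_min: float = 0.7,
    fragment_tol_da: float = 0.02,
    intensity_power: float = 0.5,
    strict: bool = False,
) -> list[MatchResult]:
    """Secondary cosine on the original, unfiltered spectra.

    Matches whose unfiltered cosine falls below ``retain_min`` are removed.
    A match whose raw spectra cannot be resolved is flagged and retained
    with a warning (or raises in strict mode).
    """
    out: list[MatchResult] = []
    n_removed = 0
    for m in matches:
        q = raw_queries.get(m.query_id)
        r = raw_library.get(m.library_id)
        if q is None or r is None:
            if strict:
                raise KeyError(f"raw spectrum missing for match {m.query_id}->{m.library_id}")
            logger.warning(
                "raw spectrum unresolvable for %s->%s; match retained unverified",
                m.query_id, m.library_id,
            )
            out.append(replace(m, unresolvable=True))
            continue
        score, _ = cosine_similarity(q, r, fragment_tol_da, intensity_power)
        if score >= retain_min:
            out.append(replace(m, unfiltered_cosine=score))
        else:
            n_removed += 1
    if n_removed:
        logger.info("secondary cosine removed %d matches below %.2f", n_removed, retain_min)
    return out


def reverse_cosine(
    query: Spectrum,
    reference: Spectrum,
    fragment_tol_da: float = 0.02,
    min_score: float = 0.7,
    min_matched: int = 3,
    intensity_power: float = 0.5,
) -> tuple[float, int, bool]:
    """Reference-normalized cosine tolerant of extra query peaks.

    Peaks are matched exactly as in the plain cosine, but the score is
    normalized by the reference peak norm and the norm of the *matched
    subset* of query peaks, so query-only peaks carry no penalty.  Returns
    (score, matched peaks, pass) where pass requires score >= min_score
    and matched >= min_matched.
    """
    if reference.n_peaks == 0:
        raise ValueError("empty reference spectrum")
    if query.n_peaks == 0:
        raise ValueError("empty query spectrum")
    matched, wq, wr = greedy_match(
        query, reference, fragment_tol_da, (0.0,), intensity_power
    )
    ref_norm = float(np.linalg.norm(wr))
    matched_q = np.array([wq[i] for i, _ in matched]) if matched else np.array([])
    q_norm = float(np.linalg.norm(matched_q))
    if ref_norm == 0.0 or q_norm == 0.0:
        score = 0.0
    else:
        num = sum(float(wq[i] * wr[j]) for i, j in matched)
        score = min(num / (q_norm * ref_norm), 1.0)
    n = len(matched)
    return score, n, bool(score >= min_score and n >= min_matched)
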