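"""Redundancy reduction: single-linkage spectral clustering + representatives.

Repository mining retrieves many near-identical MS/MS scans of the same
analyte across files.  This stage groups them: two spectra join a cluster
when a chain of pairs connects them, each pair agreeing in precursor m/z
(ppm tolerance) and in fragment cosine similarity (cosine distance <= eps).
Defaults mirror common repository-clustering settings: 20 ppm precursor,
0.02 Da fragment tolerance, eps 0.1, >= 3 fragment peaks, minimum m/z 50.

Note on eps: some tools describe eps as a *minimum cosine similarity*, the
underlying density-clustering parameter is a cosine *distance*.  Both
semantics are selectable here; distance is the default (see
``ClusterParams.eps_semantics``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._matching import cosine_from_match, greedy_match
from .spectra_io import Spectrum

__all__ = [
    "ClusterParams",
    "ClusterAssignment",
    "cosine_similarity",
    "preprocess",
    "cluster_spectra",
    "select_representative",
]


@dataclass(frozen=True)
class ClusterParams:
    precursor_tol_ppm: float = 20.0
    fragment_tol_da: float = 0.02
    eps: float = 0.1
    min_peaks: int = 3
    min_mz: float = 50.0
    min_files: int = 2  # clusters seen in fewer files are flagged, not dropped
    intensity_power: float = 0.5
    eps_semantics: str = "distance"  # or "similarity"

    def __post_init__(self) -> None:
        if min(self.precursor_tol_ppm, self.fragment_tol_da, self.eps,
               self.min_peaks, self.min_mz) <= 0:
            raise ValueError("cluster parameters must be positive")
        if self.eps > 1:
            raise ValueError("eps must be <= 1")
        if self.eps_semantics not in ("distance", "similarity"):
            raise ValueError("eps_semantics must be 'distance' or 'similarity'")

    def pair_links(self, score: float) -> bool:
        if self.eps_semantics == "distance":
            return (1.0 - score) <= self.eps
        return score >= self.eps


@dataclass
class ClusterAssignment:
    """Total mapping of retained spectra to clusters, one representative each.

    ``flagged_low_support`` lists clusters observed in fewer than
    ``min_files`` distinct file ids; ``dropped`` lists spectra removed in
    preprocessing (too few peaks).
    """

    cluster_of: dict[str, int]
    members: dict[int, list[str]]
    representatives: dict[int, str]
    flagged_low_support: set[int] = field(default_factory=set)
    dropped: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.members)


def cosine_similarity(
    a: Spectrum,
    b: Spectrum,
    fragment_tol_da: float = 0.02,
    intensity_power: float = 0.5,
) -> tuple[float, int]:
    """Cosine similarity over one-to-one matched fragment peaks.

    Peaks are matched within ``fragment_tol_da``, greedily by descending
    product of intensity weights (w = intensity**intensity_power, default
    square root); the score is the normalized dot product over matched
    pairs.  Returns (score in [0, 1], number of matched peaks); symmetric.
    """
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("cosine undefined for empty spectra")
    matched, wa, wb = greedy_match(a, b, fragment_tol_da, (0.0,), intensity_power)
    return cosine_from_match(matched, wa, wb), len(matched)


def preprocess(
    spectra: Sequence[Spectrum], min_mz: float, min_peaks: int
) -> tuple[list[Spectrum], list[str]]:
    """Drop peaks below min_mz, then spectra with fewer than min_peaks."""
    kept: list[Spectrum] = []
    dropped: list[str] = []
    for s in spectra:
        mask = s.mz >= min_mz
        trimmed = s.with_peaks(s.mz[mask], s.intensity[mask])
        if trimmed.n_peaks < min_peaks:
            dropped.append(s.spectrum_id)
        else:
            kept.append(trimmed)
    return kept, dropped


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_spectra(
    spectra: Sequence[Spectrum], params: ClusterParams | None = None
) -> ClusterAssignment:
    """Single-linkage clustering within precursor windows.

    Spectra are sorted by precursor m/z and swept: each pair within the ppm
    precursor tolerance is scored by cosine, and pairs passing the eps gate
    are merged with union-find.  Deterministic given input order; cluster
    ids are assigned in order of first appearance of each cluster's
    earliest member.
    """
    params = params or ClusterParams()
    kept, dropped = preprocess(spectra, params.min_mz, params.min_peaks)
    if not kept:
        return ClusterAssignment({}, {}, {}, set(), dropped)

    order = sorted(range(len(kept)), key=lambda i: kept[i].precursor_mz)
    uf = _UnionFind(len(kept))
    for a_pos, i in enumerate(order):
        mi = kept[i].precursor_mz
        for j in order[a_pos + 1:]:
            mj = kept[j].precursor_mz
            tol = params.precursor_tol_ppm * 1e-6 * 0.5 * (mi + mj)
            if mj - mi > tol:
                break
            score, _ = cosine_similarity(
                kept[i], kept[j], params.fragment_tol_da, params.intensity_power
            )
            if params.pair_links(score):
                uf.union(i, j)

    roots: dict[int, int] = {}
    cluster_of: dict[str, int] = {}
    members: dict[int, list[str]] = {}
    for idx, s in enumerate(kept):
        root = uf.find(idx)
        cid = roots.setdefault(root, len(roots))
        cluster_of[s.spectrum_id] = cid
        members.setdefault(cid, []).append(s.spectrum_id)

    by_id = {s.spectrum_id: s for s in kept}
    representatives = {
        cid: select_representative(
            [by_id[sid] for sid in ids], params.fragment_tol_da, params.intensity_power
        )
        for cid, ids in members.items()
    }
    flagged = {
        cid
        for cid, ids in members.items()
        if len({by_id[sid].file_id for sid in ids}) < params.min_files
    }
    return ClusterAssignment(cluster_of, members, representatives, flagged, dropped)


def select_representative(
    cluster: Sequence[Spectrum],
    fragment_tol_da: float = 0.02,
    intensity_power: float = 0.5,
) -> str:
    """Medoid spectrum id: maximal summed cosine similarity to co-members.

    Ties break by highest total peak intensity, then lexicographic id.
    """
    if not cluster:
        raise ValueError("empty cluster")
    if len(cluster) == 1:
        return cluster[0].spectrum_id
    sims = np.zeros(len(cluster))
    for i in range(len(cluster)):
        for j in range(i + 1, len(cluster)):
            score, _ = cosine_similarity(
                cluster[i], cluster[j], fragment_tol_da, intensity_power
            )
            sims[i] += score
            sims[j] += score
    best = sorted(
        range(len(cluster)),
        key=lambda i: (
            -sims[i],
            -float(cluster[i].intensity.sum()),
            cluster[i].spectrum_id,
        ),
    )[0]
    return cluster[best].spectrum_id
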