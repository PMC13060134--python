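"""Molecular networking with modified cosine and component purging.

A molecular network joins representative spectra by edges whose modified
cosine score — which lets fragment peaks match either directly or offset by
the precursor mass difference, so structural analogs connect — exceeds a
threshold.  Connected components ("subnetworks") group related chemistry;
components containing any node annotated as a non-target compound class are
purged wholesale, the network-level guilt-by-association filter used to
clean a candidate carnitine collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx

from ._matching import cosine_from_match, greedy_match
from .spectra_io import Spectrum

__all__ = [
    "MolecularNetwork",
    "modified_cosine",
    "build_network",
    "purge_nontarget_components",
    "carnitine_annotation_predicate",
]


@dataclass
class MolecularNetwork:
    """Undirected similarity graph over spectra plus its components."""

    graph: nx.Graph
    purged_components: list[dict] = field(default_factory=list)

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float, int]]:
        return [
            (a, b, d["score"], d["n_matched"])
            for a, b, d in self.graph.edges(data=True)
        ]


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    fragment_tol_da: float = 0.02,
    intensity_power: float = 0.5,
) -> tuple[float, int]:
    """Modified cosine: peaks match at zero shift or shifted by the
    precursor mass difference; greedy one-to-one assignment by descending
    intensity-weight product, normalized like the plain cosine."""
    if a.n_peaks == 0 or b.n_peaks == 0:
        raise ValueError("modified cosine undefined for empty spectra")
    shift = a.precursor_mz - b.precursor_mz
    shifts = (0.0,) if abs(shift) < 1e-12 else (0.0, shift)
    matched, wa, wb = greedy_match(a, b, fragment_tol_da, shifts, intensity_power)
    return cosine_from_match(matched, wa, wb), len(matched)


def build_network(
    representatives: Sequence[Spectrum],
    min_score: float = 0.7,
    min_matched_peaks: int = 6,
    top_k: int = 10,
    fragment_tol_da: float = 0.02,
    intensity_power: float = 0.5,
) -> MolecularNetwork:
    """Build the similarity network over representative spectra.

    An edge survives iff modified cosine >= min_score, matched peaks >=
    min_matched_peaks, and each endpoint ranks the other within its top_k
    scoring neighbors (the standard topology filter that keeps hub nodes
    from absorbing everything).
    """
    if not representatives:
        raise ValueError("need at least one spectrum")
    g = nx.Graph()
    for s in representatives:
        g.add_node(s.spectrum_id, precursor_mz=s.precursor_mz)

    scored: dict[str, list[tuple[float, str]]] = {s.spectrum_id: [] for s in representatives}
    candidate_edges: list[tuple[str, str, float, int]] = []
    for i in range(len(representatives)):
        for j in range(i + 1, len(representatives)):
            a, b = representatives[i], representatives[j]
            score, n_matched = modified_cosine(a, b, fragment_tol_da, intensity_power)
            if score >= min_score and n_matched >= min_matched_peaks:
                candidate_edges.append((a.spectrum_id, b.spectrum_id, score, n_matched))
                scored[a.spectrum_id].append((score, b.spectrum_id))
                scored[b.spectrum_id].append((score, a.spectrum_id))

    top: dict[str, set[str]] = {}
    for sid, neighbors in scored.items():
        neighbors.sort(key=lambda t: (-t[0], t[1]))
        top[sid] = {other for _, other in neighbors[:top_k]}
    for a_id, b_id, score, n_matched in candidate_edges:
        if b_id in top[a_id] and a_id in top[b_id]:
            g.add_edge(a_id, b_id, score=score, n_matched=n_matched)
    return MolecularNetwork(g)


def carnitine_annotation_predicate(
    allow: Sequence[str] = (), deny: Sequence[str] = ()
) -> Callable[[str], bool]:
    """Default target predicate: case-insensitive substring 'carnitine',
    overridable by explicit allow/deny label lists."""
    allow_set = {a.lower() for a in allow}
    deny_set = {d.lower() for d in deny}

    def is_target(label: str) -> bool:
        low = label.lower()
        if low in deny_set:
            return False
        if low in allow_set:
            return True
        return "carnitine" in low

    return is_target


def purge_nontarget_components(
    network: MolecularNetwork,
    annotations: Mapping[str, str],
    is_target: Callable[[str], bool] | None = None,
) -> MolecularNetwork:
    """Remove whole components containing any failing annotation.

    ``annotations`` is partial (unannotated nodes allowed); a component is
    purged when at least one of its nodes has an annotation for which
    ``is_target`` is False.  Components with no annotations are retained.
    The purge log records each removed component and its trigger labels.
    """
    is_target = is_target or carnitine_annotation_predicate()
    g = network.graph.copy()
    purged_log = list(network.purged_components)
    for component in list(nx.connected_components(g)):
        triggers = {
            node: annotations[node]
            for node in component
            if node in annotations and not is_target(annotations[node])
        }
        if triggers:
            purged_log.append({"nodes": set(component), "triggers": triggers})
            g.remove_nodes_from(component)
    return MolecularNetwork(g, purged_log)
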