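"""End-to-end pipeline: query -> cluster -> network + purge -> curate.

Glue over the stage modules for the common case of turning a raw
multi-dataset spectra collection plus a compound-annotation table into a
curated delta-mass library, keeping per-stage outputs for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .clustering import ClusterAssignment, ClusterParams, cluster_spectra
from .curation import LibraryEntry, build_library
from .diagnostic_query import DiagnosticQuery, default_query, filter_spectra
from .networking import (
    MolecularNetwork,
    build_network,
    carnitine_annotation_predicate,
    purge_nontarget_components,
)
from .spectra_io import Spectrum

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    retained: list[Spectrum]
    assignment: ClusterAssignment
    network: MolecularNetwork
    purged_network: MolecularNetwork
    library: list[LibraryEntry]

    @property
    def library_delta_keys(self) -> set[float]:
        return {e.delta_key for e in self.library}


def run_pipeline(
    spectra: Sequence[Spectrum],
    annotations: Mapping[str, str] | None = None,
    query: DiagnosticQuery | None = None,
    cluster_params: ClusterParams | None = None,
    min_score: float = 0.7,
    min_matched_peaks: int = 6,
    top_k: int = 10,
    min_datasets: int = 2,
) -> PipelineResult:
    """Run the full curation pipeline on a spectra collection.

    Stages: diagnostic-ion query filter with DIA exclusion; single-linkage
    clustering with representative selection; molecular networking over the
    representatives and purging of components carrying non-carnitine
    annotations; library construction with the >= min_datasets
    multi-dataset support filter.
    """
    annotations = annotations or {}
    retained = filter_spectra(spectra, query or default_query())
    assignment = cluster_spectra(retained, cluster_params)
    by_id = {s.spectrum_id: s for s in retained}
    representatives = [by_id[rid] for rid in sorted(assignment.representatives.values())]
    if representatives:
        network = build_network(
            representatives,
            min_score=min_score,
            min_matched_peaks=min_matched_peaks,
            top_k=top_k,
        )
        purged = purge_nontarget_components(
            network,
            _component_annotations(assignment, annotations),
            carnitine_annotation_predicate(),
        )
        surviving = purged.nodes
    else:
        network = MolecularNetwork(nx.Graph())
        purged = network
        surviving = set()
    rep_members = {
        assignment.representatives[cid]: members
        for cid, members in assignment.members.items()
    }
    surviving_assignments = {
        rep: members for rep, members in rep_members.items() if rep in surviving
    }
    library = build_library(surviving_assignments, by_id, min_datasets=min_datasets)
    return PipelineResult(retained, assignment, network, purged, library)


def _component_annotations(
    assignment: ClusterAssignment, annotations: Mapping[str, str]
) -> dict[str, str]:
    """Lift member-level annotations onto cluster representatives.

    A non-target annotation anywhere in a cluster must be able to trigger
    the purge, so any member's label attaches to the representative
    (non-carnitine labels win ties).
    """
    lifted: dict[str, str] = {}
    is_target = carnitine_annotation_predicate()
    for cid, members in assignment.members.items():
        rep = assignment.representatives[cid]
        labels = [annotations[m] for m in members if m in annotations]
        if not labels:
            continue
        failing = [lab for lab in labels if not is_target(lab)]
        lifted[rep] = failing[0] if failing else labels[0]
    return lifted
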