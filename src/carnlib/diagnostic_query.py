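"""Diagnostic product-ion queries over MS/MS spectra.

Acylcarnitines in positive mode share three diagnostic fragments at
m/z 60.0808, 85.0284 and 144.1019.  A :class:`DiagnosticQuery` is an
AND-list of product-ion conditions (target m/z, ppm tolerance, minimum
relative intensity as a percent of the base peak); the default query is
the three-clause carnitine query with the 85.0284 ion required at 50% of
the base peak.  The module evaluates queries, filters spectrum
collections (excluding data-independent acquisition scans, which are
chimeric), and estimates the false discovery rate of a query against a
labeled reference collection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .spectra_io import Spectrum

__all__ = [
    "QueryCondition",
    "DiagnosticQuery",
    "ConditionReport",
    "DIAGNOSTIC_IONS",
    "default_query",
    "evaluate_query",
    "filter_spectra",
    "estimate_fdr",
]

#: The three positive-mode carnitine diagnostic fragment ions (Da).
DIAGNOSTIC_IONS = (60.0808, 85.0284, 144.1019)


@dataclass(frozen=True)
class QueryCondition:
    """One product-ion clause: a peak within +-tolerance_ppm of target_mz
    whose intensity reaches min_intensity_percent of the base peak."""

    target_mz: float
    tolerance_ppm: float = 20.0
    min_intensity_percent: float = 1.0

    def __post_init__(self) -> None:
        if self.target_mz <= 0:
            raise ValueError("target_mz must be positive")
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        if not (0 < self.min_intensity_percent <= 100):
            raise ValueError("min_intensity_percent must be in (0, 100]")


@dataclass(frozen=True)
class DiagnosticQuery:
    """AND-combination of product-ion conditions."""

    conditions: tuple[QueryCondition, ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("query needs at least one condition")

    def with_threshold(self, target_mz: float, percent: float) -> "DiagnosticQuery":
        """Copy with the intensity threshold of one clause replaced."""
        conds = tuple(
            replace(c, min_intensity_percent=percent)
            if abs(c.target_mz - target_mz) < 1e-6
            else c
            for c in self.conditions
        )
        return DiagnosticQuery(conds)


def default_query(threshold_85: float = 50.0) -> DiagnosticQuery:
    """The three-ion carnitine query (60.0808 at 1%, 85.0284 at
    ``threshold_85``%, 144.1019 at 1%, all at 20 ppm)."""
    return DiagnosticQuery(
        (
            QueryCondition(60.0808, 20.0, 1.0),
            QueryCondition(85.0284, 20.0, threshold_85),
            QueryCondition(144.1019, 20.0, 1.0),
        )
    )


@dataclass(frozen=True)
class ConditionReport:
    condition: QueryCondition
    passed: bool
    witness_mz: float | None  # most intense in-window peak, if any
    witness_intensity_percent: float | None


def evaluate_query(
    spectrum: Spectrum, query: DiagnosticQuery
) -> tuple[bool, list[ConditionReport]]:
    """Evaluate an AND query against one spectrum.

    A condition passes iff some peak lies within +-tolerance_ppm of the
    target m/z (window computed on the target) and its intensity is at
    least min_intensity_percent of the spectrum base peak.  The witness of
    a condition is the most intense in-window peak.  An empty spectrum
    fails every condition (not an error).
    """
    reports: list[ConditionReport] = []
    base = spectrum.base_peak_intensity
    for cond in query.conditions:
        if spectrum.n_peaks == 0 or base <= 0:
            reports.append(ConditionReport(cond, False, None, None))
            continue
        tol = cond.target_mz * cond.tolerance_ppm * 1e-6
        lo = np.searchsorted(spectrum.mz, cond.target_mz - tol, side="left")
        hi = np.searchsorted(spectrum.mz, cond.target_mz + tol, side="right")
        if hi <= lo:
            reports.append(ConditionReport(cond, False, None, None))
            continue
        window = slice(lo, hi)
        best = lo + int(np.argmax(spectrum.intensity[window]))
        percent = 100.0 * float(spectrum.intensity[best]) / base
        reports.append(
            ConditionReport(
                cond,
                percent >= cond.min_intensity_percent,
                float(spectrum.mz[best]),
                percent,
            )
        )
    return all(r.passed for r in reports), reports


def filter_spectra(
    spectra: Iterable[Spectrum],
    query: DiagnosticQuery | None = None,
    exclude_acquisition: frozenset[str] | set[str] = frozenset({"DIA"}),
) -> list[Spectrum]:
    """Retain spectra passing the query, excluding listed acquisition modes.

    DIA spectra are excluded by default (trusted from metadata only — no
    heuristic inference).  Input order is preserved.
    """
    query = query or default_query()
    retained = []
    for s in spectra:
        if s.acquisition in exclude_acquisition:
            continue
        if evaluate_query(s, query)[0]:
            retained.append(s)
    return retained


def estimate_fdr(
    retained: Sequence[Spectrum], labels: Mapping[str, bool]
) -> float:
    """Fraction of retained spectra whose label is not the target class.

    ``labels`` maps spectrum id -> is_target.  Raises on an empty retained
    set (FDR undefined) or on an unlabeled retained spectrum.
    """
    if not retained:
        raise ValueError("FDR undefined: no retained spectra")
    missing = [s.spectrum_id for s in retained if s.spectrum_id not in labels]
    if missing:
        raise KeyError(f"unlabeled retained spectra: {missing[:5]}")
    n_decoy = sum(1 for s in retained if not labels[s.spectrum_id])
    return n_decoy / len(retained)
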