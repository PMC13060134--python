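"""Chemistry core and delta-mass library builder.

An acylcarnitine is a conjugate of the carnitine core (C7H15NO3) with an
acyl group.  Because the core fragments identically regardless of the
conjugate, the *delta mass* — precursor ion mass minus the [M+H]+ mass of
free carnitine — identifies the modification independent of its structure.
This module provides the formula arithmetic behind that idea: monoisotopic
masses, delta-mass computation with a canonical two-decimal key, mass
defect, elemental decomposition of a delta mass under bounded element
counts, the lipidomics-style ``CAR Cx:y;Oz`` nomenclature for CHO-only
acyl deltas, and the multi-dataset support filter that turns clustered
spectra into a curated library.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics.mass import nist_mass

from .spectra_io import Spectrum

__all__ = [
    "ElementCounts",
    "LibraryEntry",
    "MONOISOTOPIC",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "CARNITINE",
    "CARNITINE_MH",
    "parse_formula",
    "formula_string",
    "monoisotopic_mass",
    "ion_mz",
    "compute_delta_mass",
    "canonical_delta_key",
    "mass_defect",
    "delta_formula_from_precursor",
    "assign_car_nomenclature",
    "decompose_delta",
    "composition_class",
    "build_library",
    "chain_length_category",
]

ElementCounts = dict[str, int]

SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "S", "P", "F", "Cl", "Br", "I")

#: Standard monoisotopic atomic masses (Da), most-abundant isotope.
MONOISOTOPIC: dict[str, float] = {
    el: nist_mass[el][0][0] for el in SUPPORTED_ELEMENTS
}

PROTON_MASS = 1.00727646688  # Da
ELECTRON_MASS = 0.00054857990907  # Da

#: Free carnitine core.
CARNITINE: ElementCounts = {"C": 7, "H": 15, "N": 1, "O": 3}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-style molecular formula into element counts.

    >>> parse_formula("C9H17NO4")
    {'C': 9, 'H': 17, 'N': 1, 'O': 4}
    """
    if not isinstance(text, str) or not text:
        raise ValueError("empty formula")
    counts: ElementCounts = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        if not match.group(0):
            break
        symbol, digits = match.group(1), match.group(2)
        if symbol not in SUPPORTED_ELEMENTS:
            raise ValueError(
                f"unknown element {symbol!r} in {text!r} at position {match.start()}"
            )
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return counts


def formula_string(counts: Mapping[str, int]) -> str:
    """Hill-order formula string (C, H, then alphabetical); '' for empty."""
    items = {el: n for el, n in counts.items() if n}
    ordered = [el for el in ("C", "H") if el in items]
    ordered += sorted(el for el in items if el not in ("C", "H"))
    return "".join(f"{el}{items[el] if items[el] != 1 else ''}" for el in ordered)


def monoisotopic_mass(counts: Mapping[str, int], charge_protons: int = 0) -> float:
    """Monoisotopic mass (Da) of a formula, optionally protonated.

    ``charge_protons`` > 0 adds that many protons and subtracts the matching
    electron masses, yielding the ion m/z for charge = charge_protons.  The
    electron mass matters at the fourth decimal against printed diagnostic
    ions, so it is not neglected.
    """
    if charge_protons < 0:
        raise ValueError("charge_protons must be >= 0")
    mass = 0.0
    for el, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for element {el}")
        if el not in MONOISOTOPIC:
            raise ValueError(f"unsupported element {el}")
        mass += MONOISOTOPIC[el] * n
    mass += charge_protons * (PROTON_MASS)
    if charge_protons:
        return mass / charge_protons
    return mass


def ion_mz(counts: Mapping[str, int], charge: int = 1) -> float:
    """m/z of the [M+zH]z+ ion of a neutral formula."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (monoisotopic_mass(counts) + charge * PROTON_MASS) / charge


#: [M+H]+ of free carnitine, the reference point for every delta mass.
CARNITINE_MH = ion_mz(CARNITINE)


def compute_delta_mass(precursor_mz: float, charge: int = 1) -> float:
    """Delta mass: precursor ion mass minus the carnitine core [M+H]+ mass.

    Only singly protonated precursors are in scope (the quaternary ammonium
    of carnitine gives [M+H]+ ions); other charges raise.  A delta below
    -0.02 Da (precursor lighter than carnitine) is flagged invalid.
    """
    if charge != 1:
        raise ValueError("only charge 1 ([M+H]+) precursors are supported")
    delta = precursor_mz - CARNITINE_MH
    if delta < -0.02:
        raise ValueError(
            f"precursor {precursor_mz:.4f} below the carnitine core "
            f"({CARNITINE_MH:.4f}); not a carnitine conjugate"
        )
    return delta


def canonical_delta_key(delta: float) -> float:
    """Canonical 2-decimal delta-mass key (round-half-even)."""
    return round(delta, 2)


def mass_defect(delta: float) -> float:
    """Difference between a mass and its nearest integer, in (-0.5, 0.5]."""
    nearest = math.ceil(delta - 0.5)  # half-integer ties map to +0.5
    return delta - nearest


def delta_formula_from_precursor(
    precursor_formula: Mapping[str, int],
) -> ElementCounts | None:
    """Element-wise subtraction of the carnitine core from a precursor formula.

    Returns None when any element count would go negative (the precursor
    cannot contain the carnitine core).
    """
    delta: ElementCounts = dict(precursor_formula)
    for el, n in CARNITINE.items():
        delta[el] = delta.get(el, 0) - n
    if any(v < 0 for v in delta.values()):
        return None
    return {el: n for el, n in delta.items() if n}


def assign_car_nomenclature(delta: Mapping[str, int]) -> str | None:
    """Lipid-style ``CAR Cx:y;Oz`` label for a CHO-only acyl delta.

    x is the acyl carbon count, y the chain unsaturations and z the extra
    oxygens beyond the ester oxygen.  The ester carbonyl is not counted as
    an unsaturation, so acetylation (C2H2O) is ``CAR C2:0``.  Returns None
    for non-CHO deltas or inconsistent arithmetic (that is the signal, not
    an error).
    """
    counts = {el: n for el, n in delta.items() if n}
    if not counts or any(el not in ("C", "H", "O") for el in counts):
        return None
    c = counts.get("C", 0)
    h = counts.get("H", 0)
    o = counts.get("O", 0)
    if c < 2 or o < 1:
        return None
    y = c - h / 2 - 1
    if y < 0 or y != int(y):
        return None
    y = int(y)
    z = o - 1
    if z == 0:
        return f"CAR C{c}:{y}"
    if z == 1:
        return f"CAR C{c}:{y};O"
    return f"CAR C{c}:{y};O{z}"


def composition_class(delta: Mapping[str, int] | None) -> str:
    """Atom-combination class of a delta formula, e.g. CHO, CHNO, CHOS."""
    if delta is None:
        return "unassigned"
    present = [el for el, n in delta.items() if n]
    ordered = [el for el in ("C", "H", "N", "O") if el in present]
    ordered += sorted(el for el in present if el not in ("C", "H", "N", "O"))
    return "".join(ordered) if ordered else "none"


def decompose_delta(
    delta: float,
    tol_ppm: float = 5.0,
    element_bounds: Mapping[str, tuple[int, int]] | None = None,
    rdbe_range: tuple[float, float] = (-0.5, 40.0),
) -> list[ElementCounts]:
    """Enumerate elemental compositions for a delta mass by brute force.

    Candidate delta formulas are searched within ``element_bounds``
    (default CHNO with modest ranges); a candidate is accepted when the
    implied precursor mass (carnitine + candidate, [M+H]+) lies within
    ``tol_ppm`` of the precursor implied by ``delta``, and the ring-and-
    double-bond equivalent of the full precursor formula falls in
    ``rdbe_range``.  Results are sorted by absolute mass error.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if element_bounds is None:
        element_bounds = {"C": (0, 30), "H": (0, 60), "N": (0, 3), "O": (0, 10)}
    for el in element_bounds:
        if el not in MONOISOTOPIC:
            raise ValueError(f"unsupported element {el}")
    target_precursor = CARNITINE_MH + delta
    tol_da = tol_ppm * 1e-6 * target_precursor

    elements = list(element_bounds)
    ranges = [range(lo, hi + 1) for lo, hi in element_bounds.values()]
    out: list[tuple[float, ElementCounts]] = []
    for combo in itertools.product(*ranges):
        counts = {el: n for el, n in zip(elements, combo) if n}
        mass = sum(MONOISOTOPIC[el] * n for el, n in counts.items())
        err = mass - delta
        if abs(err) > tol_da:
            continue
        full = dict(CARNITINE)
        for el, n in counts.items():
            full[el] = full.get(el, 0) + n
        rdbe = (
            full.get("C", 0)
            - (full.get("H", 0) + full.get("F", 0) + full.get("Cl", 0)
               + full.get("Br", 0) + full.get("I", 0)) / 2
            + (full.get("N", 0) + full.get("P", 0)) / 2
            + 1
        )
        if not (rdbe_range[0] <= rdbe <= rdbe_range[1]):
            continue
        out.append((abs(err), counts))
    out.sort(key=lambda pair: (pair[0], formula_string(pair[1])))
    return [counts for _, counts in out]


@dataclass
class LibraryEntry:
    """A curated library spectrum: representative + delta mass + support."""

    representative: Spectrum
    delta_mass: float
    delta_key: float
    supporting_datasets: set[str]
    delta_formula: ElementCounts | None = None
    car_name: str | None = None
    composition_class: str = "unassigned"

    @property
    def spectrum_id(self) -> str:
        return self.representative.spectrum_id


def build_library(
    assignments: Mapping[str, Sequence[str]],
    spectra: Mapping[str, Spectrum],
    min_datasets: int = 2,
    delta_formulas: Mapping[str, Mapping[str, int]] | None = None,
) -> list[LibraryEntry]:
    """Build a delta-mass library from cluster representatives.

    ``assignments`` maps each representative spectrum id to its cluster's
    member ids; ``spectra`` resolves ids to spectra carrying dataset
    provenance.  Each entry's supporting datasets are the union over its
    cluster members; entries whose canonical 2-decimal delta key is
    supported by fewer than ``min_datasets`` distinct datasets *across the
    whole library* are dropped.  Optional ``delta_formulas`` (representative
    id -> delta element counts) attach formulas, CAR names and composition
    classes.
    """
    entries: list[LibraryEntry] = []
    for rep_id, member_ids in assignments.items():
        rep = spectra[rep_id]
        try:
            delta = compute_delta_mass(rep.precursor_mz, charge=1)
        except ValueError:
            continue  # precursor below the carnitine core: flagged invalid
        datasets = {
            spectra[mid].dataset_id for mid in member_ids if spectra[mid].dataset_id
        }
        formula = dict(delta_formulas[rep_id]) if delta_formulas and rep_id in delta_formulas else None
        entries.append(
            LibraryEntry(
                representative=rep,
                delta_mass=delta,
                delta_key=canonical_delta_key(delta),
                supporting_datasets=datasets,
                delta_formula=formula,
                car_name=assign_car_nomenclature(formula) if formula else None,
                composition_class=composition_class(formula),
            )
        )
    support: dict[float, set[str]] = {}
    for entry in entries:
        support.setdefault(entry.delta_key, set()).update(entry.supporting_datasets)
    return [e for e in entries if len(support[e.delta_key]) >= min_datasets]


def chain_length_category(x: int) -> str:
    """Acyl chain-length bracket: short C2-C6, medium C7-C12, long C13-C21,
    very long C22-C30; anything else is out_of_range."""
    if not isinstance(x, (int,)) or isinstance(x, bool):
        raise TypeError("carbon count must be an integer")
    if x < 0:
        raise ValueError("carbon count must be >= 0")
    if 2 <= x <= 6:
        return "short"
    if 7 <= x <= 12:
        return "medium"
    if 13 <= x <= 21:
        return "long"
    if 22 <= x <= 30:
        return "very_long"
    return "out_of_range"
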