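"""Greedy one-to-one fragment peak matching shared by all similarity scores.

Candidate peak pairs within a Da tolerance of an allowed m/z shift are
collected, sorted by descending product of intensity weights, and assigned
greedily with each peak used at most once — the convention of classical
molecular-networking cosine implementations.
"""

from __future__ import annotations

import numpy as np

from .spectra_io import Spectrum


def weight(intensity: np.ndarray, intensity_power: float) -> np.ndarray:
    return np.power(np.asarray(intensity, float), intensity_power)


def candidate_pairs(
    mz_a: np.ndarray,
    mz_b: np.ndarray,
    fragment_tol_da: float,
    shifts: tuple[float, ...],
) -> list[tuple[int, int]]:
    """All (i, j) index pairs with |mz_a[i] - (mz_b[j] + shift)| <= tol."""
    pairs: set[tuple[int, int]] = set()
    for shift in shifts:
        shifted = mz_b + shift
        lo = np.searchsorted(mz_a, shifted - fragment_tol_da, side="left")
        hi = np.searchsorted(mz_a, shifted + fragment_tol_da, side="right")
        for j, (l, h) in enumerate(zip(lo, hi)):
            for i in range(l, h):
                pairs.add((i, j))
    return sorted(pairs)


def greedy_match(
    a: Spectrum,
    b: Spectrum,
    fragment_tol_da: float,
    shifts: tuple[float, ...] = (0.0,),
    intensity_power: float = 0.5,
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Greedy one-to-one matching; returns (matched index pairs, wa, wb)."""
    wa = weight(a.intensity, intensity_power)
    wb = weight(b.intensity, intensity_power)
    pairs = candidate_pairs(a.mz, b.mz, fragment_tol_da, shifts)
    # stable order: product desc, then indices, so scores are deterministic
    pairs.sort(key=lambda ij: (-wa[ij[0]] * wb[ij[1]], ij))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched: list[tuple[int, int]] = []
    for i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    return matched, wa, wb


def cosine_from_match(
    matched: list[tuple[int, int]], wa: np.ndarray, wb: np.ndarray
) -> float:
    norm = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    if norm == 0.0:
        return 0.0
    num = sum(float(wa[i] * wb[j]) for i, j in matched)
    return min(num / norm, 1.0)
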