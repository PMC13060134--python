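import itertools

import numpy as np
import pytest

from carnlib.spectra_io import Spectrum


def make_spectrum(
    spectrum_id="s",
    precursor_mz=200.0,
    peaks=((100.0, 50.0), (120.0, 100.0)),
    **kwargs,
):
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    return Spectrum(spectrum_id, precursor_mz, mz, inten, **kwargs)


@pytest.fixture
def spectrum_factory():
    return make_spectrum


def random_peak_pair(rng, n_a=None, n_b=None, n_shared=None, precursor_delta=0.0):
    """A random spectrum pair sharing some peaks.

    Peak positions are well separated relative to typical tolerances, so
    greedy and optimal matchings coincide and oracles are unambiguous.
    ``precursor_delta`` offsets b's precursor (its peaks stay unshifted),
    which gives modified cosine both shift channels to consider.
    """
    n_a = n_a if n_a is not None else int(rng.integers(2, 7))
    n_b = n_b if n_b is not None else int(rng.integers(2, 7))
    n_shared = n_shared if n_shared is not None else int(rng.integers(1, min(n_a, n_b) + 1))
    # draw well-separated m/z values (>= 1 Da apart)
    grid = rng.choice(np.arange(60, 600), size=n_a + n_b - n_shared, replace=False)
    grid = np.sort(grid.astype(float)) + rng.uniform(-0.2, 0.2, grid.size)
    mz_a = grid[:n_a]
    mz_b = np.concatenate([mz_a[:n_shared] + rng.uniform(-0.005, 0.005, n_shared), grid[n_a:]])
    ia = rng.uniform(1.0, 100.0, n_a)
    ib = rng.uniform(1.0, 100.0, n_b)
    a = make_spectrum("a", 300.0, list(zip(mz_a, ia)))
    b = make_spectrum("b", 300.0 - precursor_delta, list(zip(mz_b, ib)))
    return a, b


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation's matching code)

def oracle_candidate_pairs(a, b, tol, shifts):
    pairs = []
    for i, ma in enumerate(a.mz):
        for j, mb in enumerate(b.mz):
            if any(abs(ma - (mb + s)) <= tol for s in shifts):
                pairs.append((i, j))
    return pairs


def _best_matching(pairs, wa, wb):
    """Exhaustive maximum over all one-to-one matchings of candidate pairs."""
    best_num = 0.0
    best_match = []

    def recurse(idx, used_a, used_b, num, match):
        nonlocal best_num, best_match
        if num > best_num:
            best_num, best_match = num, list(match)
        if idx == len(pairs):
            return
        # bound: remaining pairs can only add; explore all subsets
        for k in range(idx, len(pairs)):
            i, j = pairs[k]
            if i in used_a or j in used_b:
                continue
            match.append((i, j))
            recurse(k + 1, used_a | {i}, used_b | {j}, num + wa[i] * wb[j], match)
            match.pop()

    recurse(0, frozenset(), frozenset(), 0.0, [])
    return best_num, best_match


def oracle_cosine(a, b, tol, shifts=(0.0,), power=0.5):
    """Exhaustive-optimal matched cosine score and matched-peak count."""
    wa = np.power(a.intensity, power)
    wb = np.power(b.intensity, power)
    pairs = oracle_candidate_pairs(a, b, tol, shifts)
    num, match = _best_matching(pairs, wa, wb)
    norm = np.linalg.norm(wa) * np.linalg.norm(wb)
    return (num / norm if norm else 0.0), len(match)


def oracle_reverse_cosine(a, b, tol, power=0.5):
    """Reverse score on the product-maximizing matching."""
    wa = np.power(a.intensity, power)
    wb = np.power(b.intensity, power)
    pairs = oracle_candidate_pairs(a, b, tol, (0.0,))
    num, match = _best_matching(pairs, wa, wb)
    if not match:
        return 0.0, 0
    q_norm = np.sqrt(sum(wa[i] ** 2 for i, _ in match))
    norm = q_norm * np.linalg.norm(wb)
    return (num / norm if norm else 0.0), len(match)


def oracle_query_pass(spectrum, conditions):
    """Brute-force predicate scan over all peaks for an AND ion query."""
    if spectrum.n_peaks == 0:
        return False
    base = spectrum.intensity.max()
    for target, ppm, pct in conditions:
        tol = target * ppm * 1e-6
        ok = any(
            abs(mz - target) <= tol and inten >= pct * base / 100.0
            for mz, inten in zip(spectrum.mz, spectrum.intensity)
        )
        if not ok:
            return False
    return True
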