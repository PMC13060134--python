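"""Synthetic spectra collections and feature tables with known ground truth.

The generator emulates the statistical structure of multi-dataset public
repository collections of acylcarnitine MS/MS spectra: homologous
delta-mass series planted across several datasets, the three positive-mode
diagnostic ions (m/z 60.0808, 85.0284, 144.1019) with analyte-specific
relative intensities, carnitine-core neutral-loss fragments so that
structural analogs form modified-cosine pairs, and three decoy classes —

(a) non-carnitine spectra lacking at least one diagnostic ion,
(b) spectra carrying all three ions but with the 85.0284 ion well below
    the 50% relative-intensity threshold (the internal-fragmentation
    failure mode of hydroxylated acyl chains), and
(c) constructed chance-pass spectra that satisfy the diagnostic query
    despite not being carnitines, planted at a fixed rate so the query's
    false discovery rate is exactly known.

Everything is deterministic under a fixed seed (numpy Generator /
SeedSequence; per-delta fragmentation profiles derive from a CRC32 of the
formula string so they are stable across runs and platforms).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import (
    CARNITINE,
    PROTON_MASS,
    ElementCounts,
    canonical_delta_key,
    formula_string,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
)
from .diagnostic_query import DIAGNOSTIC_IONS
from .spectra_io import FeatureTable, Spectrum

__all__ = [
    "SimConfig",
    "GroundTruth",
    "GroundTruthRecord",
    "DEFAULT_ACYL_SET",
    "simulate_acylcarnitine_spectrum",
    "simulate_repository",
    "simulate_timecourse",
]

#: Loss of trimethylamine N(CH3)3, the classic carnitine neutral loss.
TMA_LOSS = monoisotopic_mass({"C": 3, "H": 9, "N": 1})
PROTON = PROTON_MASS

#: Twenty acyl delta formulas: a saturated chain-length series plus
#: unsaturated and hydroxylated members (CAR Cx:y;Oz space).  Members are
#: chosen so every delta mass sits > ~2.5 mDa away from a two-decimal
#: rounding boundary: the canonical key of a planted delta must be
#: identifiable at realistic instrument mass accuracy, otherwise ground
#: truth itself would be ambiguous.
DEFAULT_ACYL_SET: tuple[str, ...] = (
    "C2H2O", "C4H6O", "C5H8O", "C7H12O", "C9H16O", "C11H20O",
    "C14H26O", "C16H30O", "C18H34O",
    "C6H8O", "C8H12O", "C10H16O", "C12H20O", "C18H30O",
    "C6H10O2", "C8H14O2", "C10H18O2", "C12H22O2", "C16H28O2", "C18H32O2",
)


@dataclass(frozen=True)
class SimConfig:
    """Conditions for a simulated repository.

    Defaults describe a desk-scale collection: 6 datasets, 20 planted acyl
    deltas each observed in 2-4 datasets with 3-5 spectra per
    dataset, equal numbers of decoys (decoy_fraction 0.5) of which 2% are
    constructed chance-passes, 3 ppm mass accuracy and 5 low-intensity
    noise peaks per spectrum.
    """

    n_datasets: int = 6
    acyl_set: tuple[str, ...] = DEFAULT_ACYL_SET
    datasets_per_delta: tuple[int, int] = (2, 4)
    spectra_per_dataset: tuple[int, int] = (3, 5)
    decoy_fraction: float = 0.5
    chance_pass_rate: float = 0.02  # class-(c) fraction of decoys
    low_85_fraction: float = 0.3  # class-(b) fraction of decoys
    diagnostic_intensity_ranges: tuple[tuple[float, float], ...] = (
        (5.0, 40.0),   # 60.0808
        (55.0, 100.0), # 85.0284
        (5.0, 60.0),   # 144.1019
    )
    acyl_fragment_range: tuple[float, float] = (10.0, 50.0)
    tma_loss_range: tuple[float, float] = (5.0, 30.0)
    precursor_peak_range: tuple[float, float] = (2.0, 10.0)
    intensity_jitter: float = 0.08  # relative sd around the analyte profile
    mz_noise_ppm: float = 3.0
    n_noise_peaks: int = 5
    noise_intensity_range: tuple[float, float] = (0.5, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.decoy_fraction, self.chance_pass_rate, self.low_85_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.chance_pass_rate + self.low_85_fraction > 1.0:
            raise ValueError("decoy class fractions exceed 1")
        if self.n_datasets < 1:
            raise ValueError("need at least one dataset")


@dataclass(frozen=True)
class GroundTruthRecord:
    is_carnitine: bool
    delta_formula: str | None
    delta_mass: float | None
    dataset_id: str
    decoy_class: str | None = None  # 'a' | 'b' | 'c' for decoys


@dataclass
class GroundTruth:
    """Per-spectrum truth labels covering every generated spectrum."""

    records: dict[str, GroundTruthRecord] = field(default_factory=dict)

    def labels(self) -> dict[str, bool]:
        """spectrum id -> is_target, for FDR estimation."""
        return {sid: rec.is_carnitine for sid, rec in self.records.items()}

    def planted_delta_keys(self, min_datasets: int = 2) -> set[float]:
        """Canonical 2-decimal delta keys planted in >= min_datasets datasets."""
        support: dict[float, set[str]] = {}
        for rec in self.records.values():
            if rec.is_carnitine and rec.delta_mass is not None:
                support.setdefault(canonical_delta_key(rec.delta_mass), set()).add(
                    rec.dataset_id
                )
        return {k for k, ds in support.items() if len(ds) >= min_datasets}

    def decoy_ids(self, decoy_class: str | None = None) -> set[str]:
        return {
            sid
            for sid, rec in self.records.items()
            if not rec.is_carnitine
            and (decoy_class is None or rec.decoy_class == decoy_class)
        }

    def annotations(self, carnitine_stride: int = 5) -> dict[str, str]:
        """Compound labels as an annotation table would provide them.

        All decoys are labeled with their (non-carnitine) compound class;
        every ``carnitine_stride``-th carnitine spectrum is labeled
        'acylcarnitine' (reference libraries only cover part of the space).
        """
        class_labels = {"a": "phosphatidylcholine", "b": "bile acid", "c": "flavonoid"}
        out: dict[str, str] = {}
        carn_seen = 0
        for sid in sorted(self.records):
            rec = self.records[sid]
            if not rec.is_carnitine:
                out[sid] = class_labels[rec.decoy_class or "a"]
            else:
                if carn_seen % carnitine_stride == 0:
                    out[sid] = "acylcarnitine"
                carn_seen += 1
        return out


def _delta_profile(delta_name: str, config: SimConfig) -> dict[str, float]:
    """Analyte-specific mean fragment intensities, stable across runs."""
    entropy = zlib.crc32(delta_name.encode("utf8"))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, entropy]))
    lo_hi = config.diagnostic_intensity_ranges
    return {
        "d60": float(rng.uniform(*lo_hi[0])),
        "d85": float(rng.uniform(*lo_hi[1])),
        "d144": float(rng.uniform(*lo_hi[2])),
        "acyl": float(rng.uniform(*config.acyl_fragment_range)),
        "tma": float(rng.uniform(*config.tma_loss_range)),
        "prec": float(rng.uniform(*config.precursor_peak_range)),
    }


def _jitter_mz(mz: float, rng: np.random.Generator, ppm: float) -> float:
    if ppm <= 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, ppm * 1e-6))


def simulate_acylcarnitine_spectrum(
    delta_formula: Mapping[str, int] | str,
    config: SimConfig,
    rng: np.random.Generator,
    spectrum_id: str = "sim",
    dataset_id: str = "",
    file_id: str = "",
    scan: int = -1,
    profile: Mapping[str, float] | None = None,
) -> Spectrum:
    """One synthetic acylcarnitine MS/MS spectrum.

    The precursor is the [M+H]+ of carnitine + the acyl delta with ppm
    noise; peaks comprise the three diagnostic ions, an acylium-like
    fragment at monoisotopic(delta) + proton, the trimethylamine
    neutral-loss fragment, a residual precursor peak, and
    ``config.n_noise_peaks`` random low-intensity peaks.  Intensities are
    drawn around the analyte's fragmentation profile and the base peak is
    normalized to 100.
    """
    delta = parse_formula(delta_formula) if isinstance(delta_formula, str) else dict(delta_formula)
    if any(v < 0 for v in delta.values()):
        raise ValueError("negative element counts in delta formula")
    name = formula_string(delta)
    total = dict(CARNITINE)
    for el, n in delta.items():
        total[el] = total.get(el, 0) + n
    precursor_exact = ion_mz(total)
    prof = dict(profile) if profile is not None else _delta_profile(name, config)

    jit = lambda mean: max(mean * (1.0 + rng.normal(0.0, config.intensity_jitter)), 0.1)
    peaks: list[tuple[float, float]] = [
        (_jitter_mz(DIAGNOSTIC_IONS[0], rng, config.mz_noise_ppm), jit(prof["d60"])),
        (_jitter_mz(DIAGNOSTIC_IONS[1], rng, config.mz_noise_ppm), jit(prof["d85"])),
        (_jitter_mz(DIAGNOSTIC_IONS[2], rng, config.mz_noise_ppm), jit(prof["d144"])),
    ]
    if delta:
        acyl_mz = monoisotopic_mass(delta) + PROTON
        if acyl_mz > 50.0:
            peaks.append((_jitter_mz(acyl_mz, rng, config.mz_noise_ppm), jit(prof["acyl"])))
    tma_mz = precursor_exact - TMA_LOSS
    if tma_mz > 50.0:
        peaks.append((_jitter_mz(tma_mz, rng, config.mz_noise_ppm), jit(prof["tma"])))
    peaks.append((_jitter_mz(precursor_exact, rng, config.mz_noise_ppm), jit(prof["prec"])))
    for _ in range(config.n_noise_peaks):
        peaks.append(
            (
                float(rng.uniform(50.0, max(precursor_exact - 1.0, 51.0))),
                float(rng.uniform(*config.noise_intensity_range)),
            )
        )
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    inten = inten / inten.max() * 100.0
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=_jitter_mz(precursor_exact, rng, config.mz_noise_ppm),
        mz=mz,
        intensity=inten,
        dataset_id=dataset_id,
        file_id=file_id,
        scan=scan,
        acquisition="DDA",
    )


def _random_peaks(
    rng: np.random.Generator, n: int, mz_range: tuple[float, float]
) -> list[tuple[float, float]]:
    return [
        (float(rng.uniform(*mz_range)), float(rng.uniform(1.0, 100.0)))
        for _ in range(n)
    ]


def _decoy_spectrum(
    decoy_class: str,
    config: SimConfig,
    rng: np.random.Generator,
    spectrum_id: str,
    dataset_id: str,
    file_id: str,
) -> Spectrum:
    precursor = float(rng.uniform(180.0, 550.0))
    peaks: list[tuple[float, float]] = []
    if decoy_class == "a":
        # missing at least one diagnostic ion
        n_present = int(rng.integers(0, 3))
        which = rng.permutation(3)[:n_present]
        for k in which:
            peaks.append(
                (_jitter_mz(DIAGNOSTIC_IONS[k], rng, config.mz_noise_ppm),
                 float(rng.uniform(5.0, 100.0)))
            )
        peaks += _random_peaks(rng, 8, (50.0, precursor))
        peaks.append((float(rng.uniform(50.0, precursor)), 100.0))
    elif decoy_class == "b":
        # all three ions, 85.0284 well below the 50% threshold
        peaks.append((float(rng.uniform(150.0, precursor)), 100.0))  # base peak
        peaks.append(
            (_jitter_mz(DIAGNOSTIC_IONS[0], rng, config.mz_noise_ppm),
             float(rng.uniform(2.0, 30.0)))
        )
        peaks.append(
            (_jitter_mz(DIAGNOSTIC_IONS[1], rng, config.mz_noise_ppm),
             float(rng.uniform(5.5, 45.0)))
        )
        peaks.append(
            (_jitter_mz(DIAGNOSTIC_IONS[2], rng, config.mz_noise_ppm),
             float(rng.uniform(2.0, 30.0)))
        )
        peaks += _random_peaks(rng, 4, (50.0, precursor))
        # keep the planted base peak dominant so ratios stay in class
        peaks = [(m, min(i, 100.0)) for m, i in peaks]
    elif decoy_class == "c":
        # constructed chance-pass: satisfies the default query
        peaks.append(
            (_jitter_mz(DIAGNOSTIC_IONS[0], rng, config.mz_noise_ppm),
             float(rng.uniform(5.0, 40.0)))
        )
        peaks.append(
            (_jitter_mz(DIAGNOSTIC_IONS[1], rng, config.mz_noise_ppm), 100.0)
        )
        peaks.append(
            (_jitter_mz(DIAGNOSTIC_IONS[2], rng, config.mz_noise_ppm),
             float(rng.uniform(5.0, 60.0)))
        )
        peaks += _random_peaks(rng, 5, (50.0, precursor))
        peaks = [(m, min(i, 100.0)) for m, i in peaks]
    else:
        raise ValueError(f"unknown decoy class {decoy_class!r}")
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    inten = inten / inten.max() * 100.0
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor,
        mz=mz,
        intensity=inten,
        dataset_id=dataset_id,
        file_id=file_id,
        acquisition="DDA",
    )


def simulate_repository(config: SimConfig) -> tuple[list[Spectrum], GroundTruth]:
    """A multi-dataset spectra collection with labeled ground truth.

    Each planted acyl delta appears in a drawn number of datasets (several
    spectra per dataset, each from a distinct file); decoys are appended in
    classes (a)/(b)/(c), with the class-(c) chance-pass count fixed at
    round(chance_pass_rate x n_decoys) so the planted query FDR is exactly
    known.  Fully deterministic under config.seed.
    """
    if not config.acyl_set:
        raise ValueError("acyl_set must not be empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
    datasets = [f"D{i + 1}" for i in range(config.n_datasets)]
    spectra: list[Spectrum] = []
    truth = GroundTruth()

    counter = 0
    for formula in config.acyl_set:
        delta = parse_formula(formula)
        delta_mass = monoisotopic_mass(delta)
        lo, hi = config.datasets_per_delta
        k = int(rng.integers(lo, hi + 1))
        k = min(k, config.n_datasets)
        chosen = [datasets[i] for i in rng.permutation(config.n_datasets)[:k]]
        profile = _delta_profile(formula_string(delta), config)
        for ds in chosen:
            m_lo, m_hi = config.spectra_per_dataset
            for local in range(int(rng.integers(m_lo, m_hi + 1))):
                sid = f"carn{counter:05d}"
                counter += 1
                spectra.append(
                    simulate_acylcarnitine_spectrum(
                        delta,
                        config,
                        rng,
                        spectrum_id=sid,
                        dataset_id=ds,
                        file_id=f"{ds}-{sid}.mzML",
                        scan=counter,
                        profile=profile,
                    )
                )
                truth.records[sid] = GroundTruthRecord(
                    True, formula_string(delta), delta_mass, ds
                )

    n_carn = counter
    if config.decoy_fraction > 0:
        n_decoys = int(round(config.decoy_fraction / (1 - config.decoy_fraction) * n_carn)) \
            if config.decoy_fraction < 1 else 0
        n_c = int(round(config.chance_pass_rate * n_decoys))
        n_b = int(round(config.low_85_fraction * n_decoys))
        classes = ["c"] * n_c + ["b"] * n_b + ["a"] * (n_decoys - n_c - n_b)
        for d, decoy_class in enumerate(classes):
            sid = f"decoy{d:05d}"
            ds = datasets[int(rng.integers(0, config.n_datasets))]
            spectra.append(
                _decoy_spectrum(
                    decoy_class, config, rng, sid, ds, f"{ds}-{sid}.mzML"
                )
            )
            truth.records[sid] = GroundTruthRecord(False, None, None, ds, decoy_class)
    return spectra, truth


def simulate_timecourse(
    n_features: int,
    tissues: Sequence[str],
    timepoints: Sequence[float],
    planted_groups: Sequence[tuple[str, int, Sequence[float]]],
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> tuple[FeatureTable, list[tuple[str, set[str]]]]:
    """Feature table with planted synchronized time-course groups.

    ``planted_groups`` is a list of (tissue, member count, template curve
    over the timepoints).  Members of a group share the template up to a
    positive affine rescaling plus independent additive noise
    (noise_sd relative to the template scale); all other features follow
    independent smooth random curves.  Returns the table and the planted
    (tissue, member id set) ground truth.
    """
    if len(timepoints) < 3:
        raise ValueError("need at least 3 timepoints")
    rng = np.random.default_rng(seed)
    feature_ids = [f"F{i:04d}" for i in range(n_features)]

    sample_rows = []
    for tissue in tissues:
        for t in timepoints:
            for r in range(n_replicates):
                sample_rows.append(
                    {
                        "sample_id": f"{tissue}_t{t}_r{r}",
                        "tissue": tissue,
                        "timepoint": float(t),
                        "group": "timecourse",
                        "is_blank": False,
                    }
                )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")

    n_t = len(timepoints)
    profiles: dict[tuple[str, str], np.ndarray] = {}
    truth: list[tuple[str, set[str]]] = []
    next_member = 0
    for tissue, count, template in planted_groups:
        if tissue not in tissues:
            raise ValueError(f"planted tissue {tissue!r} not in tissues")
        template = np.asarray(template, dtype=float)
        if template.shape != (n_t,):
            raise ValueError("template length must match timepoints")
        members = set()
        for _ in range(count):
            if next_member >= n_features:
                raise ValueError("not enough features for planted groups")
            fid = feature_ids[next_member]
            next_member += 1
            scale = float(rng.uniform(0.5, 2.0))
            offset = float(rng.uniform(0.0, 0.2) * template.mean())
            curve = template * scale + offset
            curve = curve + rng.normal(0.0, noise_sd * max(template.mean(), 1e-9), n_t)
            profiles[(tissue, fid)] = np.clip(curve, 0.0, None)
            members.add(fid)
        truth.append((tissue, members))

    for tissue in tissues:
        for fid in feature_ids:
            if (tissue, fid) in profiles:
                continue
            base = float(rng.uniform(10.0, 100.0))
            walk = np.cumsum(rng.normal(0.0, 0.3, n_t))
            curve = base * np.exp(walk - walk.mean())
            curve = curve + rng.normal(0.0, noise_sd * base, n_t)
            profiles[(tissue, fid)] = np.clip(curve, 0.0, None)

    matrix = pd.DataFrame(index=feature_ids, columns=samples.index, dtype=float)
    for sid, row in samples.iterrows():
        t_idx = list(timepoints).index(row["timepoint"])
        for fid in feature_ids:
            value = profiles[(row["tissue"], fid)][t_idx]
            if n_replicates > 1 and noise_sd > 0:
                value = max(value + rng.normal(0.0, noise_sd * max(value, 1e-9)), 0.0)
            matrix.loc[fid, sid] = value

    features = pd.DataFrame(
        {
            "mz": rng.uniform(150.0, 500.0, n_features),
            "rt": rng.uniform(0.5, 7.5, n_features),
            "annotation": [None] * n_features,
        },
        index=feature_ids,
    )
    return FeatureTable(matrix=matrix, features=features, samples=samples), truth
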