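"""Reading and writing MS/MS spectra and feature tables.

The working spectrum format is MGF (one ``BEGIN IONS``/``END IONS`` block per
centroided MS/MS scan).  Provenance of each scan — which repository dataset
and raw file it came from, and whether it was acquired in data-dependent or
data-independent mode — travels in MGF header keys (``DATASET``, ``FILENAME``,
``SCANS``, ``ACQUISITION``, ``IONMODE``) so that downstream multi-dataset
support filters and DIA exclusion can operate on merged files.

mzML input is supported read-only for centroided spectra; quantitative
feature tables (features x samples) and their sample metadata are read from
delimited text into a :class:`FeatureTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import base64
import zlib
from xml.etree import ElementTree

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

__all__ = [
    "Spectrum",
    "FeatureTable",
    "MGFParseError",
    "read_mgf",
    "write_mgf",
    "read_mzml",
    "read_feature_table",
]

#: Recognised acquisition-mode labels.
ACQUISITIONS = ("DDA", "DIA", "unknown")
ION_MODES = ("positive", "negative", "unknown")


class MGFParseError(ValueError):
    """Raised when an MGF block cannot be interpreted."""


@dataclass(frozen=True)
class Spectrum:
    """One centroided MS/MS scan with precursor info and provenance.

    Peaks are stored as parallel numpy arrays sorted ascending by m/z.
    Intensities are arbitrary units >= 0; ``charge`` defaults to 1
    (positive-mode [M+H]+ scope).
    """

    spectrum_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int = 1
    dataset_id: str = ""
    file_id: str = ""
    scan: int = -1
    acquisition: str = "unknown"
    ion_mode: str = "positive"

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        order = np.argsort(mz, kind="stable")
        mz = mz[order]
        inten = inten[order]
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if self.precursor_mz <= 0 or not math.isfinite(self.precursor_mz):
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if mz.size and mz[0] <= 0:
            raise ValueError("all peak m/z must be positive")
        if np.any(inten < 0):
            raise ValueError("peak intensities must be non-negative")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.acquisition not in ACQUISITIONS:
            raise ValueError(f"acquisition must be one of {ACQUISITIONS}")
        if self.ion_mode not in ION_MODES:
            raise ValueError(f"ion_mode must be one of {ION_MODES}")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    def peaks(self) -> list[tuple[float, float]]:
        """Peak list as (mz, intensity) tuples, ascending in m/z."""
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def with_peaks(self, mz: Sequence[float], intensity: Sequence[float]) -> "Spectrum":
        return replace(self, mz=np.asarray(mz, float), intensity=np.asarray(intensity, float))


@dataclass
class FeatureTable:
    """Feature x sample abundance matrix with feature and sample metadata.

    ``matrix`` holds peak areas (NaN encodes *missing*, distinct from a
    detected zero).  ``features`` is indexed by feature id with columns
    ``mz``, ``rt`` (minutes) and ``annotation``; ``samples`` is indexed by
    sample id with columns ``tissue``, ``timepoint``, ``group``, ``is_blank``.
    """

    matrix: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.matrix.index.equals(self.features.index):
            raise ValueError("matrix rows must match feature metadata index")
        if list(self.matrix.columns) != list(self.samples.index):
            raise ValueError("matrix columns must match sample metadata index")
        if (self.features["rt"].dropna() < 0).any():
            raise ValueError("retention times must be >= 0")
        vals = self.matrix.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("abundances must be >= 0")

    @property
    def all_missing_features(self) -> list[str]:
        """Feature ids whose abundance row is entirely missing."""
        mask = self.matrix.isna().all(axis=1)
        return list(self.matrix.index[mask])

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.matrix.copy(), self.features.copy(), self.samples.copy())


# ---------------------------------------------------------------------------
# MGF

def _first_str(value) -> str:
    if isinstance(value, (list, tuple)):
        return str(value[0]) if value else ""
    return str(value)


def _spectrum_from_mgf_entry(entry: dict, index: int) -> Spectrum:
    params = entry.get("params", {})
    if "pepmass" not in params or params["pepmass"] is None:
        raise MGFParseError(f"MGF block {index}: missing PEPMASS")
    pepmass = params["pepmass"]
    precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
    charge = 1
    if params.get("charge"):
        try:
            charge = abs(int(params["charge"][0]))
        except (TypeError, ValueError, IndexError):
            charge = 1
        charge = max(charge, 1)
    title = _first_str(params.get("title", f"spectrum_{index}"))
    acquisition = _first_str(params.get("acquisition", "unknown")).upper()
    if acquisition not in ("DDA", "DIA"):
        acquisition = "unknown"
    ion_mode = _first_str(params.get("ionmode", "positive")).lower()
    if ion_mode not in ION_MODES:
        ion_mode = "unknown"
    try:
        scan = int(_first_str(params.get("scans", -1)))
    except ValueError:
        scan = -1
    return Spectrum(
        spectrum_id=title,
        precursor_mz=precursor,
        mz=entry["m/z array"],
        intensity=entry["intensity array"],
        charge=charge,
        dataset_id=_first_str(params.get("dataset", "")),
        file_id=_first_str(params.get("filename", "")),
        scan=scan,
        acquisition=acquisition,
        ion_mode=ion_mode,
    )


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`, in file order.

    Provenance keys (DATASET, FILENAME, SCANS, ACQUISITION, IONMODE) are read
    when present and defaulted otherwise.  An empty file yields an empty
    list; a malformed block raises :class:`MGFParseError` naming the block.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    try:
        with _mgf.read(str(path), use_index=False, convert_arrays=1) as reader:
            for i, entry in enumerate(reader):
                try:
                    spectra.append(_spectrum_from_mgf_entry(entry, i))
                except MGFParseError:
                    raise
                except (KeyError, ValueError, TypeError) as exc:
                    raise MGFParseError(f"MGF block {i}: {exc}") from exc
    except MGFParseError:
        raise
    except Exception as exc:  # malformed peak lines surface from pyteomics
        raise MGFParseError(f"MGF block {len(spectra)}: {exc}") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to MGF, losslessly round-trippable by :func:`read_mgf`."""
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "pepmass": s.precursor_mz,
            "charge": f"{s.charge}+",
        }
        if s.dataset_id:
            params["dataset"] = s.dataset_id
        if s.file_id:
            params["filename"] = s.file_id
        if s.scan >= 0:
            params["scans"] = str(s.scan)
        params["acquisition"] = s.acquisition
        params["ionmode"] = s.ion_mode
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    with open(path, "w") as handle:
        _mgf.write(entries, handle)


# ---------------------------------------------------------------------------
# mzML (read-only, centroided MS/MS). A narrow reader for the standard
# centroided layout: uncompressed or zlib base64 arrays, 32/64-bit floats.

_MZML_ACCESSIONS = {
    "MS:1000511": "ms_level",
    "MS:1000127": "centroid",
    "MS:1000128": "profile",
    "MS:1000744": "selected_ion_mz",
    "MS:1000514": "mz_array",
    "MS:1000515": "intensity_array",
    "MS:1000523": "float64",
    "MS:1000521": "float32",
    "MS:1000576": "no_compression",
    "MS:1000574": "zlib",
}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_names(element) -> dict[str, str]:
    out = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            name = _MZML_ACCESSIONS.get(child.get("accession", ""))
            if name:
                out[name] = child.get("value", "")
    return out


def _decode_binary_array(array_element) -> tuple[str | None, np.ndarray]:
    kind = None
    dtype = "<f8"
    decompress = False
    payload = b""
    for child in array_element.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            name = _MZML_ACCESSIONS.get(child.get("accession", ""))
            if name == "mz_array":
                kind = "mz"
            elif name == "intensity_array":
                kind = "intensity"
            elif name == "float32":
                dtype = "<f4"
            elif name == "zlib":
                decompress = True
        elif tag == "binary" and child.text:
            payload = base64.b64decode(child.text)
    if decompress:
        payload = zlib.decompress(payload)
    return kind, np.frombuffer(payload, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read centroided MS2 spectra from an mzML file.

    Profile-mode spectra are rejected with an error; MS1 scans are skipped.
    Only the standard binary encodings (32/64-bit float, uncompressed or
    zlib) are supported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: list[Spectrum] = []
    for i, (_, element) in enumerate(
        filter(
            lambda ev: _local(ev[1].tag) == "spectrum",
            ElementTree.iterparse(str(path), events=("end",)),
        )
    ):
        params = _cv_names(element)
        spectrum_id = element.get("id", f"scan_{i}")
        if params.get("ms_level") != "2":
            element.clear()
            continue
        if "profile" in params:
            raise ValueError(
                f"spectrum {spectrum_id} is profile mode; "
                "only centroided spectra are supported"
            )
        precursor = None
        for child in element.iter():
            if _local(child.tag) == "selectedIon":
                precursor = _cv_names(child).get("selected_ion_mz")
        if precursor is None:
            raise ValueError(f"spectrum {spectrum_id}: no precursor m/z")
        arrays: dict[str, np.ndarray] = {}
        for child in element.iter():
            if _local(child.tag) == "binaryDataArray":
                kind, values = _decode_binary_array(child)
                if kind:
                    arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"spectrum {spectrum_id}: missing peak arrays")
        spectra.append(
            Spectrum(
                spectrum_id=str(spectrum_id),
                precursor_mz=float(precursor),
                mz=arrays["mz"],
                intensity=arrays["intensity"],
                scan=i,
            )
        )
        element.clear()
    return spectra


# ---------------------------------------------------------------------------
# Feature tables

def read_feature_table(
    matrix_path: str | Path,
    metadata_path: str | Path,
    sep: str = "\t",
) -> FeatureTable:
    """Read a features x samples matrix and its sample metadata.

    The matrix file's first column holds feature ids; optional ``mz``, ``rt``
    and ``annotation`` columns are split into feature metadata.  Every sample
    column must have a row in the metadata file (indexed by ``sample_id``
    with ``tissue``, ``timepoint``, ``group``, ``is_blank``); otherwise an
    error lists the missing sample ids.  Empty cells are *missing* (NaN),
    distinct from a literal 0.
    """
    raw = pd.read_csv(matrix_path, sep=sep, index_col=0)
    meta = pd.read_csv(metadata_path, sep=sep, index_col=0)

    feat_cols = [c for c in ("mz", "rt", "annotation") if c in raw.columns]
    features = raw[feat_cols].copy() if feat_cols else pd.DataFrame(index=raw.index)
    for col, default in (("mz", np.nan), ("rt", np.nan), ("annotation", None)):
        if col not in features.columns:
            features[col] = default
    matrix = raw.drop(columns=feat_cols).astype(float)

    missing = [c for c in matrix.columns if c not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    samples = meta.loc[list(matrix.columns)].copy()
    for col, default in (
        ("tissue", ""),
        ("timepoint", np.nan),
        ("group", ""),
        ("is_blank", False),
    ):
        if col not in samples.columns:
            samples[col] = default
    samples["is_blank"] = samples["is_blank"].astype(bool)
    return FeatureTable(matrix=matrix, features=features, samples=samples)
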