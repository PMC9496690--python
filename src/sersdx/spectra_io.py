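"""Spectrum / mapping / clinical-manifest I/O and the shared wavenumber grid.

SERS fingerprints live on a canonical grid of 550-1650 cm^-1 at 1 cm^-1
spacing (1101 points), matching the acquisition range of the CSF study this
pipeline models.  Spectra are exchanged as plain two-column text
(wavenumber, intensity); Raman-mapping exports as four-column text
(x um, y um, wavenumber, intensity) with one spectrum per (x, y) site.
Clinical covariates travel in a manifest CSV with empty cells for missing
values.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GRID_MIN",
    "GRID_MAX",
    "GRID_STEP",
    "canonical_grid",
    "Spectrum",
    "MappingGroup",
    "ClinicalRecord",
    "LABELS",
    "SpectrumFormatError",
    "ManifestError",
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
]

GRID_MIN = 550.0
GRID_MAX = 1650.0
GRID_STEP = 1.0

#: Diagnostic classes: clinically normal, clinically demented, and familial
#: AD mutation carriers (fad_pos) / non-carriers (fad_neg).
LABELS = ("normal", "dementia", "fad_pos", "fad_neg")


def canonical_grid() -> np.ndarray:
    """Return the shared 550-1650 cm^-1 grid at 1 cm^-1 spacing (1101 pts)."""
    n = int(round((GRID_MAX - GRID_MIN) / GRID_STEP)) + 1
    return GRID_MIN + GRID_STEP * np.arange(n)


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum files or invalid spectral data."""


class ManifestError(ValueError):
    """Raised for malformed clinical manifest rows."""


@dataclass(frozen=True)
class Spectrum:
    """One wavenumber/intensity trace.

    Parameters
    ----------
    wavenumbers
        Strictly increasing axis in cm^-1.
    intensities
        Intensity in arbitrary units, same length as ``wavenumbers``.
    meta
        Free-form metadata (sample_id, replicate_id, map x/y in um, ...).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or i.ndim != 1 or w.shape != i.shape:
            raise SpectrumFormatError("wavenumbers and intensities must be 1-D and equal length")
        if w.size < 2:
            raise SpectrumFormatError("a spectrum needs at least two points")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(i))):
            raise SpectrumFormatError("non-finite value in spectrum")
        if np.any(np.diff(w) <= 0):
            raise SpectrumFormatError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", i)

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray, **meta) -> "Spectrum":
        """Copy of this spectrum with new intensities (grid unchanged)."""
        return Spectrum(self.wavenumbers, intensities, {**self.meta, **meta})


@dataclass
class MappingGroup:
    """All spectra from one sample's SERS mapping — the dependency group.

    Spectra acquired across one mapping share the sample's biochemistry, so
    cross-validation must hold out whole groups, never individual spectra.
    """

    sample_id: str
    spectra: list[Spectrum]
    step_size: float = 3.0  # um between map sites

    def __post_init__(self):
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if len(self.spectra) < 1:
            raise ValueError("a mapping group needs at least one spectrum")
        ref = self.spectra[0].wavenumbers
        for s in self.spectra[1:]:
            if s.wavenumbers.shape != ref.shape or not np.allclose(s.wavenumbers, ref):
                raise ValueError(f"spectra in group {self.sample_id!r} are not on one grid")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) intensity array."""
        return np.stack([s.intensities for s in self.spectra])


@dataclass
class ClinicalRecord:
    """One subject's diagnostic label and clinical covariates.

    Aβ42, t-tau and p-tau are CSF biomarker concentrations in pg/mL; MMSE is
    the 0-30 cognitive screen (higher = better); CDRSUM (0-18, 0.5 steps) and
    CDRGLOB (0-3) rate dementia severity (higher = worse).  Optional fields
    are ``None`` when missing.
    """

    sample_id: str
    label: str
    sex: str = "unknown"
    age: float | None = None
    adjusted_age: float | None = None
    abeta42: float | None = None
    t_tau: float | None = None
    p_tau: float | None = None
    mmse: int | None = None
    cdr_sum: float | None = None
    cdr_glob: float | None = None

    def __post_init__(self):
        if self.label not in LABELS:
            raise ManifestError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.sex not in ("M", "F", "unknown"):
            raise ManifestError(f"sex must be M, F or unknown, got {self.sex!r}")
        if self.mmse is not None and not (0 <= self.mmse <= 30):
            raise ManifestError(f"MMSE {self.mmse} outside 0-30")
        if self.cdr_sum is not None:
            if not (0 <= self.cdr_sum <= 18) or (self.cdr_sum * 2) % 1 != 0:
                raise ManifestError(f"CDRSUM {self.cdr_sum} not in 0-18 by 0.5")
        if self.cdr_glob is not None and not (0 <= self.cdr_glob <= 3):
            raise ManifestError(f"CDRGLOB {self.cdr_glob} outside 0-3")


# ---------------------------------------------------------------------------
# spectrum files

def _parse_numeric_rows(path: Path, n_cols: int) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != n_cols:
                raise SpectrumFormatError(
                    f"{path}: line {lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}: line {lineno}: non-numeric value") from exc
    if not rows:
        raise SpectrumFormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def _make_spectrum(wn: np.ndarray, inten: np.ndarray, meta: dict) -> Spectrum:
    order = np.argsort(wn, kind="stable")
    wn, inten = wn[order], inten[order]
    if np.any(np.diff(wn) == 0):
        raise SpectrumFormatError("duplicate wavenumber within one trace")
    return Spectrum(wn, inten, meta)


def read_spectrum(path, dialect: str = "two_column"):
    """Read a spectrum file.

    Parameters
    ----------
    path
        Text file; whitespace- or comma-delimited, ``#`` comments allowed.
    dialect
        ``"two_column"`` (wavenumber, intensity) returns one :class:`Spectrum`;
        ``"map_four_column"`` (x, y, wavenumber, intensity) returns a list of
        Spectrum, one per unique (x, y) site, in row order of first appearance.
    """
    path = Path(path)
    if dialect == "two_column":
        data = _parse_numeric_rows(path, 2)
        return _make_spectrum(data[:, 0], data[:, 1], {"path": str(path)})
    if dialect == "map_four_column":
        data = _parse_numeric_rows(path, 4)
        sites: dict[tuple, list[int]] = {}
        for idx, (x, y) in enumerate(zip(data[:, 0], data[:, 1])):
            sites.setdefault((x, y), []).append(idx)
        spectra = []
        for (x, y), idxs in sites.items():
            sel = data[idxs]
            spectra.append(
                _make_spectrum(sel[:, 2], sel[:, 3], {"x_um": x, "y_um": y, "path": str(path)})
            )
        return spectra
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column text at full precision (round-trips)."""
    with open(path, "w") as fh:
        for w, i in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{float(w)!r} {float(i)!r}\n")


def write_map(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra as a four-column map export, using each spectrum's
    ``x_um``/``y_um`` meta (site index used as a fallback coordinate)."""
    with open(path, "w") as fh:
        for k, s in enumerate(spectra):
            x = float(s.meta.get("x_um", float(k)))
            y = float(s.meta.get("y_um", 0.0))
            for w, i in zip(s.wavenumbers, s.intensities):
                fh.write(f"{x!r} {y!r} {float(w)!r} {float(i)!r}\n")


# ---------------------------------------------------------------------------
# clinical manifest

_MANIFEST_COLUMNS = (
    "sample_id", "label", "sex", "age", "adjusted_age", "abeta42",
    "t_tau", "p_tau", "mmse", "cdr_sum", "cdr_glob",
)

_LABEL_ALIASES = {
    "normal": "normal", "healthy": "normal", "control": "normal",
    "dementia": "dementia", "ad": "dementia",
    "fad_pos": "fad_pos", "fad+": "fad_pos", "fad(+)": "fad_pos",
    "fad_neg": "fad_neg", "fad-": "fad_neg", "fad(-)": "fad_neg",
}


def _opt_float(cell: str) -> float | None:
    cell = cell.strip()
    return float(cell) if cell else None


def read_manifest(path) -> list[ClinicalRecord]:
    """Read a clinical manifest CSV into :class:`ClinicalRecord` rows.

    Header must carry the recognized column names (sample_id and label are
    required; the rest optional).  Empty cells mean missing.  Labels are
    parsed case-insensitively with common aliases (``FAD(+)`` etc.).
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ManifestError(f"{path}: missing header with sample_id column")
        unknown = set(reader.fieldnames) - set(_MANIFEST_COLUMNS)
        if unknown:
            raise ManifestError(f"{path}: unrecognized columns {sorted(unknown)}")
        for lineno, row in enumerate(reader, start=2):
            raw_label = (row.get("label") or "").strip().lower()
            if raw_label not in _LABEL_ALIASES:
                raise ManifestError(f"{path}: line {lineno}: unknown label {raw_label!r}")
            sex = (row.get("sex") or "").strip().upper() or "unknown"
            if sex not in ("M", "F"):
                sex = "unknown"
            mmse = _opt_float(row.get("mmse") or "")
            try:
                records.append(
                    ClinicalRecord(
                        sample_id=row["sample_id"].strip(),
                        label=_LABEL_ALIASES[raw_label],
                        sex=sex,
                        age=_opt_float(row.get("age") or ""),
                        adjusted_age=_opt_float(row.get("adjusted_age") or ""),
                        abeta42=_opt_float(row.get("abeta42") or ""),
                        t_tau=_opt_float(row.get("t_tau") or ""),
                        p_tau=_opt_float(row.get("p_tau") or ""),
                        mmse=None if mmse is None else int(round(mmse)),
                        cdr_sum=_opt_float(row.get("cdr_sum") or ""),
                        cdr_glob=_opt_float(row.get("cdr_glob") or ""),
                    )
                )
            except ManifestError as exc:
                raise ManifestError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_manifest(records: Iterable[ClinicalRecord], path) -> None:
    """Write records as a manifest CSV; ``None`` becomes an empty cell."""
    def cell(v):
        if v is None:
            return ""
        if isinstance(v, float) and math.isnan(v):
            return ""
        return v

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_MANIFEST_COLUMNS)
        for r in records:
            writer.writerow([cell(getattr(r, c)) for c in _MANIFEST_COLUMNS])
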