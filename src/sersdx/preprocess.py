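"""Spectral preprocessing: baseline correction, denoising, averaging,
integration normalization.

The cleanup chain mirrors the acquisition-software pipeline the study relied
on: each raw spectrum gets an automatic baseline subtraction and noise
removal, the >=80 spectra of one mapping are averaged into the sample
fingerprint, and fingerprints are integration-normalized (integral over the
wavenumber range scaled to one) before samples are compared.

Baseline estimation uses asymmetric least squares (Eilers-Boelens): a
Whittaker smoother whose weights are iteratively reweighted so the fit hugs
the lower envelope (weight p << 1 above the fit, 1-p below), leaving the
peaks in the residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .spectra_io import MappingGroup, Spectrum

__all__ = [
    "PreprocessConfig",
    "baseline_correct",
    "smooth",
    "average_group",
    "integration_normalize",
    "preprocess_spectrum",
    "sample_fingerprint",
    "NormalizationError",
]


class NormalizationError(ValueError):
    """Raised when a spectrum cannot be integration-normalized."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the cleanup chain.

    baseline_lambda
        Smoothness weight of the asymmetric-least-squares baseline; larger
        means a stiffer baseline.
    baseline_p
        Asymmetry in (0, 1): weight given to points above the running
        baseline estimate.  Small values make the fit track the lower
        envelope of the spectrum.
    baseline_iters
        Reweighting iterations.
    smooth_window, smooth_polyorder
        Savitzky-Golay window (odd point count) and polynomial order.
    normalize
        Whether :func:`sample_fingerprint` integration-normalizes the
        averaged spectrum.
    """

    baseline_lambda: float = 1e5
    baseline_p: float = 0.01
    baseline_iters: int = 10
    smooth_window: int = 11
    smooth_polyorder: int = 3
    normalize: bool = True

    def __post_init__(self):
        if not 0 < self.baseline_p < 1:
            raise ValueError("baseline_p must be in (0, 1)")
        if self.smooth_window % 2 == 0 or self.smooth_window <= self.smooth_polyorder:
            raise ValueError("smooth_window must be odd and > smooth_polyorder")


def _asls_banded_dtd(n: int, lam: float) -> np.ndarray:
    # upper banded form of lam * D2.T @ D2 (D2 the second-difference matrix)
    ab = np.zeros((3, n))
    d0 = np.full(n, 6.0)
    d0[0] = d0[-1] = 1.0
    d0[1] = d0[-2] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[0] = d1[-1] = -2.0
    ab[0, 2:] = lam
    ab[1, 1:] = lam * d1
    ab[2, :] = lam * d0
    return ab


def _asls_baseline(y: np.ndarray, lam: float, p: float, n_iter: int) -> np.ndarray:
    # pentadiagonal system (W + lam*D'D) z = W y, solved by banded Cholesky
    n = y.size
    ab0 = _asls_banded_dtd(n, lam)
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        ab = ab0.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Subtract an asymmetric-least-squares baseline estimate."""
    y = spectrum.intensities
    if np.allclose(y, y[0]):
        # constant (incl. all-zero) spectra have themselves as baseline
        return spectrum.with_intensities(np.zeros_like(y))
    z = _asls_baseline(y, config.baseline_lambda, config.baseline_p, config.baseline_iters)
    return spectrum.with_intensities(y - z)


def smooth(spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Savitzky-Golay denoising; band positions are preserved."""
    if config.smooth_window > len(spectrum):
        raise ValueError(
            f"smoothing window {config.smooth_window} exceeds spectrum length {len(spectrum)}"
        )
    y = savgol_filter(spectrum.intensities, config.smooth_window, config.smooth_polyorder)
    return spectrum.with_intensities(y)


def average_group(group: MappingGroup) -> Spectrum:
    """Pointwise mean of a mapping's spectra (the sample average spectrum)."""
    mean = group.intensity_matrix().mean(axis=0)
    return Spectrum(
        group.grid, mean, {"sample_id": group.sample_id, "n_averaged": len(group)}
    )


def integration_normalize(spectrum: Spectrum) -> Spectrum:
    """Scale intensities so the trapezoidal integral over the grid is 1."""
    area = trapezoid(spectrum.intensities, spectrum.wavenumbers)
    if area <= 0:
        raise NormalizationError(f"non-positive integral {area!r}")
    return spectrum.with_intensities(spectrum.intensities / area)


def preprocess_spectrum(spectrum: Spectrum, config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Per-spectrum cleanup: baseline correction then smoothing."""
    return smooth(baseline_correct(spectrum, config), config)


def sample_fingerprint(group: MappingGroup, config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Full chain for one mapping: per-spectrum baseline + smooth, average,
    then integration-normalize (unless ``config.normalize`` is off)."""
    cleaned = MappingGroup(
        group.sample_id,
        [preprocess_spectrum(s, config) for s in group.spectra],
        group.step_size,
    )
    fp = average_group(cleaned)
    return integration_normalize(fp) if config.normalize else fp
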