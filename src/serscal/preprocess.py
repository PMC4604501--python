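"""Spectral preprocessing: ALS baseline correction, SNV, peak integration.

The calibration chain applies asymmetric least squares (ALS) baseline
estimation followed by standard normal variate (SNV) normalisation to every
spectrum, in that order.  Trapezoidal peak-area integration over a fixed
window around a characteristic band supports the univariate diagnostics
(working-range and reproducibility checks).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded

from .exceptions import DegenerateInputError
from .spectra import SpectraSet, WavenumberGrid

__all__ = [
    "ALSParams",
    "PeakWindow",
    "als_baseline",
    "snv",
    "trapezoid_peak_area",
    "preprocess_set",
    "DEFAULT_PEAK_WINDOWS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ALSParams:
    """Asymmetric least squares parameters.

    ``lam`` is the second-difference smoothness penalty (grid spacing is
    folded into it, the discrete operator assumes unit spacing), ``p`` the
    asymmetry weight given to points above the baseline.  Defaults are the
    standard choice for ~1000-channel Raman spectra.
    """

    lam: float = 1e5
    p: float = 0.001
    max_iter: int = 10
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class PeakWindow:
    """Integration window: all channels with |wavenumber - center| <= half_width."""

    center: float
    half_width: float = 20.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


#: Characteristic bands used for univariate peak-area diagnostics:
#: the C=O deformation at 693 cm^-1 for caffeine and paraxanthine and the
#: nu(C-N)+rho(CH3) band at 1303 cm^-1 for theobromine.
DEFAULT_PEAK_WINDOWS = {
    "caffeine": PeakWindow(693.0),
    "theobromine": PeakWindow(1303.0),
    "paraxanthine": PeakWindow(693.0),
}


@lru_cache(maxsize=8)
def _penalty_diagonals(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonals (main, first, second) of D2'D2 for the second-difference
    operator D2 of an n-point signal."""
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n)).tocsc()
    a = d2.T @ d2
    return a.diagonal(0), a.diagonal(1), a.diagonal(2)


def als_baseline(
    spectrum: np.ndarray,
    grid: WavenumberGrid | np.ndarray | None = None,
    params: ALSParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Asymmetric least squares baseline of one spectrum.

    Minimises  sum_i w_i (y_i - z_i)^2 + lam * sum_i (Delta^2 z_i)^2  with
    w_i = p where y_i > z_i and 1 - p elsewhere, iterating the weights to
    convergence.  Returns ``(baseline, corrected)`` with
    ``corrected == spectrum - baseline`` exactly.

    If the weights have not converged after ``max_iter`` sweeps the last
    iterate is returned and a warning is logged.
    """
    if params is None:
        params = ALSParams()
    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("spectrum must be one-dimensional with >= 3 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")
    if grid is not None:
        g = grid.values if isinstance(grid, WavenumberGrid) else np.asarray(grid)
        if g.size != y.size:
            raise ValueError("spectrum length does not match grid")

    n = y.size
    main, first, second = _penalty_diagonals(n)
    # Banded upper form for solveh_banded: row 0 = 2nd superdiag, row 2 = main.
    ab = np.zeros((3, n))
    ab[0, 2:] = params.lam * second
    ab[1, 1:] = params.lam * first

    w = np.ones(n)
    z = y
    converged = False
    for _ in range(params.max_iter):
        ab[2] = params.lam * main + w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, params.p, 1.0 - params.p)
        if np.mean(np.abs(w_new - w)) <= params.tol:
            converged = True
            break
        w = w_new
    if not converged:
        logger.warning(
            "ALS weights did not converge within %d iterations", params.max_iter
        )
    return z, y - z


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to mean 0,
    sample (n-1 denominator) standard deviation 1."""
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("spectrum must be one-dimensional with >= 2 points")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("constant spectrum: SNV undefined (sd == 0)")
    return (x - x.mean()) / sd


def trapezoid_peak_area(
    spectrum: np.ndarray,
    grid: WavenumberGrid | np.ndarray,
    window: PeakWindow,
) -> float:
    """Trapezoidal peak area (signal * cm^-1) over a wavenumber window.

    Integrates over all grid points with |nu - center| <= half_width.  The
    spectrum is expected to be baseline-corrected by the caller.
    """
    x = grid.values if isinstance(grid, WavenumberGrid) else np.asarray(grid, float)
    y = np.asarray(spectrum, dtype=float)
    if y.shape != x.shape:
        raise ValueError("spectrum length does not match grid")
    mask = np.abs(x - window.center) <= window.half_width
    if mask.sum() < 2:
        raise ValueError(
            f"window {window.center}+-{window.half_width} cm^-1 covers "
            f"{int(mask.sum())} grid points; need >= 2"
        )
    return float(np.trapezoid(y[mask], x[mask]))


def preprocess_set(
    spectra_set: SpectraSet, als_params: ALSParams | None = None
) -> SpectraSet:
    """ALS baseline correction followed by SNV, per spectrum.

    The order is fixed: baseline first, normalisation second.  Metadata and
    sample ids are preserved.  A degenerate spectrum aborts with an error
    naming the offending sample.
    """
    out = np.empty_like(spectra_set.intensities)
    for i, sid in enumerate(spectra_set.sample_ids):
        try:
            _, corrected = als_baseline(
                spectra_set.intensities[i], spectra_set.wavenumbers, als_params
            )
            out[i] = snv(corrected)
        except (DegenerateInputError, ValueError) as exc:
            raise type(exc)(f"sample {sid!r}: {exc}") from exc
    return spectra_set.with_intensities(out)
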