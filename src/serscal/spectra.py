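"""Shared containers: wavenumber grids and sets of spectra.

A :class:`SpectraSet` is the central exchange object of the package: a dense
matrix of Raman/SERS intensities on one common, equally spaced wavenumber
grid, with one row per physical sample and optional per-sample metadata.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd

#: Analyte order used throughout the package (columns of concentration
#: tables, outputs of the three-output network).
ANALYTES = ("caffeine", "theobromine", "paraxanthine")

#: Concentration-table column names, in analyte order.
CONC_COLUMNS = tuple(f"conc_{a}" for a in ANALYTES)


@dataclass(frozen=True)
class WavenumberGrid:
    """Equally spaced wavenumber axis in cm^-1.

    The default instance matches a portable Raman probe recording 1024
    channels from 200 to 3400 cm^-1.
    """

    start: float = 200.0
    end: float = 3400.0
    n_points: int = 1024

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start) and np.isfinite(self.end)):
            raise ValueError("grid endpoints must be finite")
        if self.end <= self.start:
            raise ValueError(
                f"grid span must be positive, got start={self.start}, end={self.end}"
            )
        if int(self.n_points) < 2 or self.n_points != int(self.n_points):
            raise ValueError(f"n_points must be an integer >= 2, got {self.n_points}")

    @cached_property
    def values(self) -> np.ndarray:
        """The grid points, strictly increasing, length ``n_points``."""
        v = np.linspace(self.start, self.end, self.n_points)
        v.flags.writeable = False
        return v

    @property
    def spacing(self) -> float:
        return (self.end - self.start) / (self.n_points - 1)

    def __len__(self) -> int:
        return self.n_points

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.end

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point nearest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))


def make_wavenumber_grid(start: float, end: float, n_points: int) -> WavenumberGrid:
    """Build an equally spaced grid from ``start`` to ``end`` inclusive."""
    return WavenumberGrid(float(start), float(end), int(n_points))


@dataclass(eq=False)
class SpectraSet:
    """A matrix of spectra on a shared wavenumber grid.

    Parameters
    ----------
    wavenumbers : ndarray, shape (n_channels,)
        Strictly increasing wavenumber axis (cm^-1).
    intensities : ndarray, shape (n_samples, n_channels)
        One spectrum per row, aligned with ``sample_ids``.
    sample_ids : sequence of str
        Unique identifier per row.
    metadata : DataFrame, optional
        Per-sample annotations (mixture id, replicate, design fractions);
        must carry a ``sample_id`` column when present.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    sample_ids: list[str]
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.wavenumbers.ndim != 1:
            raise ValueError("wavenumbers must be one-dimensional")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.intensities.shape != (len(self.sample_ids), self.wavenumbers.size):
            raise ValueError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavenumbers.size} channels"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if self.metadata is not None and "sample_id" not in self.metadata.columns:
            raise ValueError("metadata must have a sample_id column")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def with_intensities(self, intensities: np.ndarray) -> "SpectraSet":
        """Copy of this set with a replaced intensity matrix."""
        return SpectraSet(
            self.wavenumbers.copy(),
            np.asarray(intensities, dtype=float),
            list(self.sample_ids),
            None if self.metadata is None else self.metadata.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: index sample_id, one column per wavenumber."""
        return pd.DataFrame(
            self.intensities,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.wavenumbers,
        )

    def equals(self, other: "SpectraSet") -> bool:
        """Exact equality of grid, data and sample ids (metadata ignored)."""
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.intensities, other.intensities)
        )


def concentration_matrix(
    concentrations: pd.DataFrame, analytes: Sequence[str] = ANALYTES
) -> np.ndarray:
    """Extract the (n_samples, n_analytes) matrix from a concentration table.

    The table uses columns ``conc_<analyte>`` in mol/dm^3, plus ``sample_id``
    and ``replicate``.
    """
    cols = [f"conc_{a}" for a in analytes]
    missing = [c for c in cols if c not in concentrations.columns]
    if missing:
        raise ValueError(f"concentration table lacks columns {missing}")
    return concentrations[cols].to_numpy(dtype=float)
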