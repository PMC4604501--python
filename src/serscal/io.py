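"""Text formats: spectra/concentration CSV and a minimal JCAMP-DX reader.

The spectra CSV dialect: first row ``sample_id`` followed by the
wavenumbers; each further row a sample id followed by that spectrum's
intensities.  Concentrations: ``sample_id, replicate, conc_caffeine,
conc_theobromine, conc_paraxanthine`` in mol/dm^3.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .spectra import CONC_COLUMNS, SpectraSet, WavenumberGrid

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_concentrations_csv",
    "read_concentrations_csv",
    "read_jcamp",
    "jcamp_to_grid",
]


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet in the package's delimited-text dialect."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            "sample_id," + ",".join(repr(float(w)) for w in spectra.wavenumbers)
        )
        fh.write("\n")
        for sid, row in zip(spectra.sample_ids, spectra.intensities):
            fh.write(sid + "," + ",".join(repr(float(v)) for v in row) + "\n")


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read the spectra CSV dialect, validating shape and grid monotonicity.

    Errors name the 1-based line number of the offending row.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header and at least one sample row")
    header = lines[0].split(",")
    if header[0] != "sample_id":
        raise FormatError(f"{path}:1: first header cell must be 'sample_id'")
    try:
        wavenumbers = np.array([float(v) for v in header[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}:1: non-numeric wavenumber in header: {exc}")
    if wavenumbers.size < 2 or np.any(np.diff(wavenumbers) <= 0):
        raise FormatError(f"{path}:1: wavenumbers must be strictly increasing")
    ids, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != wavenumbers.size + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {wavenumbers.size + 1} cells, "
                f"got {len(cells)}"
            )
        ids.append(cells[0])
        try:
            rows.append([float(v) for v in cells[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric intensity: {exc}")
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate sample ids")
    return SpectraSet(wavenumbers, np.asarray(rows), ids)


def write_concentrations_csv(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "replicate", *CONC_COLUMNS]
    cols = [c for c in cols if c in table.columns] + [
        c for c in table.columns if c not in cols and c.startswith("conc_")
    ]
    table[cols].to_csv(path, index=False, float_format="%.10e")


def read_concentrations_csv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "sample_id" not in table.columns:
        raise FormatError(f"{path}: missing sample_id column")
    table["sample_id"] = table["sample_id"].astype(str)
    return table


# ---------------------------------------------------------------------------
# JCAMP-DX (read-only, XYDATA X++(Y..Y), AFFN numbers)
# ---------------------------------------------------------------------------

def read_jcamp(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a single-spectrum JCAMP-DX file (XYDATA=(X++(Y..Y)), AFFN).

    Applies XFACTOR/YFACTOR; returns (x, y) sorted by increasing x.
    Compressed (SQZ/DIF/DUP) encodings are not supported.
    """
    path = Path(path)
    xfactor = yfactor = 1.0
    deltax = firstx = lastx = npoints = None
    in_data = False
    xs: list[float] = []
    ys: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("$$")[0].strip()  # strip comments
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "DELTAX":
                    deltax = float(value)
                elif key == "FIRSTX":
                    firstx = float(value)
                elif key == "LASTX":
                    lastx = float(value)
                elif key == "NPOINTS":
                    npoints = int(float(value))
                elif key == "XYDATA":
                    if "X++" not in value.replace(" ", ""):
                        raise FormatError(
                            f"{path}:{lineno}: unsupported XYDATA form {value!r}"
                        )
                    in_data = True
                elif key == "END":
                    in_data = False
                continue
            if in_data:
                try:
                    nums = [float(v) for v in line.replace(",", " ").split()]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad data line: {exc}")
                if len(nums) < 2:
                    raise FormatError(f"{path}:{lineno}: data line needs X and Y")
                # abscissa step in actual units: DELTAX, or derived
                step = deltax
                if step is None and None not in (firstx, lastx, npoints):
                    step = (lastx - firstx) / (npoints - 1)
                x0 = nums[0] * xfactor
                yvals = [v * yfactor for v in nums[1:]]
                if len(yvals) > 1 and step is None:
                    raise FormatError(
                        f"{path}:{lineno}: multiple Y per line but no "
                        "##DELTAX or FIRSTX/LASTX/NPOINTS"
                    )
                for i, y in enumerate(yvals):
                    xs.append(x0 if i == 0 else x0 + i * step)
                    ys.append(y)
    if not xs:
        raise FormatError(f"{path}: no XYDATA found")
    x = np.asarray(xs)
    y = np.asarray(ys)
    order = np.argsort(x)
    return x[order], y[order]


def jcamp_to_grid(
    path: str | Path, grid: WavenumberGrid
) -> np.ndarray:
    """Read a JCAMP-DX spectrum and linearly interpolate it onto ``grid``.

    Grid points outside the recorded range take the nearest endpoint value.
    """
    x, y = read_jcamp(path)
    return np.interp(grid.values, x, y)
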