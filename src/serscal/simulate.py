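"""Synthetic SERS spectra for ternary xanthine mixtures.

This module emulates the measurement campaign the downstream calibration
assumes: a simplex-lattice mixture design over caffeine, theobromine and
paraxanthine at a fixed total concentration, triplicate preparations, and
SERS-like spectra built from tabulated vibrational bands with smooth
baseline drift, additive detector noise and per-component multiplicative
(enhancement) noise.

The pure-component band positions follow published SERS band assignments
for the three analytes.  Caffeine and paraxanthine share band positions and
are distinguished by different relative band intensities; caffeine is
additionally made harder to quantify (a larger multiplicative-noise
multiplier and a saturating response) to mirror its slower association with
the silver surface and higher working range observed experimentally.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import ANALYTES, CONC_COLUMNS, SpectraSet, WavenumberGrid, make_wavenumber_grid

__all__ = [
    "BandModel",
    "ComponentModel",
    "MixtureDesign",
    "NoiseConfig",
    "SimulatedDataset",
    "default_components",
    "mixture_design",
    "pure_component_spectrum",
    "component_response",
    "simulate_sample",
    "simulate_dataset",
]

#: Total analyte concentration of every simulated mixture (mol/dm^3).
DEFAULT_TOTAL_CONC = 1e-5


@dataclass(frozen=True)
class BandModel:
    """One vibrational band: position, width, relative height, line shape."""

    center: float  # cm^-1
    fwhm: float = 8.0  # cm^-1; default matches an 8 cm^-1 spectral resolution
    relative_intensity: float = 1.0  # in (0, 1]
    shape: str = "lorentzian"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.relative_intensity <= 0:
            raise ValueError("relative_intensity must be positive")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Unit-amplitude line profile evaluated on ``wavenumbers``."""
        d = wavenumbers - self.center
        if self.shape == "lorentzian":
            hwhm = self.fwhm / 2.0
            return hwhm**2 / (d**2 + hwhm**2)
        # gaussian
        return np.exp(-4.0 * math.log(2.0) * d**2 / self.fwhm**2)


@dataclass(frozen=True)
class ComponentModel:
    """Spectral and response model of one analyte.

    ``sensitivity`` is signal per (mol/dm^3); with the default 1e5 a pure
    component at the 1e-5 mol/dm^3 total concentration has unit amplitude.
    ``saturation_conc`` switches the response from linear to the saturating
    form s*c / (1 + c/c_sat).  ``noise_scale_multiplier`` scales the
    multiplicative noise applied to this component's contribution.
    ``fast_association`` marks species that are surface-bound by the time
    the aggregating agent is added and therefore share the preparation's
    hot-spot enhancement fluctuation; a slow associator (caffeine) is
    exposed to an independent enhancement instead, which is what makes it
    the hardest analyte to quantify.
    """

    name: str
    bands: tuple[BandModel, ...]
    sensitivity: float = 1e5
    saturation_conc: float | None = None
    noise_scale_multiplier: float = 1.0
    fast_association: bool = True

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("component needs at least one band")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.noise_scale_multiplier < 1.0:
            raise ValueError("noise_scale_multiplier must be >= 1")
        object.__setattr__(self, "bands", tuple(self.bands))


def _bands(spec: dict[float, float]) -> tuple[BandModel, ...]:
    return tuple(
        BandModel(center=c, relative_intensity=i) for c, i in sorted(spec.items())
    )


def default_components() -> tuple[ComponentModel, ComponentModel, ComponentModel]:
    """The three default analyte models, in the package's analyte order.

    Caffeine and paraxanthine share the band-position list of the published
    assignment table (509, 650, 693, 1006, 1247, 1450, 1672, 2953 cm^-1);
    their relative intensities differ so the two pure spectra are linearly
    independent: caffeine emphasises 693 and 1450 cm^-1, paraxanthine 650,
    1247 and 1672 cm^-1.  Theobromine has its own positions (637, 1228,
    1303, 1353, 1413, 1603, 2953 cm^-1).  Intensity ratios are declared
    modelling assumptions, not literature values.
    """
    caffeine = ComponentModel(
        name="caffeine",
        bands=_bands(
            {
                509: 0.30,
                650: 0.35,
                693: 1.00,
                1006: 0.25,
                1247: 0.40,
                1450: 0.90,
                1672: 0.35,
                2953: 0.30,
            }
        ),
        saturation_conc=DEFAULT_TOTAL_CONC,
        noise_scale_multiplier=2.5,
        fast_association=False,
    )
    theobromine = ComponentModel(
        name="theobromine",
        bands=_bands(
            {
                637: 0.80,
                1228: 0.60,
                1303: 1.00,
                1353: 0.50,
                1413: 0.45,
                1603: 0.40,
                2953: 0.30,
            }
        ),
    )
    paraxanthine = ComponentModel(
        name="paraxanthine",
        bands=_bands(
            {
                509: 0.30,
                650: 0.90,
                693: 0.80,
                1006: 0.25,
                1247: 1.00,
                1450: 0.35,
                1672: 0.80,
                2953: 0.30,
            }
        ),
    )
    return caffeine, theobromine, paraxanthine


@dataclass(frozen=True)
class MixtureDesign:
    """All k-component fractional compositions on a fixed step, summing to 1."""

    step: float
    compositions: tuple[tuple[float, ...], ...]

    @property
    def n_compositions(self) -> int:
        return len(self.compositions)

    @property
    def k_components(self) -> int:
        return len(self.compositions[0])

    def as_array(self) -> np.ndarray:
        return np.asarray(self.compositions, dtype=float)


def mixture_design(k_components: int, step: float) -> MixtureDesign:
    """Full simplex-lattice design: every composition of ``k_components``
    non-negative fractions, each an integer multiple of ``step``, summing
    to one.  Lexicographically sorted for determinism.

    For three components at a 10 % step this yields the 66 mixtures of the
    default experimental design.
    """
    if k_components < 1:
        raise ValueError("k_components must be >= 1")
    m = 1.0 / step
    if abs(m - round(m)) > 1e-9:
        raise ValueError(f"step {step} does not divide 1 into integer parts")
    m = int(round(m))
    comps = []
    for parts in _compositions_of(m, k_components):
        comps.append(tuple(p / m for p in parts))
    comps.sort()
    return MixtureDesign(step=step, compositions=tuple(comps))


def _compositions_of(m: int, k: int):
    """All k-tuples of non-negative integers summing to m."""
    if k == 1:
        yield (m,)
        return
    for first in range(m + 1):
        for rest in _compositions_of(m - first, k - 1):
            yield (first,) + rest


@dataclass(frozen=True)
class NoiseConfig:
    """Noise model parameters.

    ``additive_sd``, ``baseline_amplitude`` are relative to the reference
    amplitude — the largest pure-component response at the total
    concentration.  ``multiplicative_sd`` scales each component's
    contribution per sample (times the component's
    ``noise_scale_multiplier``).  ``aggregation_sd`` is the SD of a shared
    enhancement factor applied to all fast-associating components: species
    already surface-bound when the aggregating agent is added feel the same
    hot-spot enhancement fluctuation, whereas a slow associator sees an
    independently varying enhancement.  By default this factor varies at
    the mixture level (one value per prepared composition, shared by its
    replicate measurements, emulating a per-session aggregation state), so
    it does not inflate replicate peak-area RSDs.  Defaults are calibrated
    so replicate relative standard deviations of characteristic peak areas
    fall in the low-percent range typical of a well optimised colloidal
    SERS protocol.
    """

    additive_sd: float = 0.001
    multiplicative_sd: float = 0.01
    aggregation_sd: float = 0.15
    aggregation_level: str = "mixture"  # or "replicate"
    baseline_amplitude: float = 0.1
    baseline_smoothness: float = 600.0  # cm^-1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "additive_sd",
            "multiplicative_sd",
            "aggregation_sd",
            "baseline_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.aggregation_level not in ("mixture", "replicate"):
            raise ValueError("aggregation_level must be 'mixture' or 'replicate'")


NOISELESS = NoiseConfig(
    additive_sd=0.0,
    multiplicative_sd=0.0,
    aggregation_sd=0.0,
    baseline_amplitude=0.0,
)


def pure_component_spectrum(
    component: ComponentModel, grid: WavenumberGrid
) -> np.ndarray:
    """Noise-free pure-component spectrum, max amplitude normalised to 1.

    Each band contributes its line profile scaled by ``relative_intensity``;
    the apex of an isolated band falls on the grid point nearest its center.
    """
    x = grid.values
    for band in component.bands:
        if not grid.contains(band.center):
            raise ValueError(
                f"band center {band.center} cm^-1 of {component.name!r} lies "
                f"outside the grid [{grid.start}, {grid.end}]"
            )
    y = np.zeros_like(x)
    for band in component.bands:
        y += band.relative_intensity * band.profile(x)
    return y / y.max()


def component_response(component: ComponentModel, conc: float) -> float:
    """Signal amplitude of a component at concentration ``conc`` (mol/dm^3).

    Linear (sensitivity * c) or, when ``saturation_conc`` is set, the
    saturating form sensitivity * c / (1 + c / c_sat).
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if component.saturation_conc is None:
        return component.sensitivity * conc
    return component.sensitivity * conc / (1.0 + conc / component.saturation_conc)


def _reference_amplitude(
    components: Sequence[ComponentModel], total_conc: float
) -> float:
    return max(component_response(c, total_conc) for c in components)


def simulate_sample(
    composition: Sequence[float],
    total_conc: float,
    components: Sequence[ComponentModel],
    noise: NoiseConfig,
    rng: np.random.Generator,
    grid: WavenumberGrid | None = None,
    pure_spectra: np.ndarray | None = None,
    aggregation_factor: float | None = None,
) -> np.ndarray:
    """One simulated spectrum for a mixture ``composition`` (fractions).

    spectrum = sum_j response_j(c_j) * (1 + eps_j) * g_j * pure_j
               + smooth random baseline + additive noise,

    with c_j = composition_j * total_conc,
    eps_j ~ N(0, multiplicative_sd * noise_scale_multiplier_j), and g_j the
    shared aggregation enhancement factor (1 + eta * aggregation_sd) for
    fast-associating components, 1 for slow associators.

    ``pure_spectra`` (components x channels) may be precomputed for speed;
    ``aggregation_factor`` overrides the per-call draw of g (used to share
    one factor across the replicates of a mixture).
    """
    if grid is None:
        grid = WavenumberGrid()
    composition = np.asarray(composition, dtype=float)
    if composition.shape != (len(components),):
        raise ValueError(
            f"composition length {composition.size} != {len(components)} components"
        )
    if total_conc <= 0:
        raise ValueError("total_conc must be positive")
    concs = composition * total_conc
    if np.any(concs < 0):
        raise ValueError("negative concentrations are not allowed")
    if pure_spectra is None:
        pure_spectra = np.vstack(
            [pure_component_spectrum(c, grid) for c in components]
        )
    amp_ref = _reference_amplitude(components, total_conc)
    n = grid.n_points
    x = grid.values

    # Fixed draw order keeps a sample's stream independent of noise settings.
    eps = rng.standard_normal(len(components))
    eta_agg = rng.standard_normal()
    if aggregation_factor is not None:
        agg = aggregation_factor
    else:
        agg = 1.0 + eta_agg * noise.aggregation_sd
    base_centers = rng.uniform(grid.start, grid.end, size=3)
    base_widths = noise.baseline_smoothness * rng.uniform(0.75, 1.25, size=3)
    base_amps = noise.baseline_amplitude * amp_ref * rng.uniform(0.0, 1.0, size=3)
    white = rng.standard_normal(n)

    spectrum = np.zeros(n)
    for j, comp in enumerate(components):
        scale = 1.0 + eps[j] * noise.multiplicative_sd * comp.noise_scale_multiplier
        if comp.fast_association:
            # shared hot-spot enhancement fluctuation of the aggregation
            # state, felt by species already surface-bound when the
            # aggregating agent is added
            scale *= agg
        spectrum += component_response(comp, concs[j]) * scale * pure_spectra[j]
    for c, w, a in zip(base_centers, base_widths, base_amps):
        spectrum += a * np.exp(-0.5 * ((x - c) / w) ** 2)
    spectrum += noise.additive_sd * amp_ref * white
    return spectrum


@dataclass
class SimulatedDataset:
    """A full simulated measurement campaign."""

    spectra: SpectraSet
    concentrations: pd.DataFrame
    design: MixtureDesign
    replicates: int
    components: tuple[ComponentModel, ...] = field(default_factory=default_components)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    total_conc: float = DEFAULT_TOTAL_CONC
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.spectra.n_samples


def simulate_dataset(
    design: MixtureDesign | None = None,
    total_conc: float = DEFAULT_TOTAL_CONC,
    replicates: int = 3,
    components: Sequence[ComponentModel] | None = None,
    noise: NoiseConfig | None = None,
    seed: int | None = None,
    grid: WavenumberGrid | None = None,
) -> SimulatedDataset:
    """Simulate the full design: one spectrum per (composition, replicate).

    Defaults reproduce the emulated campaign: 66 ternary compositions at a
    10 % step, total concentration 1e-5 mol/dm^3, triplicates (198 samples),
    1024 channels from 200 to 3400 cm^-1.  The master ``seed`` spawns an
    independent substream per sample, so the dataset is bit-reproducible and
    insensitive to generation order.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if design is None:
        design = mixture_design(3, 0.1)
    if components is None:
        components = default_components()
    if noise is None:
        noise = NoiseConfig()
    if seed is None:
        seed = noise.seed
    if grid is None:
        grid = WavenumberGrid()
    if design.k_components != len(components):
        raise ValueError("design and component list disagree on k")

    pure = np.vstack([pure_component_spectrum(c, grid) for c in components])
    n_samples = design.n_compositions * replicates
    streams = np.random.SeedSequence(seed).spawn(n_samples + design.n_compositions)
    # With mixture-level aggregation noise, one enhancement factor is shared
    # by all replicates of a mixture (same measurement session).
    mixture_agg = [
        1.0 + np.random.default_rng(s).standard_normal() * noise.aggregation_sd
        for s in streams[n_samples:]
    ]

    rows = []
    ids = []
    meta_rows = []
    conc_rows = []
    idx = 0
    for i, comp in enumerate(design.compositions):
        for r in range(1, replicates + 1):
            sid = f"M{i:03d}R{r}"
            rng = np.random.default_rng(streams[idx])
            agg = (
                mixture_agg[i]
                if noise.aggregation_level == "mixture"
                else None
            )
            rows.append(
                simulate_sample(
                    comp, total_conc, components, noise, rng, grid, pure,
                    aggregation_factor=agg,
                )
            )
            ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "mixture_id": i, "replicate": r}
                | {f"frac_{c.name}": f for c, f in zip(components, comp)}
            )
            conc_rows.append(
                {"sample_id": sid, "replicate": r}
                | {
                    f"conc_{c.name}": f * total_conc
                    for c, f in zip(components, comp)
                }
            )
            idx += 1

    spectra = SpectraSet(
        grid.values.copy(), np.vstack(rows), ids, pd.DataFrame(meta_rows)
    )
    concentrations = pd.DataFrame(conc_rows)
    return SimulatedDataset(
        spectra=spectra,
        concentrations=concentrations,
        design=design,
        replicates=replicates,
        components=tuple(components),
        noise=noise,
        total_conc=total_conc,
        seed=seed,
    )
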