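"""Statsmodels-style model/results interface to the calibration pipeline.

``SERSCalibration`` holds preprocessed spectra and the concentration table;
``fit()`` runs bootstrap out-of-bag validation of the configured network
and trains a final deployment network on all samples, returning a
``SERSCalibrationResults`` with the accuracy statistics, per-sample
prediction summaries and a text ``summary()``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .chemometrics import ANNModel, ANNTopology, TrainConfig, ann_predict, calibrate_ann
from .preprocess import ALSParams, preprocess_set
from .spectra import ANALYTES, SpectraSet, concentration_matrix
from .validation import (
    BootstrapConfig,
    BootstrapResult,
    bootstrap_validate,
    summarize_predictions,
)

__all__ = ["SERSCalibration", "SERSCalibrationResults"]


class SERSCalibration:
    """Neural calibration of analyte concentrations from SERS spectra.

    Parameters
    ----------
    spectra : SpectraSet
        Preprocessed (baseline-corrected, SNV-normalised) spectra.
    concentrations : DataFrame
        Table with ``sample_id`` and ``conc_<analyte>`` columns (mol/dm^3),
        row-aligned with ``spectra``.
    topology : ANNTopology, str or None
        Network layout; defaults to <n_channels>-20-1 for a single analyte
        or <n_channels>-20-3 when ``analytes`` has three entries.
    analytes : sequence of str
        Target analyte(s); one name for single-output models, defaults to
        all three for three-output models.
    """

    def __init__(
        self,
        spectra: SpectraSet,
        concentrations: pd.DataFrame,
        topology: ANNTopology | str | None = None,
        analytes=None,
    ):
        if spectra.n_samples != len(concentrations):
            raise ValueError("spectra and concentration table sizes differ")
        ids = concentrations["sample_id"].astype(str).tolist()
        if ids != spectra.sample_ids:
            # align the table to the spectra by sample id
            lookup = {s: i for i, s in enumerate(ids)}
            missing = [s for s in spectra.sample_ids if s not in lookup]
            if missing:
                raise ValueError(f"concentrations missing samples {missing[:5]}")
            concentrations = concentrations.iloc[
                [lookup[s] for s in spectra.sample_ids]
            ].reset_index(drop=True)
        if analytes is None:
            analytes = ANALYTES
        self.analytes = tuple(analytes)
        if isinstance(topology, str):
            topology = ANNTopology.parse(topology)
        if topology is None:
            topology = ANNTopology(
                n_inputs=spectra.n_channels, n_outputs=len(self.analytes)
            )
        if topology.n_inputs != spectra.n_channels:
            raise ValueError(
                f"topology expects {topology.n_inputs} inputs, spectra have "
                f"{spectra.n_channels} channels"
            )
        if topology.n_outputs != len(self.analytes):
            raise ValueError("topology outputs != number of analytes")
        self.spectra = spectra
        self.concentrations = concentrations
        self.topology = topology

    @classmethod
    def from_dataset(
        cls,
        dataset,
        topology: ANNTopology | str | None = None,
        analytes=None,
        als_params: ALSParams | None = None,
    ) -> "SERSCalibration":
        """Build from a :class:`~serscal.simulate.SimulatedDataset`,
        preprocessing (ALS + SNV) the raw spectra first."""
        spectra = preprocess_set(dataset.spectra, als_params)
        return cls(spectra, dataset.concentrations, topology, analytes)

    def fit(
        self,
        train_config: TrainConfig | None = None,
        boot_config: BootstrapConfig | None = None,
    ) -> "SERSCalibrationResults":
        """Bootstrap-validate and fit the deployment network."""
        train_config = train_config or TrainConfig()
        boot_config = boot_config or BootstrapConfig()
        boot = bootstrap_validate(
            self.spectra,
            self.concentrations,
            self.topology,
            train_config,
            boot_config,
            self.analytes,
        )
        # Final deployment model: all samples, a fixed 70/30 tuning split.
        rng = np.random.default_rng(boot_config.seed)
        n = self.spectra.n_samples
        perm = rng.permutation(n)
        n_inner = min(max(int(round(boot_config.inner_train_fraction * n)), 1), n - 1)
        Y = concentration_matrix(self.concentrations, self.analytes)
        X = self.spectra.intensities
        final = calibrate_ann(
            X[perm[:n_inner]],
            Y[perm[:n_inner]],
            X[perm[n_inner:]],
            Y[perm[n_inner:]],
            self.topology,
            replace(train_config, seed=int(rng.integers(2**31))),
        )
        return SERSCalibrationResults(self, boot, final)


@dataclass
class SERSCalibrationResults:
    """Fitted calibration: bootstrap statistics plus a deployment network."""

    model: SERSCalibration
    bootstrap: BootstrapResult
    final_model: ANNModel

    @property
    def q2(self) -> pd.Series:
        """Mean out-of-bag Q^2 per analyte (averaged over iterations)."""
        return pd.Series(self.bootstrap.mean_q2, name="q2")

    @property
    def rmsep(self) -> pd.Series:
        """Mean out-of-bag RMSEP per analyte, mol/dm^3."""
        return pd.Series(self.bootstrap.mean_rmsep, name="rmsep")

    @property
    def r2_inner(self) -> pd.Series:
        """Mean inner-training-set R^2 per analyte (fit, not validation)."""
        return pd.Series(self.bootstrap.mean_r2_inner, name="r2_inner")

    def predictions(self) -> pd.DataFrame:
        """Per-sample out-of-bag prediction summary (mean, SD, count)."""
        return summarize_predictions(self.bootstrap)

    def predict(self, spectra: SpectraSet | np.ndarray) -> pd.DataFrame:
        """Predict concentrations for new preprocessed spectra."""
        X = spectra.intensities if isinstance(spectra, SpectraSet) else spectra
        out = ann_predict(self.final_model, X)
        return pd.DataFrame(
            out, columns=[f"conc_{a}" for a in self.model.analytes]
        )

    def plot_predicted_vs_actual(self, analyte: str | None = None, ax=None):
        """Predicted-vs-actual scatter with out-of-bag SD error bars."""
        from .plotting import plot_predicted_vs_actual

        return plot_predicted_vs_actual(self.predictions(), analyte, ax)

    def summary(self) -> str:
        """Text summary of the bootstrap validation."""
        b = self.bootstrap
        lines = [
            "SERS neural calibration — bootstrap validation",
            "=" * 54,
            f"topology:        {b.topology}",
            f"samples:         {self.model.spectra.n_samples}",
            f"iterations:      {b.n_iterations} ({b.n_failed} failed)",
            "",
            f"{'analyte':<14}{'mean Q2':>10}{'mean RMSEP':>14}{'R2 (inner)':>12}",
            "-" * 54,
        ]
        for a in b.analytes:
            lines.append(
                f"{a:<14}{b.mean_q2[a]:>10.4f}{b.mean_rmsep[a]:>14.4e}"
                f"{b.mean_r2_inner[a]:>12.4f}"
            )
        lines += [
            "-" * 54,
            "Q2/RMSEP: mean over bootstrap out-of-bag test sets;",
            "RMSEP in mol/dm^3.  R2 (inner): fit on inner training data.",
        ]
        return "\n".join(lines)
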