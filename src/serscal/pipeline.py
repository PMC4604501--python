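"""End-to-end pipeline: simulate (or load) -> preprocess -> validate -> report.

Every run writes its artifacts plus a MANIFEST recording the master seed,
the configuration digest and per-stage completion, so a run is reproducible
from its manifest alone.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

import matplotlib

matplotlib.use("Agg")

from .chemometrics import ANNTopology
from .config import RunConfig, dump_config
from .io import (
    read_concentrations_csv,
    read_spectra_csv,
    write_concentrations_csv,
    write_spectra_csv,
)
from .model import SERSCalibration
from .preprocess import preprocess_set
from .simulate import mixture_design, simulate_dataset
from .spectra import ANALYTES, WavenumberGrid

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _topology_tag(topology: ANNTopology, analytes) -> str:
    if topology.n_outputs == 1:
        return f"{topology}_{analytes[0]}"
    return f"{topology}_all"


def run_pipeline(
    config: RunConfig,
    output_dir: str | Path | None = None,
    spectra_path: str | Path | None = None,
    concentrations_path: str | Path | None = None,
) -> Path:
    """Run the full pipeline; returns the output directory.

    With ``spectra_path``/``concentrations_path`` given, measured data are
    loaded instead of simulating.  Any stage failure leaves the partial
    artifacts plus a MANIFEST recording how far the run got, then re-raises.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest: dict = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "stages": {},
        "artifacts": [],
    }

    def done(stage: str, *artifacts: Path):
        manifest["stages"][stage] = "complete"
        manifest["artifacts"] += [str(a.relative_to(out)) for a in artifacts]
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    try:
        dump_config(config, out / "config.yaml")
        done("config", out / "config.yaml")

        sim = config.simulate
        if spectra_path is not None:
            spectra = read_spectra_csv(spectra_path)
            conc = read_concentrations_csv(concentrations_path)
        else:
            dataset = simulate_dataset(
                design=mixture_design(3, sim.step),
                total_conc=sim.total_conc,
                replicates=sim.replicates,
                noise=sim.noise,
                seed=config.seed,
                grid=WavenumberGrid(sim.grid_start, sim.grid_end, sim.grid_points),
            )
            spectra, conc = dataset.spectra, dataset.concentrations
            write_spectra_csv(spectra, out / "spectra_raw.csv")
            write_concentrations_csv(conc, out / "concentrations.csv")
        done("simulate", out / "spectra_raw.csv", out / "concentrations.csv")

        pre = preprocess_set(spectra, config.preprocess)
        write_spectra_csv(pre, out / "spectra_preprocessed.csv")
        done("preprocess", out / "spectra_preprocessed.csv")

        summary_rows = []
        artifacts = []
        for topo_text in config.model.topologies:
            topology = ANNTopology.parse(topo_text)
            runs = (
                [(a,) for a in ANALYTES]
                if topology.n_outputs == 1
                else [tuple(ANALYTES)]
            )
            for analytes in runs:
                tag = _topology_tag(topology, analytes)
                cal = SERSCalibration(pre, conc, topology, analytes)
                res = cal.fit(config.model.train, config.bootstrap)
                boot = res.bootstrap

                (out / f"bootstrap_{tag}.json").write_text(
                    json.dumps(boot.to_json_dict(), indent=1)
                )
                boot.iteration_frame().to_csv(
                    out / f"iterations_{tag}.csv", index=False
                )
                res.predictions().to_csv(
                    out / f"predictions_{tag}.csv", index=False
                )
                (out / f"model_{tag}.json").write_text(res.final_model.to_json())
                ax = res.plot_predicted_vs_actual()
                ax.figure.savefig(out / f"predicted_vs_actual_{tag}.png", dpi=120)
                import matplotlib.pyplot as plt

                plt.close(ax.figure)
                artifacts += [
                    out / f"bootstrap_{tag}.json",
                    out / f"iterations_{tag}.csv",
                    out / f"predictions_{tag}.csv",
                    out / f"model_{tag}.json",
                    out / f"predicted_vs_actual_{tag}.png",
                ]
                for a in analytes:
                    summary_rows.append(
                        {
                            "topology": str(topology),
                            "analyte": a,
                            "mean_q2": boot.mean_q2[a],
                            "mean_rmsep": boot.mean_rmsep[a],
                            "mean_r2_inner": boot.mean_r2_inner[a],
                            "pooled_q2": boot.pooled_q2[a],
                            "pooled_rmsep": boot.pooled_rmsep[a],
                        }
                    )
        import pandas as pd

        pd.DataFrame(summary_rows).to_csv(out / "summary.csv", index=False)
        done("validate", out / "summary.csv", *artifacts)
    except Exception as exc:
        manifest["stages"]["failed"] = f"{type(exc).__name__}: {exc}"
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        raise
    return out
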