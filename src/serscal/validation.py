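"""Bootstrap out-of-bag validation of the neural calibration models.

Each bootstrap iteration draws n samples with replacement as the training
pool; samples never drawn form that iteration's test set.  Within the pool,
~70 % train the network and ~30 % steer early stopping.  Test-set accuracy
is summarised by the validated correlation coefficient

    Q^2 = 1 - sum_i (yhat_i - y_i)^2 / sum_i (y_i - ybar)^2

and the root mean square error of prediction

    RMSEP = sqrt( sum_i (yhat_i - y_i)^2 / n ),

with ybar the mean of the actual values over the same test set.  Statistics
are averaged over iterations (the primary report); pooled-residual
statistics over all out-of-bag predictions are computed alongside.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .chemometrics import ANNTopology, TrainConfig, ann_predict, calibrate_ann
from .exceptions import DegenerateInputError
from .spectra import ANALYTES, SpectraSet, concentration_matrix

__all__ = [
    "AccuracyStats",
    "BootstrapConfig",
    "BootstrapResult",
    "q_squared",
    "rmsep",
    "bootstrap_split",
    "bootstrap_validate",
    "summarize_predictions",
]

logger = logging.getLogger(__name__)


def q_squared(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Validated correlation coefficient on a test set (<= 1)."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("y_hat and y must be equal-length 1-d arrays, n >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("constant actual values: Q^2 undefined")
    return 1.0 - float(np.sum((y_hat - y) ** 2)) / ss_tot


def rmsep(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Root mean square error of prediction, in the units of y."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y.ndim != 1 or y.size < 1:
        raise ValueError("y_hat and y must be equal-length 1-d arrays, n >= 1")
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


@dataclass(frozen=True)
class AccuracyStats:
    """Test-set accuracy of one analyte in one bootstrap iteration."""

    q2: float
    rmsep: float
    n_test: int


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap validation settings.

    ``n_iterations`` defaults to the full 1000-iteration procedure; desk-
    scale runs typically use 100-200.  ``group_by_mixture`` resamples whole
    mixtures (all replicates together) instead of individual samples, which
    avoids replicate leakage between train and test; the default resamples
    at sample level.
    """

    n_iterations: int = 1000
    inner_train_fraction: float = 0.7
    seed: int = 0
    group_by_mixture: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.inner_train_fraction < 1:
            raise ValueError("inner_train_fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class IterationRecord:
    """Bookkeeping for one bootstrap iteration (reproducible in isolation)."""

    seed: int
    oob_idx: np.ndarray
    inner_idx: np.ndarray
    tune_idx: np.ndarray
    stats: dict[str, AccuracyStats]
    r2_inner: dict[str, float]
    input_center: np.ndarray | None = None


@dataclass
class BootstrapResult:
    """Aggregate of a bootstrap validation run.

    ``mean_q2``/``mean_rmsep`` are arithmetic means of the per-iteration
    statistics (the primary report); ``pooled_q2``/``pooled_rmsep`` are
    computed once from all out-of-bag residuals pooled together.
    ``per_sample`` accumulates, for every sample and analyte, how often it
    was out-of-bag and the mean/SD of its out-of-bag predictions.
    """

    analytes: tuple[str, ...]
    topology: ANNTopology
    n_iterations: int
    per_iteration: list[IterationRecord]
    mean_q2: dict[str, float]
    mean_rmsep: dict[str, float]
    mean_r2_inner: dict[str, float]
    pooled_q2: dict[str, float]
    pooled_rmsep: dict[str, float]
    per_sample: pd.DataFrame
    n_failed: int = 0

    def to_json_dict(self) -> dict:
        return {
            "analytes": list(self.analytes),
            "topology": str(self.topology),
            "n_iterations": self.n_iterations,
            "n_failed": self.n_failed,
            "mean_q2": self.mean_q2,
            "mean_rmsep": self.mean_rmsep,
            "mean_r2_inner": self.mean_r2_inner,
            "pooled_q2": self.pooled_q2,
            "pooled_rmsep": self.pooled_rmsep,
            "per_iteration": [
                {
                    "seed": rec.seed,
                    "stats": {
                        a: {"q2": s.q2, "rmsep": s.rmsep, "n_test": s.n_test}
                        for a, s in rec.stats.items()
                    },
                }
                for rec in self.per_iteration
            ],
        }

    def iteration_frame(self) -> pd.DataFrame:
        """Long DataFrame of per-iteration statistics."""
        rows = []
        for i, rec in enumerate(self.per_iteration):
            for a, s in rec.stats.items():
                rows.append(
                    {
                        "iteration": i,
                        "seed": rec.seed,
                        "analyte": a,
                        "q2": s.q2,
                        "rmsep": s.rmsep,
                        "n_test": s.n_test,
                        "r2_inner": rec.r2_inner[a],
                    }
                )
        return pd.DataFrame(rows)


def bootstrap_split(
    n_samples: int,
    rng: np.random.Generator,
    groups: Sequence | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One bootstrap resample: (train index multiset, out-of-bag indices).

    Draws ``n_samples`` indices with replacement; units never drawn form the
    out-of-bag set.  With ``groups`` given, whole groups are drawn with
    replacement and all members of a drawn group enter the training multiset
    together.  An empty out-of-bag set triggers a redraw (logged).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples to bootstrap")
    for attempt in range(1000):
        if groups is None:
            train = rng.integers(0, n_samples, size=n_samples)
            oob_mask = np.ones(n_samples, dtype=bool)
            oob_mask[train] = False
        else:
            groups = np.asarray(groups)
            uniq = np.unique(groups)
            drawn = rng.choice(uniq, size=uniq.size, replace=True)
            member_lists = {g: np.flatnonzero(groups == g) for g in uniq}
            train = np.concatenate([member_lists[g] for g in drawn])
            oob_mask = ~np.isin(np.arange(n_samples), train)
        oob = np.flatnonzero(oob_mask)
        if oob.size > 0:
            if attempt > 0:
                logger.info("bootstrap redraw: %d empty out-of-bag draws", attempt)
            return train, oob
    raise RuntimeError("could not draw a non-empty out-of-bag set")


def bootstrap_validate(
    spectra_set: SpectraSet | np.ndarray,
    concentrations: pd.DataFrame | np.ndarray,
    topology: ANNTopology,
    train_config: TrainConfig | None = None,
    boot_config: BootstrapConfig | None = None,
    analytes: Sequence[str] | None = None,
) -> BootstrapResult:
    """Bootstrap out-of-bag validation of one network configuration.

    ``analytes`` selects the target column(s); its length must equal the
    topology's output count (default: the single analyte must be named for
    1-output models, all three analytes for 3-output models).  Spectra must
    already be preprocessed.  Per-iteration seeds derive deterministically
    from the master seed.  Failed iterations are logged and skipped; more
    than 5 % failures aborts.
    """
    if train_config is None:
        train_config = TrainConfig()
    if boot_config is None:
        boot_config = BootstrapConfig()

    if isinstance(spectra_set, SpectraSet):
        X = spectra_set.intensities
        sample_ids = list(spectra_set.sample_ids)
        meta = spectra_set.metadata
    else:
        X = np.asarray(spectra_set, dtype=float)
        sample_ids = [str(i) for i in range(X.shape[0])]
        meta = None

    if analytes is None:
        if topology.n_outputs == len(ANALYTES):
            analytes = ANALYTES
        else:
            raise ValueError(
                "analytes must be given for a "
                f"{topology.n_outputs}-output topology"
            )
    analytes = tuple(analytes)
    if len(analytes) != topology.n_outputs:
        raise ValueError(
            f"{len(analytes)} analytes for a {topology.n_outputs}-output topology"
        )
    if isinstance(concentrations, pd.DataFrame):
        Y = concentration_matrix(concentrations, analytes)
    else:
        Y = np.atleast_2d(np.asarray(concentrations, dtype=float).T).T
    n = X.shape[0]
    if Y.shape[0] != n:
        raise ValueError("spectra and concentrations disagree on sample count")
    if X.shape[1] != topology.n_inputs:
        raise ValueError(
            f"{X.shape[1]} channels but topology expects {topology.n_inputs}"
        )

    groups = None
    if boot_config.group_by_mixture:
        if meta is None or "mixture_id" not in meta.columns:
            raise ValueError("group_by_mixture needs metadata with mixture_id")
        groups = meta["mixture_id"].to_numpy()

    iter_seeds = np.random.SeedSequence(boot_config.seed).generate_state(
        boot_config.n_iterations
    )
    # Per-sample accumulators, per analyte.
    count = np.zeros(n, dtype=int)
    pred_sum = np.zeros((n, len(analytes)))
    pred_sumsq = np.zeros((n, len(analytes)))
    pooled_y = [[] for _ in analytes]
    pooled_yhat = [[] for _ in analytes]

    records: list[IterationRecord] = []
    n_failed = 0
    max_failed = max(1, int(np.ceil(0.05 * boot_config.n_iterations)))
    for it, s in enumerate(iter_seeds):
        s = int(s) % (2**31)
        rng = np.random.default_rng(s)
        try:
            train_idx, oob_idx = bootstrap_split(n, rng, groups)
            perm = rng.permutation(train_idx)
            n_inner = int(round(boot_config.inner_train_fraction * perm.size))
            n_inner = min(max(n_inner, 1), perm.size - 1)
            inner, tune = perm[:n_inner], perm[n_inner:]
            cfg = replace(train_config, seed=int(rng.integers(2**31)))
            model = calibrate_ann(
                X[inner], Y[inner], X[tune], Y[tune], topology, cfg
            )
            pred_oob = ann_predict(model, X[oob_idx])
            pred_inner = ann_predict(model, X[inner])
            stats = {}
            r2_inner = {}
            for j, a in enumerate(analytes):
                stats[a] = AccuracyStats(
                    q2=q_squared(pred_oob[:, j], Y[oob_idx, j]),
                    rmsep=rmsep(pred_oob[:, j], Y[oob_idx, j]),
                    n_test=oob_idx.size,
                )
                r2_inner[a] = q_squared(pred_inner[:, j], Y[inner, j])
        except (DegenerateInputError, FloatingPointError, ValueError) as exc:
            n_failed += 1
            logger.warning("bootstrap iteration %d (seed %d) failed: %s", it, s, exc)
            if n_failed > max_failed:
                raise RuntimeError(
                    f"{n_failed} bootstrap iterations failed (> 5 %); aborting"
                ) from exc
            continue
        count[oob_idx] += 1
        pred_sum[oob_idx] += pred_oob
        pred_sumsq[oob_idx] += pred_oob**2
        for j in range(len(analytes)):
            pooled_y[j].append(Y[oob_idx, j])
            pooled_yhat[j].append(pred_oob[:, j])
        records.append(
            IterationRecord(
                seed=s,
                oob_idx=oob_idx,
                inner_idx=inner,
                tune_idx=tune,
                stats=stats,
                r2_inner=r2_inner,
                input_center=model.input_center,
            )
        )

    if not records:
        raise RuntimeError("all bootstrap iterations failed")

    mean_q2 = {
        a: float(np.mean([r.stats[a].q2 for r in records])) for a in analytes
    }
    mean_rmsep = {
        a: float(np.mean([r.stats[a].rmsep for r in records])) for a in analytes
    }
    mean_r2_inner = {
        a: float(np.mean([r.r2_inner[a] for r in records])) for a in analytes
    }
    pooled_q2 = {}
    pooled_rmsep = {}
    for j, a in enumerate(analytes):
        yy = np.concatenate(pooled_y[j])
        yh = np.concatenate(pooled_yhat[j])
        pooled_q2[a] = q_squared(yh, yy)
        pooled_rmsep[a] = rmsep(yh, yy)

    mean_pred = np.divide(
        pred_sum, count[:, None], out=np.full_like(pred_sum, np.nan),
        where=count[:, None] > 0,
    )
    # Sample SD of each sample's out-of-bag predictions; undefined below 2 draws.
    with np.errstate(invalid="ignore"):
        var = (pred_sumsq - count[:, None] * mean_pred**2) / (count[:, None] - 1)
        sd_pred = np.sqrt(np.clip(var, 0.0, None))
    sd_pred[count < 2] = np.nan

    rows = []
    for i, sid in enumerate(sample_ids):
        for j, a in enumerate(analytes):
            rows.append(
                {
                    "sample_id": sid,
                    "analyte": a,
                    "actual": Y[i, j],
                    "n_oob": int(count[i]),
                    "mean_pred": mean_pred[i, j],
                    "sd_pred": sd_pred[i, j],
                }
            )
    per_sample = pd.DataFrame(rows)

    return BootstrapResult(
        analytes=analytes,
        topology=topology,
        n_iterations=boot_config.n_iterations,
        per_iteration=records,
        mean_q2=mean_q2,
        mean_rmsep=mean_rmsep,
        mean_r2_inner=mean_r2_inner,
        pooled_q2=pooled_q2,
        pooled_rmsep=pooled_rmsep,
        per_sample=per_sample,
        n_failed=n_failed,
    )


def summarize_predictions(result: BootstrapResult) -> pd.DataFrame:
    """Per-sample predicted-vs-actual table for a recovery plot.

    Columns: sample_id, analyte, actual, n_oob, mean_pred, sd_pred.  The SD
    is NaN (missing, not zero) for samples out-of-bag fewer than twice;
    samples never out-of-bag are flagged in a log message.
    """
    never = result.per_sample.loc[
        result.per_sample["n_oob"] == 0, "sample_id"
    ].unique()
    if never.size:
        logger.warning(
            "%d samples were never out-of-bag: %s", never.size, list(never[:5])
        )
    return result.per_sample.copy()
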