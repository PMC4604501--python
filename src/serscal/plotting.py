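"""Predicted-vs-actual recovery plots."""
from __future__ import annotations

import numpy as np
import pandas as pd


def plot_predicted_vs_actual(
    predictions: pd.DataFrame, analyte: str | None = None, ax=None
):
    """Scatter of mean out-of-bag prediction vs actual concentration.

    Error bars show the SD of each sample's out-of-bag predictions; the
    dashed line is y = x.  ``predictions`` is the per-sample summary table
    (columns sample_id, analyte, actual, mean_pred, sd_pred).
    """
    import matplotlib.pyplot as plt

    if analyte is not None:
        predictions = predictions[predictions["analyte"] == analyte]
        analytes = [analyte]
    else:
        analytes = list(predictions["analyte"].unique())
    if ax is None:
        _, ax = plt.subplots()
    for a in analytes:
        sub = predictions[predictions["analyte"] == a]
        ax.errorbar(
            sub["actual"],
            sub["mean_pred"],
            yerr=np.nan_to_num(sub["sd_pred"].to_numpy(), nan=0.0),
            fmt="o",
            ms=3,
            lw=0.8,
            capsize=2,
            alpha=0.7,
            label=a,
        )
    lim = [
        min(predictions["actual"].min(), predictions["mean_pred"].min()),
        max(predictions["actual"].max(), predictions["mean_pred"].max()),
    ]
    ax.plot(lim, lim, "k--", lw=1, label="y = x")
    ax.set_xlabel("actual concentration (mol/dm$^3$)")
    ax.set_ylabel("predicted concentration (mol/dm$^3$)")
    ax.legend(fontsize=8)
    return ax
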