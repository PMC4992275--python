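"""Two-panel bias/SE figures for a sweep (bias on top, SE below)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .estimators import MODEL_DESCRIPTIONS
from .sweep import SweepSummary

__all__ = ["plot_sweep"]


def plot_sweep(summary: SweepSummary, se_kind: str = "se_empirical"):
    """Bias (top) and SE (bottom) versus the varied edge's odds ratio.

    ``se_kind`` selects ``"se_empirical"`` (SD across replicates) or
    ``"se_model_mean"`` (mean model-based SE).
    """
    if se_kind not in ("se_empirical", "se_model_mean"):
        raise ValueError("se_kind must be 'se_empirical' or 'se_model_mean'")
    fig, (ax_bias, ax_se) = plt.subplots(2, 1, figsize=(6, 7), sharex=True)
    for m in summary.config.models:
        sub = summary.table[summary.table["model_id"] == m].sort_values("odds_ratio")
        label = f"model {m}"
        ax_bias.plot(sub["odds_ratio"], sub["mean_bias"], marker="o", label=label)
        ax_se.plot(sub["odds_ratio"], sub[se_kind], marker="o", label=label)
    ax_bias.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax_bias.set_ylabel(r"bias of $\hat\beta_1$")
    ax_bias.set_title(
        f"scenario {summary.scenario_id}: varying OR({summary.varied_edge})"
    )
    ax_se.set_ylabel("SE" + (" (empirical)" if se_kind == "se_empirical" else " (model)"))
    ax_se.set_xlabel(f"odds ratio of {summary.varied_edge}")
    ax_bias.legend(fontsize=8)
    fig.tight_layout()
    return fig
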