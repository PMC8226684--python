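"""Figures: group trend curves and dynamic-prediction panels."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "dusjm"
import matplotlib.pyplot as plt  # noqa: E402

from .lmm import MixedModelResults  # noqa: E402
from .prediction import SubjectHistory, predict_lesion_free  # noqa: E402


def trend_curve(res: MixedModelResults, grid, covs: dict | None = None):
    """Population mean log-value curve with pointwise 95% delta-method bands.

    Baseline covariates are held at their sample means unless given.
    """
    grid = np.asarray(grid, dtype=float)
    if covs is None:
        df = res.model._df
        covs = {c: float(df[c].mean()) for c in res.spec.covariates}
    X = res.spec.x_row(grid, res.basis, covs)
    mean = X @ res.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, res.vcov_beta, X))
    return mean, mean - 1.959963984540054 * se, mean + 1.959963984540054 * se


def fig2_trends(results_by_group: dict[str, MixedModelResults], grid=None,
                ylabel: str = "log value"):
    """Fitted trends of repeatedly measured DUS values over time per outcome
    group, with shaded pointwise 95% confidence bands."""
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"lesion": "tab:red", "no_lesion": "tab:blue"}
    for i, (name, res) in enumerate(sorted(results_by_group.items())):
        if grid is None:
            tmax = float(res.model._df["time"].max())
            g = np.linspace(0, tmax, 60)
        else:
            g = np.asarray(grid, dtype=float)
        mean, lo, hi = trend_curve(res, g)
        color = colors.get(name, f"C{i}")
        ax.plot(g, mean, label=name.replace("_", " "), color=color)
        ax.fill_between(g, lo, hi, alpha=0.25, color=color)
    ax.set_xlabel("months since procedure")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    return fig


def fig3_panel(res, hist_sequence: list[SubjectHistory], grid, n_mc: int = 0,
               seed: int | None = None):
    """Stacked panels: the lesion-free probability curve after each update
    step, with the measured log values on a twin axis."""
    if not hist_sequence or not hist_sequence[0].measurements:
        raise ValueError("need at least one measurement")
    n = len(hist_sequence)
    fig, axes = plt.subplots(n, 1, figsize=(6, 2.8 * n), squeeze=False)
    for k, hist in enumerate(hist_sequence):
        ax = axes[k, 0]
        g = np.asarray(grid, dtype=float)
        g = g[g >= hist.t - 1e-9]
        pred = predict_lesion_free(res, hist, g, n_mc=n_mc, seed=seed)
        ax.plot(pred.grid, pred.pi, color="tab:green",
                label="lesion-free probability")
        if pred.ci_low is not None:
            ax.fill_between(pred.grid, pred.ci_low, pred.ci_high,
                            color="gray", alpha=0.3)
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel(r"$\pi(u\,|\,t)$")
        ax2 = ax.twinx()
        ts = [m[0] for m in hist.measurements]
        ys = [m[1] for m in hist.measurements]
        ax2.plot(ts, ys, "*", color="tab:blue", markersize=10)
        ax2.set_ylabel("measured log value")
        ax.set_title(f"update {k + 1}: t = {hist.t:.2f} months")
    axes[-1, 0].set_xlabel("months since procedure")
    fig.tight_layout()
    return fig
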