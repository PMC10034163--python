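"""Simple diagnostic plots: scatter, funnel and leave-one-out forest."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .estimators import ratio_estimates
from .harmonize import HarmonizedSet
from .sensitivity import LeaveOneOutResult

__all__ = ["scatter_plot", "funnel_plot", "loo_forest_plot"]


def scatter_plot(hset: HarmonizedSet, results, path) -> None:
    """Per-variant exposure vs outcome effects with fitted estimator lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sign = np.where(hset.gamma < 0, -1.0, 1.0)
    x, y = hset.gamma * sign, hset.Gamma * sign
    ax.errorbar(x, y, xerr=hset.se_gamma, yerr=hset.se_Gamma, fmt="o", ms=4,
                color="0.3", ecolor="0.7", lw=0.8)
    xs = np.linspace(0, x.max() * 1.05, 50)
    for r in results:
        icpt = r.extra.get("intercept", 0.0)
        ax.plot(xs, icpt + r.beta * xs, label=r.method, lw=1.2)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def funnel_plot(hset: HarmonizedSet, path) -> None:
    """Instrument precision against Wald ratio (asymmetry suggests pleiotropy)."""
    b, w, _ = ratio_estimates(hset)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(b, np.sqrt(w), "o", ms=4, color="0.3")
    ax.axvline(float(np.sum(w * b) / np.sum(w)), color="C0", lw=1)
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("sqrt(weight)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def loo_forest_plot(loo: LeaveOneOutResult, path) -> None:
    """Leave-one-out estimates with CIs, full estimate as reference band."""
    fig, ax = plt.subplots(figsize=(5, 0.25 * len(loo.results) + 1.5))
    ys = np.arange(len(loo.results))
    for y, r in zip(ys, loo.results):
        ax.plot([r.ci_low, r.ci_high], [y, y], color="0.5", lw=1)
        ax.plot(r.beta, y, "o", ms=3, color="0.2")
    ax.axvspan(loo.full.ci_low, loo.full.ci_high, color="C0", alpha=0.15)
    ax.axvline(loo.full.beta, color="C0", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels([r.extra.get("omitted", "") for r in loo.results], fontsize=6)
    ax.set_xlabel("IVW estimate omitting one variant")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
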