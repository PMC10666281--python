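"""Figure writers for Shapley explanations (beeswarm-style summary and
dependence scatter) and normalized series with the margin period."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def beeswarm(expl, features: pd.DataFrame, top_k: int = 20, path=None):
    """Summary scatter: one row per feature (by mean |contribution|), x =
    contribution, colour = feature value. A compact stand-in for the usual
    beeswarm summary plot."""
    order = expl.values.abs().mean().sort_values(ascending=False).index[:top_k]
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(order) + 1.5))
    rng = np.random.default_rng(0)
    for row, feat in enumerate(reversed(list(order))):
        sv = expl.values[feat].to_numpy()
        fv = features[feat].to_numpy(dtype=float)
        fr = (fv - fv.min()) / (np.ptp(fv) or 1.0)
        ax.scatter(
            sv,
            row + rng.uniform(-0.25, 0.25, len(sv)),
            c=fr, cmap="coolwarm", s=8, alpha=0.8,
        )
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels(list(reversed(list(order))))
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("contribution to predicted impact")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def dependence(expl, features: pd.DataFrame, feature_name: str, path=None):
    """Feature value vs its contribution per area, with Pearson R in the title."""
    from aqcausal.attribution import dependence_summary

    tab, r = dependence_summary(expl, features, feature_name)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(tab["feature_value"], tab["shap_value"], s=10, alpha=0.7)
    ax.axhline(0, color="grey", lw=0.8)
    ax.set_xlabel(feature_name)
    ax.set_ylabel("contribution")
    ax.set_title(f"R = {r:.2f}" if np.isfinite(r) else "R undefined")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def normalized_series(daily: pd.DataFrame, t0, margin_half_width: int = 14,
                      cps=None, path=None):
    """Normalized daily series with T0, the margin period, and any detected
    change points marked."""
    t0 = pd.Timestamp(t0)
    fig, ax = plt.subplots(figsize=(9, 3.5))
    values = daily["value"] if isinstance(daily, pd.DataFrame) else daily
    ax.plot(values.index, values.to_numpy(), lw=0.8)
    hw = pd.Timedelta(days=margin_half_width)
    ax.axvspan(t0 - hw, t0 + hw, color="orange", alpha=0.25, label="margin period")
    ax.axvline(t0, color="red", lw=1.2, ls="--", label="T0")
    if cps is not None:
        for d in cps.dates:
            ax.axvline(pd.Timestamp(d), color="green", lw=0.8, ls=":")
        ax.plot(cps.fitted.index, cps.fitted.to_numpy(), color="black", lw=1.2)
    ax.set_ylabel("normalized concentration")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
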