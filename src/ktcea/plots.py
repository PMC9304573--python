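"""Convenience figures: tornado diagram, cost-effectiveness plane, CEAC."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["tornado_plot", "ce_plane_plot", "ceac_plot"]


def tornado_plot(tornado, path, top: int = 12):
    df = tornado.head(top).iloc[::-1]
    base = 0.5 * (df["outcome_at_low"] + df["outcome_at_high"]).median()
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(df) + 1.5))
    y = np.arange(len(df))
    left = np.minimum(df["outcome_at_low"], df["outcome_at_high"])
    width = (df["outcome_at_high"] - df["outcome_at_low"]).abs()
    ax.barh(y, width, left=left, color="#4878d0")
    ax.set_yticks(y, df["parameter"])
    ax.axvline(base, color="k", lw=0.8)
    ax.set_xlabel("incremental outcome (USD)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_plane_plot(plane, path):
    df = plane["per_draw"]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["delta_qaly"], df["delta_cost"], s=6, alpha=0.4)
    xs = np.linspace(df["delta_qaly"].min(), df["delta_qaly"].max(), 50)
    ax.plot(xs, plane["wtp"] * xs, "r--", lw=1, label=f"WTP {plane['wtp']:,.0f}/QALY")
    ax.axhline(0, color="k", lw=0.6)
    ax.axvline(0, color="k", lw=0.6)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (USD)")
    ax.set_title(f"{plane['reference']} vs {plane['comparator']}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(curve, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in curve.columns:
        if col == "wtp":
            continue
        ax.plot(curve["wtp"], curve[col], label=col)
    ax.set_xlabel("willingness to pay (USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
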