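"""Optional diagnostic plots; numeric tables are the authoritative output."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .psychometric import SimultaneityJudgment, compute_rates

__all__ = ["plot_group_curves"]

_COLORS = {"active": "tab:blue", "passive": "tab:red"}


def plot_group_curves(trials: pd.DataFrame, estimates: pd.DataFrame, path) -> None:
    """Mean fitted window curves per condition with the 50% crossings marked.

    For each condition, every participant's fitted two-sided curve is
    evaluated on an SOA grid and averaged; vertical lines mark the group
    mean crossings (the window limits) and the dashed line the 50%
    criterion. Observed mean per-SOA rates are overlaid as points.
    """
    soa_min = float(trials["soa_ms"].min())
    soa_max = float(trials["soa_ms"].max())
    grid = np.linspace(soa_min, soa_max, 400)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cond, sub in trials.groupby("condition", sort=True):
        color = _COLORS.get(cond, None)
        curves, rates = [], []
        for pid, unit in sub.groupby("participant"):
            try:
                res = SimultaneityJudgment(unit).fit()
            except Exception:
                continue
            curves.append(res.predict(grid))
            rates.append(compute_rates(unit)["rate"])
        if not curves:
            continue
        mean_curve = np.mean(curves, axis=0)
        ax.plot(grid, 100 * mean_curve, color=color, label=cond)
        rate_tbl = pd.concat(rates, axis=1).mean(axis=1)
        ax.plot(rate_tbl.index, 100 * rate_tbl, "o", ms=4, color=color, alpha=0.6)
        est = estimates.loc[estimates["condition"] == cond]
        for x in (-est["av_ms"].mean(), est["va_ms"].mean()):
            ax.axvline(x, color=color, lw=1, ls=":")
    ax.axhline(50, color="k", lw=0.8, ls="--")
    ax.set_xlabel("SOA (ms)  [negative: auditory leads]")
    ax.set_ylabel("perceived synchrony (%)")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
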