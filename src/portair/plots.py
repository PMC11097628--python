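"""Figure exports: stacked intake bars, ranked disparity bars, Q-Q plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .equity import DisparityResult


def intake_bars(intake_by_scenario: dict[str, dict[str, float]], path: str) -> None:
    """Stacked horizontal bars of intake (g/yr) by category, one bar per
    scenario."""
    df = pd.DataFrame(intake_by_scenario).T.fillna(0.0)
    ax = df.plot.barh(stacked=True, figsize=(9, 0.5 * len(df) + 2))
    ax.set_xlabel("annual inhalation intake (g PM$_{2.5}$/yr)")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)


def disparity_bars(result: DisparityResult, path: str) -> None:
    """Ranked per-source relative exposure disparity for one group."""
    ps = result.per_source_disparity * 100.0
    colors = ["firebrick" if v > 0 else "steelblue" for v in ps]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(ps) + 2))
    ax.barh(ps.index[::-1], ps.to_numpy()[::-1], color=colors[::-1])
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("relative exposure disparity (%)")
    ax.set_title(
        f"{result.group}: average disparity {100 * result.disparity:+.0f}%, "
        f"{100 * result.fraction_sources_positive:.0f}% of sources positive"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def qq_plot(qq_tables: dict[str, pd.DataFrame], path: str) -> None:
    """Q-Q plot of group vs population exposure quantiles with a 1:1
    reference line."""
    fig, ax = plt.subplots(figsize=(6, 6))
    hi = 0.0
    for label, tab in qq_tables.items():
        ax.plot(tab["population_quantile"], tab["group_quantile"],
                marker="o", ms=3, lw=1, label=label)
        hi = max(hi, tab[["population_quantile", "group_quantile"]].to_numpy().max())
    ax.plot([0, hi], [0, hi], "k--", lw=0.8, label="1:1")
    ax.set_xlabel("population quantile ($\\mu$g m$^{-3}$)")
    ax.set_ylabel("group quantile ($\\mu$g m$^{-3}$)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
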