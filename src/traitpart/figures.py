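"""Optional figure exports: decomposition stacked bars and trait-biomass fits."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def decomposition_figure(decomp: pd.DataFrame, path: str | Path) -> None:
    """Stacked turnover/ITV bars with a dot at the specific relative SS,
    one panel per site, traits on the x axis, treatment terms side by side."""
    sites = sorted(decomp["site"].unique())
    terms = [t for t in decomp["term"].unique() if t not in ("residual", "total")]
    fig, axes = plt.subplots(1, len(sites), figsize=(5 * len(sites), 4), squeeze=False)
    for ax, site in zip(axes[0], sites):
        sub = decomp[(decomp["site"] == site) & decomp["term"].isin(terms)]
        traits = sorted(sub["trait"].unique())
        width = 0.8 / len(terms)
        for k, term in enumerate(terms):
            s = sub[sub["term"] == term].set_index("trait").reindex(traits)
            x = [i + k * width for i in range(len(traits))]
            ax.bar(x, s["rel_fixed"], width, label=f"{term} turnover" if site == sites[0] else None)
            ax.bar(x, s["rel_itv"], width, bottom=s["rel_fixed"],
                   label=f"{term} ITV" if site == sites[0] else None)
            ax.plot(x, s["rel_specific"], "k.", ms=6)
        ax.set_xticks(range(len(traits)))
        ax.set_xticklabels(traits, rotation=45, ha="right")
        ax.set_title(site)
        ax.set_ylabel("fraction of specific total SS")
    fig.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def trait_biomass_figure(
    models: pd.DataFrame,
    cwm: pd.DataFrame,
    biomass: pd.DataFrame,
    path: str | Path,
    component: str = "specific",
) -> None:
    """Scatter of biomass vs each trait's CWM; significant fits drawn as lines."""
    sub = models[models["component"] == component]
    traits = sorted(sub["trait"].unique())
    bio = biomass.set_index("plot_id")["total_biomass"]
    fig, axes = plt.subplots(1, len(traits), figsize=(3 * len(traits), 3), squeeze=False)
    for ax, trait in zip(axes[0], traits):
        pts = cwm[(cwm["trait"] == trait) & (cwm["component"] == component)]
        x = pts.set_index("plot_id")["value"]
        y = bio.reindex(x.index)
        ax.scatter(x, y, s=10, alpha=0.6)
        for r in sub[sub["trait"] == trait].itertuples(index=False):
            if r.significant:
                xs = pd.Series([x.min(), x.max()])
                intercept = y.mean() - r.slope * x.mean()
                ax.plot(xs, intercept + r.slope * xs, "r-", lw=1)
        ax.set_xlabel(trait)
    axes[0][0].set_ylabel("biomass (g m$^{-2}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
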