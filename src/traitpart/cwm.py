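"""Community-weighted mean (CWM) trait estimation by abundance-weighted bootstrap.

The plot-level CWM of a trait is estimated nonparametrically: individual trait
values are resampled with species chosen proportionally to their relative
percent cover, individuals uniformly within species.  Averaging the resample
means gives the "specific" CWM (turnover + intraspecific variation together).
Freezing every species at a control-condition reference mean and resampling
the same way gives the "fixed" CWM (turnover only); the difference is the
intraspecific (ITV) component.
"""
from __future__ import annotations

import logging
import zlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("traitpart")

TRAITS = ("SLA", "LDMC", "CN", "height", "leaf_area", "tannin")

#: reference-mean provenance codes, in fallback order
PROVENANCE = ("control", "ambient_fallback", "site_fallback")


def select_dominant_species(
    covers: Mapping[str, float] | Iterable[tuple[str, float]],
    threshold: float = 0.8,
) -> list[str]:
    """Minimal set of most-abundant species strictly exceeding ``threshold``
    cumulative relative cover.

    Species are ranked by descending cover, ties broken by species identifier;
    the returned prefix is the smallest whose cumulative relative cover is
    strictly greater than ``threshold`` (so a cumulative share of exactly 0.8
    does not suffice at the default threshold).
    """
    items = list(covers.items()) if isinstance(covers, Mapping) else list(covers)
    total = float(sum(c for _, c in items))
    if total <= 0:
        raise ValueError("empty community: all covers are zero")
    items.sort(key=lambda sc: (-sc[1], sc[0]))
    chosen: list[str] = []
    cum = 0.0
    for sp, c in items:
        chosen.append(sp)
        cum += c / total
        if cum > threshold:
            break
    return chosen


def filter_dominant(cover: pd.DataFrame, threshold: float = 0.8) -> pd.DataFrame:
    """Restrict a cover table to each plot's dominant (>threshold) species."""
    keep = []
    for plot, grp in cover.groupby("plot_id", sort=True):
        dom = set(select_dominant_species(zip(grp["species"], grp["cover"]), threshold))
        keep.append(grp[grp["species"].isin(dom)])
    return pd.concat(keep, ignore_index=True)


def _cell_rng(seed: int, plot_id: str, trait: str) -> np.random.Generator:
    # stable, order-independent stream per plot x trait
    key = zlib.crc32(f"{plot_id}|{trait}".encode())
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, key])


def _bootstrap_cell(
    pools: Sequence[np.ndarray],
    weights: np.ndarray,
    n_resamples: int,
    sample_size: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Mean and SD over resamples of the abundance-weighted resample mean."""
    counts = rng.multinomial(sample_size, weights, size=n_resamples)
    totals = np.zeros(n_resamples)
    for s, vals in enumerate(pools):
        cs = counts[:, s]
        m = int(cs.sum())
        if m == 0:
            continue
        if len(vals) == 1:
            totals += cs * vals[0]
        else:
            draws = vals[rng.integers(0, len(vals), m)]
            seg = np.repeat(np.arange(n_resamples), cs)
            totals += np.bincount(seg, weights=draws, minlength=n_resamples)
    means = totals / sample_size
    se = float(means.std(ddof=1)) if n_resamples > 1 else 0.0
    return float(means.mean()), se


def _bootstrap_component(
    value_pools: Mapping[str, Mapping[str, Mapping[str, np.ndarray]]],
    covers: pd.DataFrame,
    component: str,
    traits: Sequence[str],
    n_resamples: int,
    sample_size: int,
    seed: int,
) -> pd.DataFrame:
    rows = []
    cover_by_plot = {p: g for p, g in covers.groupby("plot_id", sort=True)}
    for plot in sorted(cover_by_plot):
        grp = cover_by_plot[plot]
        sp_cover = dict(zip(grp["species"], grp["cover"].astype(float)))
        plot_pools = value_pools.get(plot, {})
        for trait in traits:
            pools, w = [], []
            for sp in sorted(sp_cover):
                vals = plot_pools.get(sp, {}).get(trait)
                if vals is not None and len(vals) and sp_cover[sp] > 0:
                    pools.append(vals)
                    w.append(sp_cover[sp])
            if not pools:
                logger.warning(
                    "plot %s trait %s: no species with both cover and trait data; "
                    "%s CWM recorded as missing", plot, trait, component,
                )
                rows.append((plot, trait, component, np.nan, np.nan))
                continue
            w = np.asarray(w, dtype=float)
            w /= w.sum()
            rng = _cell_rng(seed, plot, trait)
            est, se = _bootstrap_cell(pools, w, n_resamples, sample_size, rng)
            rows.append((plot, trait, component, est, se))
    return pd.DataFrame(
        rows, columns=["plot_id", "trait", "component", "value", "bootstrap_se"]
    )


def _pools_from_measurements(
    traits: pd.DataFrame,
) -> dict[str, dict[str, dict[str, np.ndarray]]]:
    pools: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for (plot, sp, tr), grp in traits.groupby(["plot_id", "species", "trait"], sort=True):
        pools.setdefault(plot, {}).setdefault(sp, {})[tr] = grp["value"].to_numpy(float)
    return pools


def bootstrap_cwm(
    traits: pd.DataFrame,
    covers: pd.DataFrame,
    n_resamples: int = 100,
    sample_size: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Specific CWM per plot x trait by the abundance-weighted bootstrap.

    Per resample, ``sample_size`` individuals are drawn: species proportional
    to relative cover (restricted to species with trait data, weights
    renormalized), individuals uniformly within species.  The statistic is the
    resample mean; the estimate averages ``n_resamples`` resample means and
    ``bootstrap_se`` is their SD.  Deterministic given ``seed``.
    """
    trait_names = sorted(traits["trait"].unique())
    pools = _pools_from_measurements(traits)
    return _bootstrap_component(
        pools, covers, "specific", trait_names, n_resamples, sample_size, seed
    )


def reference_species_means(traits: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per site x species x trait reference means from control conditions.

    Primary source: mean over control plots (no nutrient, no fence); if a
    species lacks control-plot data, fall back to unfertilized ("ambient")
    plots, then to all plots of the site.  Provenance is recorded per row.
    """
    meta = design.set_index("plot_id")[["site", "nutrient", "fence"]]
    missing = set(traits["plot_id"]) - set(meta.index)
    if missing:
        raise ValueError(f"trait plots absent from design: {sorted(missing)}")
    t = traits.merge(meta, left_on="plot_id", right_index=True)
    rows = []
    for (site, sp, tr), grp in t.groupby(["site", "species", "trait"], sort=True):
        ctrl = grp[(grp["nutrient"] == 0) & (grp["fence"] == 0)]
        if len(ctrl):
            rows.append((site, sp, tr, ctrl["value"].mean(), "control"))
            continue
        amb = grp[grp["nutrient"] == 0]
        if len(amb):
            rows.append((site, sp, tr, amb["value"].mean(), "ambient_fallback"))
        else:
            rows.append((site, sp, tr, grp["value"].mean(), "site_fallback"))
    return pd.DataFrame(
        rows, columns=["site", "species", "trait", "reference_mean", "provenance"]
    )


def fixed_cwm(
    species_means: pd.DataFrame,
    covers: pd.DataFrame,
    design: pd.DataFrame,
    n_resamples: int = 100,
    sample_size: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Fixed-reference CWM: the same bootstrap with each species' trait
    distribution collapsed to its site-level reference mean."""
    site_of = design.set_index("plot_id")["site"].to_dict()
    by_site: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for r in species_means.itertuples(index=False):
        by_site.setdefault(r.site, {}).setdefault(r.species, {})[r.trait] = np.array(
            [r.reference_mean]
        )
    pools = {
        plot: by_site.get(site_of.get(plot, ""), {})
        for plot in covers["plot_id"].unique()
    }
    trait_names = sorted(species_means["trait"].unique())
    return _bootstrap_component(
        pools, covers, "fixed", trait_names, n_resamples, sample_size, seed
    )


def itv_component(specific: pd.DataFrame, fixed: pd.DataFrame) -> pd.DataFrame:
    """ITV = specific − fixed, exact subtraction per plot x trait."""
    s = specific.set_index(["plot_id", "trait"])
    f = fixed.set_index(["plot_id", "trait"])
    mismatch = s.index.symmetric_difference(f.index)
    if len(mismatch):
        raise ValueError(
            f"specific/fixed CWM key mismatch: {sorted(map(tuple, mismatch))[:10]}"
        )
    out = pd.DataFrame(
        {
            "plot_id": [i[0] for i in s.index],
            "trait": [i[1] for i in s.index],
            "component": "itv",
            "value": s["value"].to_numpy() - f.loc[s.index, "value"].to_numpy(),
            "bootstrap_se": np.nan,
        }
    )
    return out.reset_index(drop=True)


def cwm_wide(cwm: pd.DataFrame, component: str = "specific") -> pd.DataFrame:
    """Pivot a long CWM table to a plot x trait matrix for one component."""
    sub = cwm[cwm["component"] == component]
    return sub.pivot(index="plot_id", columns="trait", values="value")
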