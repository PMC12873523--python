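"""Sum-of-squares decomposition of CWM variation into turnover, ITV and covariation.

For each design term of the 2x2 factorial, separate ANOVAs on the specific CWM,
the fixed CWM and the ITV component yield sums of squares related by

    SS_specific = SS_fixed + SS_itv + SS_cov

where the covariation term SS_cov is positive when species turnover and
intraspecific shifts reinforce each other and negative when they oppose.
Relative contributions are expressed as fractions of the specific-CWM total SS
so sources and terms are comparable across traits and sites.
"""
from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("traitpart")

TERMS = ("nutrient", "fence", "nutrient:fence")
TREATMENT_TERMS = TERMS


def effect_columns(design: pd.DataFrame, terms: Sequence[str] = TERMS) -> np.ndarray:
    """Sum-to-zero (±1) coded columns for the 2x2 factorial terms."""
    def col(name: str) -> np.ndarray:
        return 2.0 * design[name].to_numpy(float) - 1.0

    out = []
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            out.append(col(a) * col(b))
        else:
            out.append(col(t))
    return np.column_stack(out)


def factorial_anova_ss(
    response: pd.Series,
    design: pd.DataFrame,
    terms: Sequence[str] = TERMS,
) -> pd.DataFrame:
    """Sequential (type-I) ANOVA of one per-plot response on the 2x2 factorial.

    ``response`` is indexed by plot_id; ``design`` must cover one site.  Block
    is deliberately not a term here: the decomposition ANOVAs use only the two
    treatments and their interaction.  Under a balanced design the effect-coded
    columns are orthogonal, so the sequential SS are order-invariant.
    """
    if design["site"].nunique() != 1:
        raise ValueError("factorial_anova_ss expects a single-site design")
    y = response.reindex(design["plot_id"]).to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("response missing for some plots")
    n = len(y)
    cells = design.groupby(["nutrient", "fence"]).size()
    if len(cells) < 4 or cells.nunique() > 1:
        logger.warning("unbalanced 2x2 design: sequential SS depend on term order")
    X = np.column_stack([np.ones(n), effect_columns(design, terms)])
    Q, _ = np.linalg.qr(X)
    qty = Q.T @ y
    ss_seq = qty[1:] ** 2  # per term, after intercept
    ss_total = float(y @ y - qty[0] ** 2)
    ss_resid = max(ss_total - float(ss_seq.sum()), 0.0)
    df_resid = n - X.shape[1]
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan
    rows = []
    for t, ss in zip(terms, ss_seq):
        ms = float(ss)
        F = ms / ms_resid if ms_resid and ms_resid > 0 else np.nan
        p = float(stats.f.sf(F, 1, df_resid)) if np.isfinite(F) else np.nan
        rows.append((t, 1, float(ss), ms, F, p))
    rows.append(("residual", df_resid, ss_resid, ms_resid, np.nan, np.nan))
    rows.append(("total", n - 1, ss_total, ss_total / (n - 1), np.nan, np.nan))
    return pd.DataFrame(rows, columns=["term", "df", "SS", "MS", "F", "p"])


def decompose_ss(
    anova_specific: pd.DataFrame,
    anova_fixed: pd.DataFrame,
    anova_itv: pd.DataFrame,
) -> pd.DataFrame:
    """Per-term partition SS_cov = SS_specific − SS_fixed − SS_itv.

    Relative contributions are fractions of the specific-CWM *total* SS;
    negative covariation is reported as-is, never clipped.
    """
    tabs = {
        "specific": anova_specific.set_index("term"),
        "fixed": anova_fixed.set_index("term"),
        "itv": anova_itv.set_index("term"),
    }
    terms = list(tabs["specific"].index)
    for name, tab in tabs.items():
        if list(tab.index) != terms or not tab["df"].equals(tabs["specific"]["df"]):
            raise ValueError(f"ANOVA table '{name}' does not share terms/df")
    total_spec = float(tabs["specific"].loc["total", "SS"])
    rows = []
    for t in terms:
        s = float(tabs["specific"].loc[t, "SS"])
        f = float(tabs["fixed"].loc[t, "SS"])
        i = float(tabs["itv"].loc[t, "SS"])
        c = s - f - i
        denom = total_spec if total_spec > 0 else np.nan
        rows.append(
            (
                t,
                int(tabs["specific"].loc[t, "df"]),
                s, f, i, c,
                s / denom, f / denom, i / denom, c / denom,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "term", "df",
            "ss_specific", "ss_fixed", "ss_itv", "ss_cov",
            "rel_specific", "rel_fixed", "rel_itv", "rel_cov",
        ],
    )


def decompose_cwm(cwm: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Run the full decomposition per site x trait from a long CWM table."""
    out = []
    for site, dsite in design.groupby("site", sort=True):
        plots = set(dsite["plot_id"])
        sub = cwm[cwm["plot_id"].isin(plots)]
        for trait in sorted(sub["trait"].unique()):
            tri = {}
            ok = True
            for comp in ("specific", "fixed", "itv"):
                ser = sub[(sub["trait"] == trait) & (sub["component"] == comp)]
                ser = ser.set_index("plot_id")["value"]
                if ser.reindex(dsite["plot_id"]).isna().any():
                    logger.warning(
                        "site %s trait %s: missing %s CWM, skipped", site, trait, comp
                    )
                    ok = False
                    break
                tri[comp] = factorial_anova_ss(ser, dsite)
            if not ok:
                continue
            d = decompose_ss(tri["specific"], tri["fixed"], tri["itv"])
            d.insert(0, "trait", trait)
            d.insert(0, "site", site)
            out.append(d)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


def turnover_itv_fractions(
    decomp: pd.DataFrame, terms: Sequence[str] = TREATMENT_TERMS
) -> tuple[float, float]:
    """Treatment-driven split between turnover and ITV.

    Sums ``ss_fixed`` and ``ss_itv`` over the treatment terms (all sites/traits
    present in ``decomp``) and normalizes the pair to 1.  Returns
    ``(turnover_fraction, itv_fraction)``; NaNs if there is no treatment signal.
    """
    sub = decomp[decomp["term"].isin(terms)]
    tf = float(sub["ss_fixed"].sum())
    ti = float(sub["ss_itv"].sum())
    tot = tf + ti
    if tot <= 0:
        return (np.nan, np.nan)
    return (tf / tot, ti / tot)


def decomposition_report(decomp: pd.DataFrame) -> pd.DataFrame:
    """Tidy stacked-bar-ready export: bars for turnover/ITV relative SS,
    a dot series for the specific total, and the covariation as its own row."""
    if decomp.empty:
        return pd.DataFrame(
            columns=["site", "trait", "term", "source", "series", "value"]
        )
    rows = []
    for r in decomp.itertuples(index=False):
        rows.append((r.site, r.trait, r.term, "turnover", "bar", r.rel_fixed))
        rows.append((r.site, r.trait, r.term, "itv", "bar", r.rel_itv))
        rows.append((r.site, r.trait, r.term, "covariation", "bar", r.rel_cov))
        rows.append((r.site, r.trait, r.term, "specific", "dot", r.rel_specific))
    return pd.DataFrame(
        rows, columns=["site", "trait", "term", "source", "series", "value"]
    )
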