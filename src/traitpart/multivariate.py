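"""Multi-trait composition analysis: standardization, Bray-Curtis, PERMANOVA.

The six CWM traits live on incommensurable scales, so they are standardized to
a common nonnegative range before the Bray-Curtis dissimilarity is computed.
PERMANOVA partitions the total squared dissimilarity by the factorial design
terms sequentially (order-entered, adonis2-style) and derives p-values from
free permutation of plots, with optional within-block restriction.
"""
from __future__ import annotations

import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .decompose import effect_columns

logger = logging.getLogger("traitpart")

PERMANOVA_TERMS = ("nutrient", "fence", "nutrient:fence")


def standardize_traits(matrix: pd.DataFrame, method: str = "range01") -> pd.DataFrame:
    """Map each trait column to a nonnegative, commensurate scale.

    ``range01``: (x - min)/(max - min) per column.  ``zscore_shift``: z-score,
    then shift by the column minimum to nonnegativity.  Zero-range columns are
    dropped with a warning; a single plot cannot be standardized.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 plots to standardize")
    out = {}
    for col in matrix.columns:
        x = matrix[col].astype(float)
        rng = x.max() - x.min()
        if rng == 0 or not np.isfinite(rng):
            logger.warning("trait %s has zero range and was dropped", col)
            continue
        if method == "range01":
            out[col] = (x - x.min()) / rng
        elif method == "zscore_shift":
            z = (x - x.mean()) / x.std(ddof=1)
            out[col] = z - z.min()
        else:
            raise ValueError(f"unknown standardization method {method!r}")
    if not out:
        raise ValueError("no traits with nonzero range")
    return pd.DataFrame(out, index=matrix.index)


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = sum|xi-xj| / sum(xi+xj) between rows."""
    X = matrix.to_numpy(float)
    if (X < 0).any():
        i, j = np.argwhere(X < 0)[0]
        raise ValueError(
            f"negative entry at plot {matrix.index[i]!r}, trait {matrix.columns[j]!r}"
        )
    if (X.sum(axis=1) == 0).any():
        bad = matrix.index[X.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero rows: {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in matrix.index])


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _term_projectors(design: pd.DataFrame, terms: Sequence[str]):
    """Sequential orthonormal bases (after the intercept) per design term."""
    n = len(design)
    X = np.column_stack([np.ones(n), effect_columns(design, terms)])
    q, r = np.linalg.qr(X)
    # columns with ~zero diagonal in R are aliased given earlier terms
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())
    bases, dfs = [], []
    for k, term in enumerate(terms, start=1):
        if keep[k]:
            bases.append(q[:, k])
            dfs.append(1)
        else:
            bases.append(None)
            dfs.append(0)
            logger.warning("term %s is rank-deficient given earlier terms", term)
    return bases, dfs


def _term_ss(G: np.ndarray, bases) -> np.ndarray:
    return np.array([float(b @ G @ b) if b is not None else 0.0 for b in bases])


def permanova(
    dist: DistanceMatrix,
    design: pd.DataFrame,
    terms: Sequence[str] = PERMANOVA_TERMS,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "sampled",
    restrict_blocks: bool = False,
) -> pd.DataFrame:
    """Sequential PERMANOVA of a distance matrix on the factorial design.

    Pseudo-F per term is (SS_term/df)/(SS_resid/df_resid) from the
    Gower-centered inner-product matrix; p_perm = (1 + #{F* >= F}) / (1 + n_perm)
    under free row permutation (``method='exact'`` enumerates all n!
    permutations for n <= 8 and reports the exact tail probability).
    Deterministic given ``seed``.
    """
    design = design.set_index("plot_id").loc[list(dist.ids)].reset_index()
    d = dist.data
    n = d.shape[0]
    G = _gower_center(d)
    bases, dfs = _term_projectors(design, terms)
    ss_total = float(np.trace(G))
    ss_terms = _term_ss(G, bases)
    df_resid = n - 1 - int(sum(dfs))
    ss_resid = max(ss_total - float(ss_terms.sum()), 0.0)
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        # ms_resid == 0 with positive term SS is perfect separation: F = inf
        F_obs = np.array(
            [
                (ss / df) / ms_resid if df > 0 else np.nan
                for ss, df in zip(ss_terms, dfs)
            ]
        )

    def f_for(perm: np.ndarray) -> np.ndarray:
        Gp = G[np.ix_(perm, perm)]
        ssp = _term_ss(Gp, bases)
        rp = max(ss_total - float(ssp.sum()), 0.0)
        msr = rp / df_resid if df_resid > 0 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.array(
                [
                    (ss / df) / msr if df > 0 else np.nan
                    for ss, df in zip(ssp, dfs)
                ]
            )

    counts = np.zeros(len(terms))
    if method == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        total = 0
        for perm in itertools.permutations(range(n)):
            fs = f_for(np.array(perm))
            counts += fs >= F_obs - 1e-12
            total += 1
        p = counts / total
        n_eff = total
    else:
        rng = np.random.default_rng(seed)
        blocks = design["block"].to_numpy()
        for _ in range(n_perm):
            if restrict_blocks:
                perm = np.arange(n)
                for b in np.unique(blocks):
                    idx = np.where(blocks == b)[0]
                    perm[idx] = rng.permutation(idx)
            else:
                perm = rng.permutation(n)
            fs = f_for(perm)
            counts += fs >= F_obs - 1e-12
        p = (1.0 + counts) / (1.0 + n_perm)
        n_eff = n_perm

    rows = []
    for term, df, ss, F, pp in zip(terms, dfs, ss_terms, F_obs, p):
        rows.append(
            (term, df, float(ss), float(ss) / ss_total, F,
             pp if df > 0 else np.nan, n_eff)
        )
    rows.append(("residual", df_resid, ss_resid, ss_resid / ss_total,
                 np.nan, np.nan, n_eff))
    rows.append(("total", n - 1, ss_total, 1.0, np.nan, np.nan, n_eff))
    return pd.DataFrame(
        rows, columns=["term", "df", "SS", "R2", "pseudo_F", "p_perm", "n_perm"]
    )
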