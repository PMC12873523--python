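"""Calibration and parameter-recovery experiments for the whole pipeline.

Each function runs one self-contained experiment — identity checks on the
sum-of-squares decomposition, agreement of the mixed-model F-tests with the
classical randomized-complete-block ANOVA, PERMANOVA exactness and type-I
calibration, bootstrap consistency, and recovery of known turnover/ITV splits
and trait-biomass coefficients from synthetic communities — and returns the
measured quantities.  The test suite asserts on these numbers and the
acceptance script reports them.
"""
from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from . import cwm as cwm_mod
from . import lmm as lmm_mod
from . import multivariate as mv_mod
from .decompose import decompose_cwm, decompose_ss, factorial_anova_ss
from .pipeline import PipelineConfig, run_pipeline
from .simulate import (
    SimulationParams,
    TRAITS,
    generate_community,
    generate_design,
    mixed_params,
    pure_itv_params,
    pure_turnover_params,
)


def _sub_seeds(seed: int, n: int, key: str) -> list[int]:
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(key.encode())])
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# decomposition identity suite

def decomposition_identity(n_triples: int = 1000, seed: int = 0) -> dict:
    """Machine-precision identities on random response triples.

    For random specific/fixed responses on a balanced 16-plot design (itv
    defined as their difference), checks ss_cov = ss_specific - ss_fixed -
    ss_itv and additivity of the relative contributions per term.
    """
    design = generate_design(1, 4, seed=seed)
    rng = np.random.default_rng(seed)
    max_id_err = 0.0
    max_add_err = 0.0
    for _ in range(n_triples):
        spec = pd.Series(rng.normal(0, 1 + 9 * rng.random(), 16),
                         index=design["plot_id"])
        fixed = pd.Series(rng.normal(0, 1, 16), index=design["plot_id"])
        itv = spec - fixed
        d = decompose_ss(
            factorial_anova_ss(spec, design),
            factorial_anova_ss(fixed, design),
            factorial_anova_ss(itv, design),
        )
        scale = max(float(d["ss_specific"].abs().max()), 1e-300)
        id_err = (
            (d["ss_cov"] - (d["ss_specific"] - d["ss_fixed"] - d["ss_itv"]))
            .abs().max() / scale
        )
        add_err = (
            (d["rel_fixed"] + d["rel_itv"] + d["rel_cov"] - d["rel_specific"])
            .abs().max()
        )
        max_id_err = max(max_id_err, float(id_err))
        max_add_err = max(max_add_err, float(add_err))
    return {
        "max_identity_rel_error": max_id_err,
        "max_additivity_error": max_add_err,
        "n": n_triples,
    }


# ---------------------------------------------------------------------------
# RCBD oracle equivalence

def rcbd_oracle(y: np.ndarray, design: pd.DataFrame) -> pd.DataFrame:
    """Classical two-stratum RCBD ANOVA (blocks + 2x2 treatments), closed form."""
    n = len(y)
    blocks = design["block"].to_numpy()
    t = design.groupby("block").size().iloc[0]
    gm = y.mean()
    ss_block = float(
        sum(t * (y[blocks == b].mean() - gm) ** 2 for b in np.unique(blocks))
    )
    cn = 2.0 * design["nutrient"].to_numpy(float) - 1.0
    cf = 2.0 * design["fence"].to_numpy(float) - 1.0
    rows = []
    ss_terms = {}
    for term, c in (("nutrient", cn), ("fence", cf), ("nutrient:fence", cn * cf)):
        ss_terms[term] = float((c @ y) ** 2 / n)
    ss_tot = float(((y - gm) ** 2).sum())
    df_e = (len(np.unique(blocks)) - 1) * (t - 1)
    ss_e = ss_tot - ss_block - sum(ss_terms.values())
    ms_e = ss_e / df_e
    for term, ss in ss_terms.items():
        F = ss / ms_e
        rows.append((term, 1, df_e, F, float(stats.f.sf(F, 1, df_e))))
    return pd.DataFrame(rows, columns=["term", "num_df", "den_df", "F", "p"])


def rcbd_equivalence(n_datasets: int = 200, seed: int = 0) -> dict:
    """Mixed-model F/p vs the classical RCBD ANOVA on balanced 4-block 2x2 data."""
    design = generate_design(1, 4, seed=seed)
    X = lmm_mod._factorial_X(design)
    rng = np.random.default_rng(seed)
    max_f = max_p = max_df = 0.0
    for _ in range(n_datasets):
        blocks = design["block"].to_numpy()
        # standardize drawn block effects to SD 3 so block heterogeneity is
        # nondegenerate: the RCBD equivalence is an interior-REML identity and
        # fails (for any software) when var_block is estimated at the boundary
        draw = rng.normal(0, 1.0, 4)
        draw = (draw - draw.mean()) / draw.std(ddof=0) * 3.0
        beff = dict(zip(np.unique(blocks), draw))
        y = (
            np.array([beff[b] for b in blocks])
            + 1.0 * design["nutrient"].to_numpy()
            + 0.5 * design["fence"].to_numpy()
            + 0.25 * (design["nutrient"] * design["fence"]).to_numpy()
            + rng.normal(0, 1.0, len(design))
        )
        fit = lmm_mod.fit_random_intercept_lmm(y, X, blocks)
        got = lmm_mod.lmm_anova(fit).set_index("term")
        want = rcbd_oracle(y, design).set_index("term")
        max_f = max(max_f, float((got["F"] - want["F"]).abs().max()))
        max_p = max(max_p, float((got["p"] - want["p"]).abs().max()))
        max_df = max(max_df, float((got["den_df"] - 9.0).abs().max()))
    return {
        "max_abs_F_diff": max_f,
        "max_abs_p_diff": max_p,
        "max_abs_den_df_minus_9": max_df,
        "n": n_datasets,
    }


# ---------------------------------------------------------------------------
# PERMANOVA exactness and calibration

def _two_group_design(n_per: int = 3) -> tuple[DistanceMatrix, pd.DataFrame]:
    n = 2 * n_per
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if (i < n_per) != (j < n_per):
                d[i, j] = 1.0
    ids = [f"p{i}" for i in range(n)]
    design = pd.DataFrame(
        {
            "plot_id": ids,
            "site": "s",
            "block": "b1",
            "treatment": ["N"] * n_per + ["C"] * n_per,
            "nutrient": [1] * n_per + [0] * n_per,
            "fence": 0,
        }
    )
    return DistanceMatrix(d, ids=ids), design


def permanova_exactness(n_perm: int = 999, seed: int = 0) -> dict:
    """Exact vs sampled permutation p on the 6-plot two-group design.

    With zero within-group and unit between-group distances only the 2 x 3! x 3!
    group-preserving permutations reach the observed pseudo-F, so the exact
    tail probability over the 20 distinct assignments is 2/20 = 0.1.
    """
    dm, design = _two_group_design(3)
    exact = mv_mod.permanova(dm, design, terms=("nutrient",), method="exact")
    sampled = mv_mod.permanova(
        dm, design, terms=("nutrient",), n_perm=n_perm, seed=seed
    )
    return {
        "exact_p": float(exact.loc[0, "p_perm"]),
        "sampled_p": float(sampled.loc[0, "p_perm"]),
        "n_perm": n_perm,
    }


def permanova_type1(
    n_sims: int = 1000, n: int = 16, n_perm: int = 199, seed: int = 0
) -> dict:
    """Empirical type-I error at alpha = 0.05 for a structureless cloud."""
    rng = np.random.default_rng(seed)
    ids = [f"p{i}" for i in range(n)]
    design = pd.DataFrame(
        {
            "plot_id": ids, "site": "s", "block": "b1",
            "treatment": "x",
            "nutrient": [1] * (n // 2) + [0] * (n - n // 2),
            "fence": 0,
        }
    )
    rejections = 0
    pvals = np.empty(n_sims)
    for i in range(n_sims):
        X = pd.DataFrame(rng.random((n, 6)), index=ids)
        dm = mv_mod.bray_curtis(X)
        tab = mv_mod.permanova(
            dm, design, terms=("nutrient",), n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        pvals[i] = tab.loc[0, "p_perm"]
        rejections += pvals[i] <= 0.05
    return {
        "type1_error": rejections / n_sims,
        "mean_p": float(pvals.mean()),
        "n_sims": n_sims,
        "n_perm": n_perm,
    }


# ---------------------------------------------------------------------------
# bootstrap consistency

def bootstrap_consistency(n_seeds: int = 50, seed: int = 0) -> dict:
    """Two species with constant traits 10/2 at relative covers 0.75/0.25:
    the bootstrap CWM must sit within ±0.1 of the analytic 8.0 at defaults."""
    covers = pd.DataFrame(
        {"plot_id": "p1", "species": ["A", "B"], "cover": [75.0, 25.0]}
    )
    traits = pd.DataFrame(
        {
            "plot_id": "p1",
            "species": ["A"] * 5 + ["B"] * 5,
            "replicate": list(range(1, 6)) * 2,
            "trait": "SLA",
            "value": [10.0] * 5 + [2.0] * 5,
        }
    )
    errs = []
    for s in _sub_seeds(seed, n_seeds, "bootcwm"):
        est = cwm_mod.bootstrap_cwm(traits, covers, 100, 200, s)
        errs.append(abs(float(est["value"].iloc[0]) - 8.0))
    return {"max_abs_error": float(max(errs)), "mean_abs_error": float(np.mean(errs)),
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# parameter recovery

def _pipeline_decomposition(params: SimulationParams):
    design = generate_design(params.n_sites, params.n_blocks, params.seed)
    cover, traits, biomass, truth = generate_community(design, params)
    cover_dom = cwm_mod.filter_dominant(cover, params.dominance_threshold)
    spec = cwm_mod.bootstrap_cwm(traits, cover_dom, 100, 200, params.seed + 1)
    refs = cwm_mod.reference_species_means(traits, design)
    fixed = cwm_mod.fixed_cwm(refs, cover_dom, design, 100, 200, params.seed + 1)
    itv = cwm_mod.itv_component(spec, fixed)
    cwm_all = pd.concat([spec, fixed, itv], ignore_index=True)
    decomp = decompose_cwm(cwm_all, design)
    return decomp, truth


def _nutrient_fractions(decomp: pd.DataFrame) -> pd.DataFrame:
    """Per trait, nutrient-term ITV and turnover shares of the specific SS,
    pooled over sites."""
    sub = decomp[decomp["term"] == "nutrient"]
    g = sub.groupby("trait")[["ss_specific", "ss_fixed", "ss_itv"]].sum()
    return pd.DataFrame(
        {
            "rel_itv": g["ss_itv"] / g["ss_specific"],
            "rel_fixed": g["ss_fixed"] / g["ss_specific"],
        }
    )


def recovery_pure_scenarios(n_seeds: int = 20, seed: int = 0) -> dict:
    """Recovery of pure-turnover and pure-ITV ground truth.

    The ITV/turnover contribution is the nutrient-term SS share of the
    specific-CWM SS, a dimensionless fraction pooled over sites and averaged
    across the six traits and over seeds (the scenarios apply the same
    relative effect to every trait, so the fractions are exchangeable).
    Per-trait means are reported alongside the pooled value.
    """
    out = {}
    for label, factory in (
        ("turnover", pure_turnover_params),
        ("itv", pure_itv_params),
    ):
        fracs = []
        for s in _sub_seeds(seed, n_seeds, f"pure-{label}"):
            decomp, _ = _pipeline_decomposition(factory(s))
            fracs.append(_nutrient_fractions(decomp))
        allf = pd.concat(fracs)
        per_trait = allf.groupby(level=0).mean()
        out[f"{label}_scenario_mean_rel_itv"] = float(allf["rel_itv"].mean())
        out[f"{label}_scenario_mean_rel_fixed"] = float(allf["rel_fixed"].mean())
        if label == "turnover":
            out["turnover_scenario_max_trait_rel_itv"] = float(
                per_trait["rel_itv"].max()
            )
        else:
            out["itv_scenario_max_trait_rel_fixed"] = float(
                per_trait["rel_fixed"].max()
            )
    out["n_seeds"] = n_seeds
    return out


def recovery_mixed_grid(seed: int = 0, n_reps: int = 2) -> dict:
    """Noise-reduced 3x3 effect-size grid: per-trait ITV fraction from the
    fitted decomposition vs the noise-free brute-force oracle.

    Each grid cell is averaged over ``n_reps`` replicate communities (both
    the fitted fractions and the oracle), so the comparison measures the
    estimator's systematic agreement rather than single-draw noise.
    """
    devs = []
    seeds = _sub_seeds(seed, 9 * n_reps, "mixed")
    i = 0
    for k in (2.0, 4.0, 6.0):
        for delta in (1.0, 2.0, 3.0):
            fitted = {t: [] for t in TRAITS}
            oracle = {t: [] for t in TRAITS}
            for _ in range(n_reps):
                params = mixed_params(k, delta, seeds[i])
                i += 1
                decomp, truth = _pipeline_decomposition(params)
                for trait in TRAITS:
                    sub = decomp[
                        (decomp["trait"] == trait)
                        & (decomp["term"].isin(
                            ("nutrient", "fence", "nutrient:fence")))
                    ]
                    tf = float(sub["ss_fixed"].sum())
                    ti = float(sub["ss_itv"].sum())
                    fitted[trait].append(ti / (tf + ti))
                    oracle[trait].append(truth.expected_split[trait][1])
            for trait in TRAITS:
                devs.append(
                    abs(float(np.mean(fitted[trait]))
                        - float(np.mean(oracle[trait])))
                )
    return {"max_abs_deviation": float(max(devs)),
            "mean_abs_deviation": float(np.mean(devs)), "n_cells": 9}


# ---------------------------------------------------------------------------
# trait-biomass coefficient recovery

def trait_biomass_recovery(n_seeds: int = 20, seed: int = 0) -> dict:
    """Biomass built as 2 x CWM height + block noise: slope and significance
    recovery, plus the false-positive rate under trait-independent biomass."""
    slopes, sig_seeds = [], 0
    for s in _sub_seeds(seed, n_seeds, "slope"):
        params = SimulationParams(
            seed=s, biomass_coef={"height": 2.0}, biomass_intercept=0.0,
            noise_sd=5.0, biomass_block_sd=10.0,
        )
        design = generate_design(params.n_sites, params.n_blocks, params.seed)
        cover, traits, biomass, _ = generate_community(design, params)
        cover_dom = cwm_mod.filter_dominant(cover, params.dominance_threshold)
        spec = cwm_mod.bootstrap_cwm(traits, cover_dom, 100, 200, s + 1)
        tb = lmm_mod.trait_biomass_models(spec, biomass, design)
        h = tb[(tb["trait"] == "height") & (tb["component"] == "specific")]
        slopes.extend(h["slope"].tolist())
        if bool(h["significant"].all()):
            sig_seeds += 1
    # null: biomass independent of all traits
    nonsig = total = 0
    for s in _sub_seeds(seed, n_seeds, "null"):
        params = SimulationParams(
            seed=s, biomass_coef={}, biomass_intercept=200.0,
            noise_sd=30.0, biomass_block_sd=15.0,
        )
        design = generate_design(params.n_sites, params.n_blocks, params.seed)
        cover, traits, biomass, _ = generate_community(design, params)
        cover_dom = cwm_mod.filter_dominant(cover, params.dominance_threshold)
        spec = cwm_mod.bootstrap_cwm(traits, cover_dom, 100, 200, s + 1)
        tb = lmm_mod.trait_biomass_models(spec, biomass, design)
        nonsig += int((~tb["significant"]).sum())
        total += len(tb)
    return {
        "mean_slope": float(np.mean(slopes)),
        "significant_seed_fraction": sig_seeds / n_seeds,
        "null_nonsignificant_fraction": nonsig / total,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# end-to-end determinism

def pipeline_determinism(seed: int = 0, n_perm: int = 199) -> dict:
    """Run the default pipeline twice with one config; compare bundles byte-wise."""
    with tempfile.TemporaryDirectory() as tmp:
        cfg = PipelineConfig(
            sim=SimulationParams(seed=seed),
            bootstrap_seed=seed + 1,
            perm_seed=seed + 2,
            n_perm=n_perm,
            outdir=str(Path(tmp) / "bundle"),
        )
        snapshots = []
        for _ in range(2):
            bundle = run_pipeline(cfg)
            snapshots.append(
                {p.name: p.read_bytes() for p in bundle.outdir.iterdir()}
            )
        names = sorted(snapshots[0])
        identical = sorted(snapshots[1]) == names and all(
            snapshots[0][n] == snapshots[1][n] for n in names
        )
        n_tables = sum(1 for n in names if n.endswith(".csv"))
    return {
        "bundles_identical": int(identical),
        "n_files_compared": len(names),
        "n_tables": n_tables,
    }
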