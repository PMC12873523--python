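"""Synthetic factorial grassland communities with known turnover/ITV structure.

Emulates a NutNet-style nutrient-addition x herbivore-exclusion experiment:
two grassland sites, four blocks per site, the four factorial treatments
randomly arranged within each block (16 plots per site).  Treatments act on
the community through two dials that can be turned independently:

* ``turnover_effect`` — multiplicative cover change of a designated responsive
  species subset (the dominant, acquisitive species), shifting CWM traits via
  abundance reallocation only;
* ``itv_effect`` — additive within-species trait shifts (in units of the
  within-plot trait SD), shifting CWM traits with no abundance change.

Species trait means are organized along a dominant acquisitive–conservative
axis (leaf-economics style), correlated with abundance rank, so turnover has a
coherent signature across traits.  Block intercepts, within-plot measurement
noise, and a trait-driven biomass model complete the data-generating process.
"""
from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cwm import TRAITS, select_dominant_species
from .decompose import TREATMENT_TERMS, decompose_ss, factorial_anova_ss

logger = logging.getLogger("traitpart")

#: treatment code -> (nutrient flag, fence flag)
TREATMENT_CODES = {"C": (0, 0), "F": (0, 1), "N": (1, 0), "NF": (1, 1)}

TRAIT_UNITS = {
    "SLA": "mm2/mg",
    "LDMC": "mg/g",
    "CN": "dimensionless",
    "height": "cm",
    "leaf_area": "cm2",
    "tannin": "mg/g",
}

#: typical tundra-grassland community means per trait
TRAIT_MEANS = {
    "SLA": 20.0,
    "LDMC": 250.0,
    "CN": 20.0,
    "height": 30.0,
    "leaf_area": 15.0,
    "tannin": 50.0,
}

#: loading of each trait on the acquisitive axis (sign = direction in which
#: fast-growing, dominant species deviate from the community mean)
TRAIT_LOADINGS = {
    "SLA": 1.0,
    "LDMC": -0.8,
    "CN": -0.8,
    "height": 1.0,
    "leaf_area": 0.9,
    "tannin": -0.3,
}


def _frac_of_mean(frac: float) -> dict[str, float]:
    return {t: frac * TRAIT_MEANS[t] for t in TRAITS}


@dataclass
class SimulationParams:
    """Generator settings; defaults emulate the study's design and scale."""

    n_sites: int = 2
    n_blocks: int = 4
    n_species: int = 16
    #: lognormal sigma of species base abundances within a site pool
    base_sigma: float = 1.2
    #: lognormal sigma of plot-to-plot cover jitter around the base abundance
    plot_sigma: float = 0.35
    #: expected summed percent cover per plot
    total_cover: float = 85.0
    #: between-species trait spread along the acquisitive axis (CV units)
    trait_spread: float = 0.22
    trait_loadings: dict[str, float] = field(default_factory=lambda: dict(TRAIT_LOADINGS))
    #: optional explicit site x species x trait means (columns: site, species,
    #: trait, mean); overrides the axis construction when given
    species_trait_means: pd.DataFrame | None = None
    #: within-plot individual SD per trait (trait units)
    trait_sd_within: dict[str, float] = field(default_factory=lambda: _frac_of_mean(0.10))
    #: per-treatment cover multiplier on the responsive species subset
    turnover_effect: dict[str, float] = field(
        default_factory=lambda: {"nutrient": 4.0, "fence": 2.0}
    )
    #: fraction of the species pool (most abundant first) that responds
    responsive_fraction: float = 0.25
    #: per-treatment, per-trait within-species shift in trait_sd_within units
    itv_effect: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "nutrient": {"SLA": 1.5, "LDMC": -1.2, "CN": -1.2,
                         "height": 2.0, "leaf_area": 1.5, "tannin": -0.5},
            "fence": {"SLA": 0.8, "height": 1.5, "leaf_area": 1.2},
        }
    )
    #: SD of block-level trait intercepts (trait units)
    block_sd: dict[str, float] = field(default_factory=lambda: _frac_of_mean(0.05))
    #: linear map from latent plot CWM traits to expected biomass (g/m2)
    biomass_coef: dict[str, float] = field(
        default_factory=lambda: {"height": 5.0, "SLA": 2.0}
    )
    biomass_intercept: float = 60.0
    biomass_block_sd: float = 15.0
    #: residual biomass SD (g/m2)
    noise_sd: float = 20.0
    n_individuals: int = 5
    dominance_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name in ("base_sigma", "plot_sigma", "trait_spread",
                     "biomass_block_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.trait_sd_within.values()):
            raise ValueError("trait_sd_within entries must be >= 0")
        if any(v < 0 for v in self.block_sd.values()):
            raise ValueError("block_sd entries must be >= 0")
        if any(v < 0 for v in self.turnover_effect.values()):
            raise ValueError("turnover_effect multipliers must be >= 0")


@dataclass
class SyntheticTruth:
    """Latent states behind one simulated data set, for oracle use."""

    params: SimulationParams
    #: plot x species realized percent covers (post-treatment, pre-observation)
    realized_covers: pd.DataFrame
    #: plot x species x trait latent means including block + ITV effects
    realized_species_plot_means: pd.DataFrame
    #: same but without the ITV treatment shifts (species mean + block only)
    realized_reference_means: pd.DataFrame
    #: per trait, generator-implied (turnover, itv) share of treatment signal
    expected_split: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_truncated: int = 0


def _site_names(n_sites: int) -> list[str]:
    if n_sites <= 2:
        return ["low", "high"][:n_sites]
    return [f"site{i + 1}" for i in range(n_sites)]


def generate_design(n_sites: int, n_blocks: int, seed: int = 0) -> pd.DataFrame:
    """Balanced factorial block layout: every block holds the four treatment
    combinations once, in randomized order.  Deterministic given ``seed``."""
    if n_sites < 1 or n_blocks < 2:
        raise ValueError("need n_sites >= 1 and n_blocks >= 2")
    rng = np.random.default_rng(seed)
    codes = list(TREATMENT_CODES)
    rows = []
    for site in _site_names(n_sites):
        for b in range(1, n_blocks + 1):
            for idx in rng.permutation(4):
                code = codes[idx]
                nut, fen = TREATMENT_CODES[code]
                rows.append((f"{site}-b{b}-{code}", site, f"b{b}", code, nut, fen))
    return pd.DataFrame(
        rows, columns=["plot_id", "site", "block", "treatment", "nutrient", "fence"]
    )


def _rng_for(seed: int, *keys) -> np.random.Generator:
    ent = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(ent)


def _species_pool(site: str, params: SimulationParams):
    """Base abundances, trait means and responsive subset for one site."""
    rng = _rng_for(params.seed, "pool", site)
    raw = rng.lognormal(0.0, params.base_sigma, params.n_species)
    base = raw / raw.sum() * params.total_cover
    species = np.array([f"{site}_sp{i + 1:02d}" for i in range(params.n_species)])
    ranks = base.argsort().argsort()  # 0 = rarest
    if len(ranks) > 1:
        u = (ranks - ranks.mean()) / ranks.std()  # acquisitive score, dominants high
    else:
        u = np.zeros(1)
    means = pd.DataFrame(index=species, columns=list(TRAITS), dtype=float)
    if params.species_trait_means is not None:
        stm = params.species_trait_means
        sub = stm[stm["site"] == site]
        means = sub.pivot(index="species", columns="trait", values="mean")
        species = means.index.to_numpy()
        base = base[: len(species)]
        u = u[: len(species)]
    else:
        for t in TRAITS:
            jitter = 1.0 + 0.05 * rng.standard_normal(params.n_species)
            vals = TRAIT_MEANS[t] * (
                1.0 + params.trait_loadings.get(t, 0.0) * params.trait_spread * u
            ) * jitter
            means[t] = np.clip(vals, 0.2 * TRAIT_MEANS[t], None)
    n_resp = max(1, int(np.ceil(params.responsive_fraction * len(species))))
    responsive = set(species[np.argsort(-base)[:n_resp]])
    return species, base, means, responsive


def generate_community(
    design: pd.DataFrame, params: SimulationParams
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate covers, individual trait measurements and biomass for a design.

    Covers: lognormal around species base abundance, multiplied by the
    treatment multipliers on the responsive subset; not renormalized (visual
    cover estimates need not sum to 100).  Traits: latent plot-level species
    mean = species mean + block intercept + ITV shifts, observed with
    within-plot noise on the >threshold dominant species of each plot.
    Biomass: linear in the latent all-species CWM traits plus block and
    residual noise.  Fully reproducible from ``params.seed``.
    """
    p = params
    cover_rows, trait_rows, biomass_rows = [], [], []
    latent_rows, ref_rows = [], []
    n_trunc = 0
    floor = {t: 1e-6 * TRAIT_MEANS[t] for t in TRAITS}

    for site in sorted(design["site"].unique()):
        dsite = design[design["site"] == site]
        species, base, means, responsive = _species_pool(site, p)
        if means.isna().any().any():
            raise ValueError(f"species trait means incomplete for site {site}")
        brng = _rng_for(p.seed, "blocks", site)
        blocks = sorted(dsite["block"].unique())
        block_int = {
            b: {t: brng.normal(0.0, p.block_sd.get(t, 0.0)) for t in TRAITS}
            for b in blocks
        }
        bio_block = {b: brng.normal(0.0, p.biomass_block_sd) for b in blocks}

        for row in dsite.sort_values("plot_id").itertuples(index=False):
            rng = _rng_for(p.seed, "plot", row.plot_id)
            z = rng.standard_normal(len(species))
            cov = base * np.exp(p.plot_sigma * z - 0.5 * p.plot_sigma**2)
            mult_n = p.turnover_effect.get("nutrient", 1.0) if row.nutrient else 1.0
            mult_f = p.turnover_effect.get("fence", 1.0) if row.fence else 1.0
            resp_mask = np.array([s in responsive for s in species])
            cov = np.where(resp_mask, cov * mult_n * mult_f, cov)
            cov = np.clip(cov, 0.0, None)

            shifts = {t: 0.0 for t in TRAITS}
            for eff, flag in (("nutrient", row.nutrient), ("fence", row.fence)):
                if flag:
                    for t, d in p.itv_effect.get(eff, {}).items():
                        shifts[t] += d * p.trait_sd_within.get(t, 0.0)

            plot_means = {}
            for t in TRAITS:
                m = means[t].to_numpy() + block_int[row.block][t] + shifts[t]
                ref = means[t].to_numpy() + block_int[row.block][t]
                low = m < floor[t]
                n_trunc += int(low.sum())
                plot_means[t] = np.where(low, floor[t], m)
                for s, mv, rv in zip(species, plot_means[t], np.maximum(ref, floor[t])):
                    latent_rows.append((row.plot_id, s, t, mv))
                    ref_rows.append((row.plot_id, s, t, rv))

            for s, c in zip(species, cov):
                cover_rows.append((row.plot_id, s, float(c)))

            dominant = select_dominant_species(
                dict(zip(species, cov)), p.dominance_threshold
            )
            sp_index = {s: i for i, s in enumerate(species)}
            for s in sorted(dominant):
                i = sp_index[s]
                for t in TRAITS:
                    sd = p.trait_sd_within.get(t, 0.0)
                    vals = plot_means[t][i] + sd * rng.standard_normal(p.n_individuals)
                    low = vals < floor[t]
                    n_trunc += int(low.sum())
                    vals = np.where(low, floor[t], vals)
                    for rep, v in enumerate(vals, start=1):
                        trait_rows.append((row.plot_id, s, rep, t, float(v)))

            # biomass responds to the dominant-community trait state (the
            # same estimand the measured CWMs target)
            dom_idx = np.array([sp_index[s] for s in dominant])
            dom_cov = cov[dom_idx]
            relcov = dom_cov / dom_cov.sum()
            cwm_true = {t: float(relcov @ plot_means[t][dom_idx]) for t in TRAITS}
            mu = p.biomass_intercept + sum(
                c * cwm_true[t] for t, c in p.biomass_coef.items()
            )
            bio = mu + bio_block[row.block] + rng.normal(0.0, p.noise_sd)
            biomass_rows.append((row.plot_id, float(max(bio, 1e-6))))

    cover = pd.DataFrame(cover_rows, columns=["plot_id", "species", "cover"])
    traits = pd.DataFrame(
        trait_rows, columns=["plot_id", "species", "replicate", "trait", "value"]
    )
    biomass = pd.DataFrame(biomass_rows, columns=["plot_id", "total_biomass"])
    truth = SyntheticTruth(
        params=p,
        realized_covers=cover.copy(),
        realized_species_plot_means=pd.DataFrame(
            latent_rows, columns=["plot_id", "species", "trait", "mean"]
        ),
        realized_reference_means=pd.DataFrame(
            ref_rows, columns=["plot_id", "species", "trait", "mean"]
        ),
        n_truncated=n_trunc,
    )
    if n_trunc:
        logger.warning("%d simulated values truncated at the positive floor", n_trunc)
    truth.expected_split = {
        t: ground_truth_partition(truth, t, design) for t in TRAITS
    }
    return cover, traits, biomass, truth


def _truth_cwm(truth: SyntheticTruth, trait: str, means: pd.DataFrame) -> pd.Series:
    # restrict to the measured (dominant) community: the estimand is the CWM
    # of the species covered by the >threshold sampling rule, noise-free
    from .cwm import filter_dominant

    covers = filter_dominant(
        truth.realized_covers, truth.params.dominance_threshold
    )
    cov = covers.pivot(index="plot_id", columns="species", values="cover")
    m = means[means["trait"] == trait].pivot(
        index="plot_id", columns="species", values="mean"
    )
    m = m.reindex(index=cov.index, columns=cov.columns)
    w = cov.div(cov.sum(axis=1), axis=0)
    return (w * m).sum(axis=1)


def ground_truth_partition(
    truth: SyntheticTruth, trait: str, design: pd.DataFrame | None = None
) -> tuple[float, float]:
    """Noise-free brute-force (turnover, itv) split for one trait.

    Rebuilds per-plot CWMs from realized covers times (a) the latent plot-level
    species means and (b) the block-matched reference means without ITV shifts,
    then runs the same per-site factorial ANOVA decomposition on these
    noise-free responses and pools the treatment-term SS.
    """
    if trait not in TRAITS:
        raise KeyError(f"unknown trait {trait!r}")
    if design is None:
        design = generate_design(
            truth.params.n_sites, truth.params.n_blocks, truth.params.seed
        )
    spec = _truth_cwm(truth, trait, truth.realized_species_plot_means)
    fixed = _truth_cwm(truth, trait, truth.realized_reference_means)
    itv = spec - fixed
    tf = ti = 0.0
    for _, dsite in design.groupby("site"):
        d = decompose_ss(
            factorial_anova_ss(spec, dsite),
            factorial_anova_ss(fixed, dsite),
            factorial_anova_ss(itv, dsite),
        )
        sub = d[d["term"].isin(TREATMENT_TERMS)]
        tf += float(sub["ss_fixed"].sum())
        ti += float(sub["ss_itv"].sum())
    tot = tf + ti
    if tot <= 0:
        return (float("nan"), float("nan"))
    return (tf / tot, ti / tot)


# --- scenario factories -----------------------------------------------------

def _strong_loadings() -> dict[str, float]:
    # scenario communities have a maximal trait syndrome: every trait loads
    # fully on the acquisitive axis, so the designated turnover response
    # carries an identifiable signal in each trait
    return {"SLA": 1.0, "LDMC": -1.0, "CN": -1.0,
            "height": 1.0, "leaf_area": 1.0, "tannin": -1.0}


def pure_turnover_params(seed: int = 0) -> SimulationParams:
    """Treatments act only through abundance shifts of the responsive species.

    The community is kept relatively even (low lognormal sigma) so the >80%
    sampling rule retains most of the pool in every plot: under strongly
    skewed covers the dominance cut both truncates the turnover signal and
    concentrates the measurement noise on one or two species, making the
    generator-implied split unidentifiable from the measured community.
    """
    return SimulationParams(
        seed=seed,
        base_sigma=0.6,
        trait_spread=0.30,
        trait_loadings=_strong_loadings(),
        turnover_effect={"nutrient": 6.0, "fence": 3.0},
        itv_effect={},
    )


def pure_itv_params(seed: int = 0, delta: float = 3.0) -> SimulationParams:
    """Treatments act only through within-species trait shifts."""
    shifts = {t: delta * np.sign(TRAIT_LOADINGS[t]) for t in TRAITS}
    half = {t: 0.5 * v for t, v in shifts.items()}
    return SimulationParams(
        seed=seed,
        base_sigma=0.6,
        trait_spread=0.30,
        trait_loadings=_strong_loadings(),
        turnover_effect={},
        itv_effect={"nutrient": shifts, "fence": half},
    )


def mixed_params(
    turnover_k: float, itv_delta: float, seed: int = 0
) -> SimulationParams:
    """Both dials on, with reduced observation noise for oracle comparison."""
    shifts = {t: itv_delta * np.sign(TRAIT_LOADINGS[t]) for t in TRAITS}
    return SimulationParams(
        seed=seed,
        trait_loadings=_strong_loadings(),
        turnover_effect={"nutrient": turnover_k},
        itv_effect={"nutrient": shifts},
        trait_sd_within=_frac_of_mean(0.02),
        block_sd=_frac_of_mean(0.02),
        plot_sigma=0.10,
        n_individuals=10,
    )


def params_to_dict(p: SimulationParams) -> dict:
    d = dataclasses.asdict(p)
    if p.species_trait_means is not None:
        d["species_trait_means"] = p.species_trait_means.to_dict("records")
    return d


def params_from_dict(d: dict) -> SimulationParams:
    d = dict(d)
    stm = d.get("species_trait_means")
    if stm is not None and not isinstance(stm, pd.DataFrame):
        d["species_trait_means"] = pd.DataFrame(stm)
    return SimulationParams(**d)
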