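"""End-to-end run: simulate-or-load -> CWM bootstrap -> decomposition ->
PERMANOVA -> treatment tests -> trait-biomass models -> report bundle."""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cwm as cwm_mod
from . import decompose as dec_mod
from . import io as io_mod
from . import lmm as lmm_mod
from . import multivariate as mv_mod
from . import simulate as sim_mod

logger = logging.getLogger("traitpart")


@dataclass
class PipelineConfig:
    simulate: bool = True
    sim: sim_mod.SimulationParams = field(default_factory=sim_mod.SimulationParams)
    design_path: str | None = None
    cover_path: str | None = None
    traits_path: str | None = None
    biomass_path: str | None = None
    n_resamples: int = 100
    sample_size: int = 200
    bootstrap_seed: int = 1
    dominance_threshold: float = 0.8
    standardization: str = "range01"
    n_perm: int = 999
    perm_seed: int = 1
    restrict_blocks: bool = False
    log_transform: dict[str, bool] = field(default_factory=dict)
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        for name in ("n_resamples", "sample_size", "n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0 < self.dominance_threshold < 1:
            raise ValueError("dominance_threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = sim_mod.params_to_dict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and not isinstance(d["sim"], sim_mod.SimulationParams):
            d["sim"] = sim_mod.params_from_dict(d["sim"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where results land does not affect them
        return io_mod.config_hash(d)


@dataclass
class ReportBundle:
    outdir: Path
    tables: dict[str, Path]
    metadata: dict


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _load_or_simulate(config: PipelineConfig):
    if config.simulate:
        design = sim_mod.generate_design(
            config.sim.n_sites, config.sim.n_blocks, config.sim.seed
        )
        cover, traits, biomass, truth = sim_mod.generate_community(design, config.sim)
        return design, cover, traits, biomass, truth
    paths = {
        "design": config.design_path,
        "cover": config.cover_path,
        "traits": config.traits_path,
        "biomass": config.biomass_path,
    }
    missing = [k for k, v in paths.items() if v is None or not Path(v).exists()]
    if missing:
        raise FileNotFoundError(f"input tables missing: {missing}")
    tabs = {k: io_mod.read_table(Path(v)) for k, v in paths.items()}
    return tabs["design"], tabs["cover"], tabs["traits"], tabs["biomass"], None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages; idempotent and byte-reproducible given the config."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash
    collector = _WarningCollector()
    logger.addHandler(collector)
    written: list[Path] = []
    stage = "load"
    try:
        design, cover, traits, biomass, truth = _load_or_simulate(config)
        stage = "validate"
        errors = io_mod.validate_inputs(design, cover, traits, biomass)
        if errors:
            raise ValueError("input validation failed:\n" + "\n".join(errors))

        stage = "cwm"
        cover_dom = cwm_mod.filter_dominant(cover, config.dominance_threshold)
        specific = cwm_mod.bootstrap_cwm(
            traits, cover_dom, config.n_resamples, config.sample_size,
            config.bootstrap_seed,
        )
        refs = cwm_mod.reference_species_means(traits, design)
        fixed = cwm_mod.fixed_cwm(
            refs, cover_dom, design, config.n_resamples, config.sample_size,
            config.bootstrap_seed,
        )
        itv = cwm_mod.itv_component(specific, fixed)
        cwm_all = pd.concat([specific, fixed, itv], ignore_index=True)
        cwm_all = cwm_all.sort_values(["plot_id", "trait", "component"]).reset_index(
            drop=True
        )

        stage = "decomposition"
        decomp = dec_mod.decompose_cwm(cwm_all, design)

        stage = "permanova"
        perm_tabs = []
        for site, dsite in design.groupby("site", sort=True):
            wide = cwm_mod.cwm_wide(
                cwm_all[cwm_all["plot_id"].isin(set(dsite["plot_id"]))], "specific"
            ).dropna(axis=1)
            std = mv_mod.standardize_traits(wide, config.standardization)
            dm = mv_mod.bray_curtis(std)
            tab = mv_mod.permanova(
                dm, dsite, n_perm=config.n_perm, seed=config.perm_seed,
                restrict_blocks=config.restrict_blocks,
            )
            tab.insert(0, "site", site)
            perm_tabs.append(tab)
        perm = pd.concat(perm_tabs, ignore_index=True)

        stage = "treatment_tests"
        tests = lmm_mod.treatment_effect_suite(
            cwm_all, biomass, design, config.log_transform
        )

        stage = "trait_biomass"
        tb = lmm_mod.trait_biomass_models(cwm_all, biomass, design)

        stage = "write"
        tables = {}
        for name, df in (
            ("design", design), ("cover", cover), ("traits", traits),
            ("biomass", biomass), ("cwm", cwm_all), ("decomposition", decomp),
            ("permanova", perm), ("treatment_tests", tests),
            ("trait_biomass", tb), ("reference_means", refs),
        ):
            path = outdir / f"{name}.csv"
            io_mod.write_table(df.round(10), path, chash)
            written.append(path)
            tables[name] = path
        cfg_echo = config.to_dict()
        cfg_echo.pop("outdir", None)
        metadata = {
            "config": cfg_echo,
            "config_hash": chash,
            "seeds": {
                "simulation": config.sim.seed if config.simulate else None,
                "bootstrap": config.bootstrap_seed,
                "permutation": config.perm_seed,
            },
            "standardization": config.standardization,
            "warnings": collector.messages,
            "n_plots": int(len(design)),
        }
        if truth is not None:
            metadata["expected_split"] = {
                t: list(v) for t, v in truth.expected_split.items()
            }
            metadata["n_truncated"] = truth.n_truncated
        meta_path = outdir / "run_metadata.json"
        with open(meta_path, "w") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        written.append(meta_path)
        tables["run_metadata"] = meta_path
        return ReportBundle(outdir=outdir, tables=tables, metadata=metadata)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        logger.removeHandler(collector)
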