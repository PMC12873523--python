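"""Tabular I/O, schema validation and config hashing for the pipeline."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

SCHEMAS = {
    "design": ["plot_id", "site", "block", "treatment", "nutrient", "fence"],
    "cover": ["plot_id", "species", "cover"],
    "traits": ["plot_id", "species", "replicate", "trait", "value"],
    "biomass": ["plot_id", "total_biomass"],
}


def validate_inputs(
    design: pd.DataFrame,
    cover: pd.DataFrame,
    traits: pd.DataFrame,
    biomass: pd.DataFrame,
) -> list[str]:
    """Return the full list of schema / referential-integrity violations."""
    errors: list[str] = []
    tables = {"design": design, "cover": cover, "traits": traits, "biomass": biomass}
    for name, tab in tables.items():
        missing = [c for c in SCHEMAS[name] if c not in tab.columns]
        if missing:
            errors.append(f"{name}: missing columns {missing}")
        unknown = [c for c in tab.columns if c not in SCHEMAS[name]]
        if unknown:
            errors.append(f"{name}: unknown columns {unknown}")
    if errors:
        return errors
    dup = design["plot_id"][design["plot_id"].duplicated()]
    if len(dup):
        errors.append(f"design: duplicate plot_ids {sorted(set(dup))}")
    for name, keys in (("cover", ["plot_id", "species"]),
                       ("traits", ["plot_id", "species", "replicate", "trait"]),
                       ("biomass", ["plot_id"])):
        tab = tables[name]
        d = tab[tab.duplicated(subset=keys)]
        if len(d):
            errors.append(f"{name}: {len(d)} duplicate rows on key {keys}")
    plots = set(design["plot_id"])
    for name in ("cover", "traits", "biomass"):
        orphans = sorted(set(tables[name]["plot_id"]) - plots)
        if orphans:
            errors.append(f"{name}: plots not in design: {orphans}")
    if (cover["cover"] < 0).any():
        bad = cover[cover["cover"] < 0]
        errors.append(f"cover: negative cover for {len(bad)} rows, "
                      f"first at plot {bad.iloc[0]['plot_id']!r}")
    nonpos = traits[traits["value"] <= 0]
    for r in nonpos.head(10).itertuples(index=False):
        errors.append(
            f"traits: nonpositive value {r.value} (plot {r.plot_id!r}, "
            f"species {r.species!r}, trait {r.trait!r}, replicate {r.replicate})"
        )
    if (biomass["total_biomass"] <= 0).any():
        bad = biomass[biomass["total_biomass"] <= 0]
        errors.append(f"biomass: nonpositive biomass for plots "
                      f"{sorted(bad['plot_id'])}")
    if not set(design["nutrient"]).issubset({0, 1}) or not set(
        design["fence"]
    ).issubset({0, 1}):
        errors.append("design: nutrient/fence flags must be 0/1")
    return errors


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path, chash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=False)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
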