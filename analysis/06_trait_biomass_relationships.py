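#!/usr/bin/env python
"""Trait-biomass relationships across treatments.

Regresses total aboveground biomass on each trait's CWM component (one
predictor per model, block random intercept) per site, reporting slope,
Satterthwaite p and marginal/conditional variance explained; only P < 0.05
relationships are flagged for display.
"""
from pathlib import Path

import traitpart as tp
from traitpart.io import config_hash, read_table, write_table

OUT = Path("results/analysis")


def main() -> None:
    design = read_table(OUT / "design.csv")
    cwm = read_table(OUT / "cwm.csv")
    biomass = read_table(OUT / "biomass.csv")
    tb = tp.trait_biomass_models(cwm, biomass, design)
    write_table(tb, OUT / "trait_biomass.csv",
                config_hash({"stage": "trait_biomass"}))
    sig = tb[tb["significant"]]
    print(f"{len(tb)} models; {len(sig)} significant at 0.05")
    for r in sig[sig["component"] == "specific"].itertuples(False):
        print(f"  {r.site:5s} biomass ~ CWM {r.trait:10s} "
              f"slope {r.slope:8.2f}  R2m {r.r2_marginal:.2f} "
              f"R2c {r.r2_conditional:.2f}  p {r.p:.2g}")


if __name__ == "__main__":
    main()
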