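# traitpart

Turnover vs intraspecific trait variation in factorial grassland experiments.

## The problem

When grassland communities respond to nutrient addition or release from
herbivory, community-level trait averages can shift for two distinct reasons:
the species composition changes (**turnover**) or the species themselves
change (**intraspecific trait variation, ITV**). Distinguishing the two is
central to trait-based community ecology, because they imply different
mechanisms (species sorting vs plasticity/within-species selection).

`traitpart` implements the full analysis chain for a NutNet-style factorial
nutrient x herbivore-exclusion experiment (2 sites x 4 blocks x 4 treatments,
percent-cover quadrats, individual trait measurements on the species making
up >80% of relative cover, plot biomass), plus a synthetic community
generator with known ground truth so every stage is testable without any
field data.

## The statistics

For each plot, the **community-weighted mean** of trait *t* is estimated by a
nonparametric bootstrap: draw 200 individuals per resample, species chosen
with probability equal to relative cover, individuals uniformly within
species; the CWM is the mean over 100 resample means.

- CWM<sub>specific</sub> — bootstrap over the plot's own measured individuals
  (turnover + ITV together);
- CWM<sub>fixed</sub> — the same bootstrap with each species frozen at its
  reference mean from control plots (turnover only);
- ITV = CWM<sub>specific</sub> − CWM<sub>fixed</sub>.

Separate factorial ANOVAs (nutrient, fence, interaction) on the three
responses give, per design term,

SS<sub>specific</sub> = SS<sub>fixed</sub> + SS<sub>ITV</sub> + SS<sub>cov</sub>,

where a positive covariation term means turnover and within-species shifts
reinforce each other and a negative one means they oppose. Inference uses
random-intercept (block) mixed models fitted by profiled REML with
Satterthwaite denominator degrees of freedom (exactly the classical RCBD
ANOVA on balanced layouts), multi-trait composition uses Bray–Curtis
PERMANOVA with sequential sums of squares and 999 permutations, and
trait–biomass relationships are single-predictor mixed models with
marginal/conditional R².

## Worked example

Run the numbered drivers in order (or `traitpart run` / `run_pipeline` for a
single end-to-end call):

```sh
python analysis/01_simulate_communities.py
python analysis/02_bootstrap_cwm.py
python analysis/03_turnover_itv_decomposition.py
```

The generator's default scenario lets treatments act mostly through
within-species shifts; step 01 prints the generator-implied split, e.g.

```
  SLA        turnover  0.06  itv  0.94
  height     turnover  0.02  itv  0.98
```

and step 03 shows the fitted decomposition recovering it from the noisy
bootstrap tables:

```
treatment-term ITV fraction (fitted vs generator truth):
  SLA        fitted  0.92   truth  0.94
  height     fitted  0.98   truth  0.98
  leaf_area  fitted  0.95   truth  0.95
```

Steps 04–06 add the PERMANOVA (e.g. `low nutrient R2 0.60 pseudo-F 31.6
p 0.001`), the per-response factorial F-tests, and the trait–biomass table
(e.g. `low biomass ~ CWM height slope 6.28 R2m 0.73 p 2.8e-05`). All outputs
are CSV files under `results/analysis/`, each stamped with the config hash;
rerunning an identical configuration reproduces the files byte for byte.

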