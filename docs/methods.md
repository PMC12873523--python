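# Methods

## Bootstrapped community-weighted means

The CWM estimator resamples individual trait measurements with species
weights proportional to relative percent cover within the plot, restricted to
species that have trait data for the trait in question (weights renormalized;
species without data are dropped rather than imputed, matching a
selected-species measurement design). Defaults: 100 resamples of 200
individuals; the reported value is the mean over resample means and
`bootstrap_se` their SD. 100 resamples is the conventional choice for this
estimator; the per-resample draw count of 200 follows the source bootstrap
tool's convention and is exposed in the config. With both defaults the Monte
Carlo SE of a CWM is roughly the within-plot mixture SD divided by 140, i.e.
negligible next to ecological variation.

The fixed-reference CWM uses the same resampling code path with each
species' trait distribution collapsed to a single reference value, so the two
estimators are exactly exchangeable under a shared seed (a tested
invariant). Reference means are computed within site — never pooled across
sites, whose pools and productivity differ — as the species mean over
control plots; a species absent from control plots falls back to
unfertilized ("ambient") plots, then to all plots of the site, with the
provenance recorded per row. "Ambient" is read as *unfertilized-first*
because nutrient addition is the treatment that shifts traits most strongly;
this is an interpretation, flagged as such.

Dominant-species selection takes the minimal prefix of species (descending
cover, ties by identifier) whose cumulative relative cover strictly exceeds
the threshold (default 0.8), so an exact 80% share does not stop the scan.

## Sum-of-squares decomposition

Per site and trait, three sequential factorial ANOVAs (nutrient, fence,
interaction; no block term — the decomposition is kept distinct from the
inferential mixed models) are run on the specific CWM, fixed CWM and ITV
component. Per term, `ss_cov = ss_specific − ss_fixed − ss_itv`; negative
covariation is reported as-is. Relative contributions are normalized by the
specific-CWM **total** SS so that sources and terms are comparable across
panels. Sequential SS are computed by QR projection; under a balanced design
the effect-coded columns are orthogonal and the SS are order-invariant
(tested), and the implementation is cross-checked against statsmodels'
type-I ANOVA.

## Mixed models

Every inferential model is Gaussian with a single random intercept per
block, fitted by REML profiled down to the variance ratio
rho = var_block/var_resid. The 1-D criterion is minimized by bounded search
and then polished to machine precision on the analytic stationarity
condition; the boundary rho = 0 is permitted and reproduces OLS. Wald
F-tests per fixed term use Satterthwaite denominator degrees of freedom
computed from the exact REML information matrix in (var_block, var_resid);
on a balanced b-block 2x2 layout this collapses to the classical two-stratum
RCBD ANOVA with den_df = (b−1)(t−1) = 9, an identity verified to 1e-6 over
simulated datasets. The identity presumes an interior REML solution: when
the between-block mean square falls below the residual mean square the
variance estimate hits zero and the mixed model legitimately reverts to OLS
(the same happens in lmerTest); the equivalence experiment therefore
standardizes its simulated block effects to their nominal SD so every
dataset is interior.

Marginal R² is var(fixed fitted values) over the sum of that, the block
variance and the residual variance; conditional R² adds the block variance
to the numerator. "Log-transform when necessary" is a per-response config
flag plus a skewness advisory (|skew| > 1 on residuals); transforms are never
applied silently, and the flag is ignored with a warning for responses with
nonpositive values (the ITV component can be negative).

## PERMANOVA

The six CWM traits are incommensurable, so the plot x trait matrix is
standardized before Bray–Curtis — default `range01` (per-trait min-max), with
`zscore_shift` as the alternative; the choice is config-exposed and echoed in
the run metadata. The distance matrix is Gower-centered and partitioned by
sequential orthonormal term projectors (adonis2-style order-entered SS);
pseudo-F uses the residual mean square, and p-values count permutations with
F* ≥ F under free row permutation, `(1+k)/(1+n_perm)`, with an exact
enumeration mode for n ≤ 8 and an optional within-block restricted mode.
Perfect separation (zero residual) yields an infinite pseudo-F that only
group-preserving permutations can match. Type-I error at alpha = 0.05 is
calibrated to [0.03, 0.07] over 1000 null simulations.

## Synthetic communities

The generator emulates the experiment's structure: per site a 16-species
pool with lognormal base abundances (sigma 1.2, expected total cover 85%),
per-plot lognormal cover jitter (sigma 0.35), species trait means organized
on an acquisitive–conservative axis correlated with abundance rank (spread
CV 0.22; SLA, height, leaf area load positively; LDMC, C:N, tannin
negatively), block intercepts (SD 5% of the trait mean), and five measured
individuals per species per plot with within-species SD 10% of the trait
mean. Trait units: SLA mm²/mg, LDMC mg/g, C:N dimensionless, height cm,
leaf area cm², tannin mg/g. Treatments act through two independent dials:
multiplicative cover changes on the most-abundant quartile of species
(turnover) and additive within-species shifts in units of the within-plot SD
(ITV). Covers are not renormalized (visual estimates need not sum to 100);
negative simulated values are floored at 1e-6 of the trait mean and counted.
Biomass is linear in the dominant-community latent CWM traits plus block and
residual noise — the dominant-community state is used because that is the
estimand the measured CWMs target. One global seed drives stable per-plot
substreams.

The generator does **not** emulate spatial structure, multi-year dynamics,
species' differential within-species responses, trait–abundance feedbacks,
or observer error in cover estimation; passing tests therefore demonstrate
estimator correctness under the stated data-generating process, not
robustness to those features of real field data.

### Ground-truth partition

The oracle rebuilds noise-free CWMs from realized covers times (a) the
latent plot-level species means and (b) block-matched reference means
without ITV shifts, runs the same ANOVA decomposition, and pools the
treatment-term SS into a (turnover, ITV) pair. Both oracle CWMs are
restricted to the >80% dominant community — the estimand the measurement
protocol defines. This matters: under strong cover shifts the dominance rule
both truncates turnover signal carried by subordinate species and
concentrates measurement noise on few species, so an all-species oracle and
the measured-community estimate would disagree for reasons no estimator can
remove.

### Recovery scenarios

The pure-turnover and pure-ITV scenarios use a more even pool (lognormal
sigma 0.6), a full-strength trait syndrome (|loading| = 1 on all six traits)
and spread CV 0.30, so every trait carries identifiable signal under the
dominance rule; contribution bounds are asserted on the across-trait,
across-seed mean of the dimensionless SS fractions, because a single 1-df SS
is chi-square distributed and no per-draw bound is meaningful. The mixed
3x3 grid (cover multipliers 2/4/6 x ITV shifts 1/2/3 SD) is run in a
noise-reduced regime (within-species CV 0.02, cover jitter 0.10, 10
individuals) with each cell averaged over two replicate communities, so the
±0.10 oracle comparison measures systematic agreement. The trait–biomass
scenario builds biomass as 2 x CWM height + block noise (residual SD 5 g/m²)
and checks the across-seed mean slope; the null scenario draws biomass
independent of all traits.

## Numerical choices and degenerate inputs

- Residual SS in ANOVA/PERMANOVA are clamped at zero against floating-point
  cancellation; identity checks use 1e-10 relative tolerance.
- Plots with no trait-covered species yield missing CWMs with a logged
  warning, never an exception; downstream stages skip incomplete responses
  and log the reason.
- Zero-range traits are dropped before standardization; single-plot or
  single-group inputs are rejected with explicit errors; rank-deficient
  fixed-effect matrices name the aliased columns.
- All randomness flows from explicit seeds through stable per-plot/per-cell
  substreams (CRC-keyed SeedSequences), making every table byte-reproducible
  under an identical config; the config hash is stamped in every output file.

## Known limitations

Satterthwaite df are exact only under balance; unbalanced designs get a
sequential-SS warning and approximate df. The PERMANOVA free-permutation
default ignores blocks (the restricted mode is available but not default).
The ITV component inherits both bootstrap Monte Carlo error and
reference-mean estimation error; with five individuals per species its noise
floor is visible in the decomposition whenever treatment signals are weak.
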