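# Methods

## Scope and data model

The package post-processes sequentially-Markovian-coalescent (SMC) output:
piecewise-constant scaled coalescence rates λ on contiguous scaled-time
segments, one table per (species, population, replicate), where replicates
are one "main" run plus bootstrap re-estimates. Scaled quantities convert
to real units as

    t_years = t_scaled / μ · g        Ne = 1 / (2 μ λ)

with μ the per-generation per-site mutation rate (default 4×10⁻⁸) and g
the generation time in years (default 5). All times are years before
present, present = 0, matching the orientation of the sea-level series.
Parsing takes column order from the header, tolerates `inf` or blank final
right boundaries, and reports format violations by row.

## Harmonization

Each segment contributes its boundary midpoint; segments with an infinite
right boundary have no midpoint and are dropped. The common grid has
exactly 100 logarithmically spaced points from 1 year to the maximum
reconstructed time rounded half-up to the nearest million years (floor one
million, so the grid always spans the last glacial cycles). Interpolation
is linear in raw time and raw Ne — a log-time variant exists for
sensitivity analysis but is not the default — and grid points outside a
trajectory's midpoint range stay missing; no imputation happens anywhere
downstream. The sea-level covariate is linearly interpolated onto the same
grid, without extrapolation.

Epoch summaries use the weighted harmonic mean H = Σw / Σ(w/Ne) with
weights equal to the overlap duration between each original segment and
the epoch. Summaries deliberately operate on the original segments (whose
durations are the natural weights), not the interpolated grid; for
piecewise-constant Ne this equals the continuous-time harmonic mean
exactly, which the tests confirm against a 1-year Riemann discretization.
Default epochs are the two windows of pronounced sea-level fluctuation
(350–150 ka and 120–15 ka) and the post-glacial rise (15–0 ka); all are
configurable because such boundaries are judgement calls.

## Quality control

Two quantile filters, both using linear interpolation between order
statistics (h = (n−1)q) so thresholds are bit-reproducible:

- **Replicate outliers** (q = 0.975): within a species and epoch, the
  threshold pools all replicates' in-epoch grid values — across the
  species' populations by default, per population by option — and any
  replicate with at least one value strictly above it is removed entirely
  for its population. Strict comparison means identical data remove
  nothing.
- **Extreme-value trimming** (q = 0.95): each replicate's own segment
  values above its own quantile are masked (set missing). The default
  masks wherever the threshold is exceeded; an edges-only mode restricts
  masking to leading/trailing runs, since implausible estimates
  concentrate where coalescent information runs out. Masked segments are
  excluded from interpolation and carry no harmonic-mean weight.

Curated removals (e.g., bootstrap sets known to contain hybrids) are a
config-driven exclusion list, never code.

## Split times

The relative cross-coalescence rate r(t) = 2λ₀₁/(λ₀₀+λ₁₁) is ~1 under
ancestral panmixia and decays to 0 after isolation. Scanning from the
present, the first adjacent midpoint pair with r_i < 0.5 ≤ r_{i+1}
brackets the split and the time is interpolated linearly in (r, t).
Curves never dropping below threshold return 0 with a `no_split` flag;
curves never reaching it return missing with `unresolved`. On noisy
curves the most recent crossing is used (reading the completion of
isolation); an oldest-crossing switch and optional 3-point median
smoothing are available but off by default, preserving the literal rule.
The estimate is invariant to common rescaling of the three rates.

## Windowed statistics

Sites pass a pooled minor-allele-frequency filter (MAF ≥ 0.02, computed
from observed chromosomes). Per-site π = ab/C(n,2) is averaged over 10 kb
windows; dxy = p₁(1−p₂)+p₂(1−p₁) over 50 kb windows. Windows are 0-based
half-open tiles from coordinate 0; VCF positions are converted on read.
Window means use the variant-sites denominator (matching averaging of
per-site values); a sequence-length denominator is available by flag.
FST is the Weir–Cockerham (1984) estimator for two populations with
unequal sample sizes and observed heterozygosity; the genome-wide value is
the ratio of sums Σa/Σ(a+b+c), since per-site ratios are unstable and may
be negative. Missing genotypes are dropped per site per population.
Geographic distance is the haversine great-circle distance (R = 6371 km).

## Comparative models

**Ne mixed model.** The response model is a Gamma GLMM with log link in
spirit: fixed effects are the full three-way interaction of standardized
sea level, host category and standardized time; random intercepts nest
species / population / replicate. The default backend (`lmm-log`) fits a
linear mixed model on log Ne — the log-link correspondence — via
statsmodels MixedLM, with population as a random intercept within species
(the published-formula variant with population also as a fixed effect is
available but redundant). Covariates are standardized over exactly the
rows entering the model, i.e. after all filtering.

One structural addition matters for inference: trajectory values
interpolated onto a dense grid are strongly dependent within a replicate,
so a model with intercept-only random effects would judge sea-level
contrasts against a pseudo-replicated residual and wildly overstate
significance. The default backend therefore gives each replicate a random
slope on standardized sea level, so that tests of sea-level effects are
referred to between-replicate slope variation. With this structure a
planted 0.5 vs 0 response contrast is recovered in sign with p < 0.05 in
20/20 seeded runs, while a null contrast rejects at the 5% level in 7/100
runs (both measured by the test suite). The intercept-only literal
structure remains available (`replicate_sea_slope=False`). Time-direction
coefficients are not protected by an analogous term and their p-values
should be read as descriptive. A fixed-effects Gamma GLM backend
(`glm-gamma`) serves as a sign/scale cross-check; every fit reports its
backend, convergence flag and row count. Optimization tries L-BFGS then
Powell, since variance components at the boundary routinely defeat
gradient methods; a zero-variance response is flagged degenerate rather
than fitted.

**Functional ANOVA.** Whole trajectories are compared between host groups
by a pointwise one-way F statistic at every grid point where each group
has at least two covered trajectories; the global statistic is the mean
pointwise F over those points. Significance comes from permuting host
labels at the species level (all trajectories of a species move
together — species, not replicates, are the exchangeable units), with
p = (1 + #{permuted ≥ observed})/(B + 1), deterministic per seed. Note
the granularity this implies: with s species there are only
C(s, s₁) distinguishable label assignments, so with 3 + 3 species the
smallest achievable p is ≈ 0.1; reaching the floor of 1/(B+1) requires
on the order of ten species per group.

**Epoch rank tests.** Kruskal–Wallis across host groups within each
epoch and rank-sum (Mann–Whitney) tests between epochs within each group,
with midrank tie handling and exact enumeration where scipy's exact
method applies. Raw p-values are reported without multiplicity
correction, matching the descriptive use of these tests. Rows with
insufficient data are flagged, not dropped.

**Pairwise adjustment.** FST and dxy are modelled separately as
value ~ standardized distance + standardized split time + host category
with crossed random intercepts for the two populations of each pair and
for species (statsmodels MixedLM with variance components; an OLS
backend exists for degenerate cases). Adjusted values subtract only the
fitted distance and split-time contributions, retaining host-category and
random-effect structure. A rank-deficient fixed design is an error that
names the collinear columns.

## Synthetic data

The generators define the study conditions and are pure functions of
(config, seed):

- **Sea level**: two cosine terms with 100 ky and 41 ky periods (both
  zero at present) plus smoothed noise re-zeroed at age 0, clamped to
  [−140, +10] m — the amplitude and periodicity of late-Pleistocene
  glacial cycles without claiming any particular reconstruction.
- **Trajectories**: segment boundaries log-spaced over [100, max_age]
  years; log Ne = log(base_Ne) + γ_host · z(sea at midpoint) + AR(1)
  lognormal noise (stationary, marginal sd `noise_sd`, default 0.2,
  lag correlation 0.3). Noise is multiplicative on Ne, matching the
  strictly positive Gamma response. Defaults: base Ne 20 000, 20
  segments, 50 bootstraps per population (the uncertainty design of the
  source reconstructions; the demo config scales this to 10). Bootstraps
  share their main run's boundaries for simplicity, but nothing
  downstream relies on that. A configurable fraction of contaminated
  replicates (default 0) exercises the outlier filter. Each trajectory
  can be emitted as an SMC scaled table via the inverse scaling, so the
  pipeline runs end-to-end from files.
- **Cross-coalescence**: constant within-rates 1/(2μN); the cross rate
  rises from 0 to the within rate as a step or a logistic centred at the
  known split, so the RCCR equals 0.5 exactly there.
- **Genotypes**: Balding–Nichols island model — ancestral frequency
  Uniform(0.05, 0.95), deme frequency Beta(p(1−F)/F, (1−p)(1−F)/F),
  genotypes Binomial(2, deme frequency) — written as a minimal
  deterministic VCF 4.2. Realized Weir–Cockerham θ recovers F (mean
  0.0998 over 20 seeds at F = 0.10, 2×25 diploids, 5000 sites).

What the synthetic data do **not** emulate: SMC estimation noise and its
time-correlation structure (bootstraps here are iid perturbations of a
known truth, not genome resamples), between-replicate differences in time
discretization, phasing or mapping artifacts, linkage and selection in
genotypes, migration after the split, and any real geography. Passing
tests therefore demonstrate the correctness and statistical behaviour of
the *analysis*, not the accuracy of SMC inference on real genomes, and
the published coefficients from the real dataset are not reproduction
targets.

## Problem sizes and determinism

The demo configuration (2 host groups × 3 species × 2 populations, 10
bootstraps, 20 segments; 12 demes × 8 diploids × 2000 SNPs) runs the full
pipeline in a few seconds; the calibration experiments in the test suite
use 20-seed power runs and 100-seed null sweeps at the same per-run
scale. All randomness flows from a single run seed through fixed offsets;
outputs embed the resolved-config hash and are byte-identical across
reruns.

## Known limitations

- statsmodels provides no true Gamma GLMM; the log-LMM correspondence is
  exact for the mean structure on the log scale but not for the variance,
  and Wald p-values use the normal approximation.
- The functional ANOVA's species-level permutation is coarse for few
  species (p-value floor C-dependent, see above).
- Harmonic means over an epoch only partially covered by a trajectory
  summarize the covered part; coverage is visible through the QC and
  ensemble exports.
- Multi-chromosome VCFs must be split by chromosome before reading;
  multi-allelic sites are skipped.
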