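# demres

Demographic-resilience analysis for SMC-based reconstructions of effective
population size (Ne), built around the question of whether ecologically
specialised marine populations (here: clownfishes bound to particular sea
anemone hosts) weathered Pleistocene sea-level fluctuations differently
from generalists.

The package consumes the *outputs* of sequentially-Markovian-coalescent
inference (MSMC2-style tables of scaled coalescence rates λ) plus diploid
genotypes in VCF, and implements the comparative analysis downstream:

- **Scaling** — scaled time `t` and rate `λ` become real years
  `t/μ · g` and `Ne = 1/(2μλ)` (defaults `μ = 4×10⁻⁸` per generation per
  site, generation time `g = 5` years).
- **Harmonization** — segment midpoints are interpolated onto a common
  grid of 100 log-spaced times between 1 year and the rounded maximum;
  points outside a reconstruction's range stay missing.
- **Quality control** — bootstrap replicates with any Ne above the 97.5%
  quantile of their species' pooled in-epoch values are dropped whole;
  within a replicate, values above its own 95% quantile are masked.
- **Epoch summaries** — Ne inside a climatic epoch is the weighted
  harmonic mean `H = Σw / Σ(w/Ne)` with segment-overlap durations as
  weights (drift compounds via 1/Ne).
- **Split times** — the relative cross-coalescence rate
  `r(t) = 2λ₀₁/(λ₀₀+λ₁₁)` crosses 0.5 at the population split; the
  crossing is located scanning from the present and linearly interpolated.
- **Windowed statistics** — per-site π = `ab/C(n,2)` averaged in 10 kb
  windows, Weir–Cockerham FST (ratio-of-sums θ), and
  `dxy = p₁(1−p₂) + p₂(1−p₁)` in 50 kb windows, after a MAF ≥ 0.02 filter.
- **Comparative models** — a mixed model of log Ne on
  sea level × host category × time with nested species/population/replicate
  random effects; a permutation functional ANOVA of whole trajectories;
  Kruskal–Wallis and rank-sum tests of epoch harmonic means; and a
  fixed-effect-removal adjustment of pairwise FST/dxy for geographic
  distance and split time with crossed population random intercepts.

Because the original genomes are not required, a first-class synthetic
module generates every input with known parameters: a glacial-cycle
sea-level curve, piecewise Ne trajectories whose log-Ne responds linearly
to sea level with host-specific coefficients, cross-coalescence tables
with known split times, and Balding–Nichols genotypes with known FST.

## Worked example

Run the bundled desk-scale demo (2 host groups × 3 species × 2
populations, 10 bootstraps, 2000 SNPs in 12 demes) end to end:

```bash
demres run --stage all --outdir out --seed 1
```

This writes simulated SMC tables, VCF and sea-level series under
`out/sim/`, then the harmonized ensemble, QC reports, split-time
estimates, harmonic-mean summaries, windowed statistics, model fits and
adjusted pairwise statistics. With seed 1 the key numbers are:

- `out/model/glmm_coefficients.csv` — the sea-level × host-category
  interaction is `+0.680` (p ≈ 0 at double precision, backend
  `lmm-log`): the specialist
  group was simulated with log-Ne response −1 to standardized sea level
  and generalists with 0, and the fitted contrast recovers that gap in
  sign and magnitude (covariates are re-standardized over the model
  table, so the coefficient is scaled accordingly).
- `out/summarize/harmonic_means.csv` — median specialist harmonic-mean Ne
  is 2.20× higher in the 120–15 ka fluctuation epoch than in the 15–0 ka
  rise, while the generalist ratio is 1.01: the simulated specialist
  decline with post-glacial sea-level rise, and nothing else, survives
  the whole pipeline.
- `out/split/split_times.csv` vs `out/sim/true_split_times.csv` — RCCR
  split-time estimates land within ~1.4% of the generator's truth on
  average.
- `out/popgen/pairwise.csv` — mean Weir–Cockerham θ across demes is
  0.099 against a Balding–Nichols target of 0.10.

Each output CSV carries a header comment with the resolved-config hash
and seed; re-running with the same config is byte-identical.

## Layout

```
src/demres/
  smc_io.py      SMC-table parsing and unit scaling
  synthetic.py   generators for sea level, trajectories, splits, genotypes
  harmonize.py   common grid, interpolation, epochs, harmonic means
  qc.py          quantile-based replicate and value filters
  split_time.py  RCCR curves and split-time estimation
  popgen.py      MAF filter, pi, Weir-Cockerham FST, dxy, distances
  stats.py       mixed models, functional ANOVA, rank tests, adjustment
  config.py      YAML run configuration
  pipeline.py    stage orchestration
  cli.py         demres command-line interface
```

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
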