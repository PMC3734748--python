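# hospprofile

Bayesian profiling of hospital performance on risk-adjusted 30-day
mortality. The package implements a complete, seeded pipeline:

1. **`hospprofile.cohort`** — synthetic admission-level cohort generator
   (hospital, age, systolic blood pressure, heart rate, discharge
   diagnosis, 30-day death status) with known ground truth: hospital
   effects drawn from a normal distribution on the log-SMR scale.
2. **`hospprofile.casemix`** — cohort filters (age 18–100, SBP 49–250,
   heart rate 20–200, sparse-hospital exclusion), covariate banding
   (fixed age bands; SBP/HR empirical fifths), a banded logistic risk
   model fitted by IRLS with a c-statistic, and per-hospital observed
   (O) and expected (E) deaths.
3. **`hospprofile.bayes`** — Poisson models `O_i ~ Poisson(E_i exp(θ_i))`
   under a fixed prior `θ_i ~ N(0, 1000)` or a hierarchical prior
   `θ_i ~ N(μ0, σ0²)` with conjugate hyper-priors (gamma on the
   precision, or uniform on the SD as a sensitivity option). Sampling is
   adaptive Metropolis-within-Gibbs over multiple lock-step chains, with
   Gelman–Rubin diagnostics.
4. **`hospprofile.profiling`** — risk-adjusted mortality rates
   `RAMR = μ30·exp(θ)`, exceedance-probability classification against
   `(1±δ)·μ30` thresholds, posterior rank credible intervals, and
   quartile-based rank classification.
5. **`hospprofile.agreement`** — 3×3 cross-tabulations of the four
   method labels (fixed/hierarchical × RAMR/rank) and linearly weighted
   Cohen's kappa for all six pairwise comparisons.
6. **`hospprofile.pipeline` / `hospprofile.cli`** — end-to-end seeded
   orchestration with manifests, plus threshold / hyper-prior
   sensitivity reruns.

## CLI

Every verb accepts `--seed` and `--output-dir`.

```sh
# full pipeline from defaults (or a YAML config)
hospprofile run --seed 1 --output-dir out
hospprofile run --config config.yaml

# individual stages
hospprofile generate --seed 1 --output-dir out
hospprofile adjust   --cohort out/cohort.csv --output-dir out
hospprofile fit      --summaries out/hospital_summaries.csv --kind both \
                     --iterations 5000 --burn-in 1000 --seed 1 --output-dir out
hospprofile profile  --summaries out/hospital_summaries.csv \
                     --draws out/draws_fixed.csv --output-dir out
hospprofile agree    --profiles fixed out/profiles_fixed.csv \
                     --profiles hierarchical out/profiles_hierarchical.csv \
                     --output-dir out

# sensitivity: rerun with delta = 0.15 and/or a uniform-SD hyper-prior
hospprofile sensitivity --delta 0.15 --hyper-prior uniform_sd --output-dir out
```

Example YAML config:

```yaml
cohort:
  n_hospitals: 128
  size_median: 300
  size_max: 2200
  seed: 1
mcmc:
  n_chains: 3
  n_iterations: 50000
  burn_in: 15000
  seed: 1
profiling:
  delta: 0.20
mu30_override: 10.2   # omit to compute mu30 from the analysed cohort
output_dir: out
```

Note: at the default MCMC scale (3 chains × 50,000 iterations) the
persisted draw files are large; reduce `n_iterations` or set
`write_draws: false` for exploratory runs.

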