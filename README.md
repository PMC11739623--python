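# frugijam

Joint Bayesian modelling of frugivore diets, bite-force allometry and fruit
traits, built around three chained model stages:

1. **Joint attribute model** (`frugijam.gjam`) — a censored multivariate
   (Tobit/probit-style) Gibbs sampler linking bat covariates (species, age,
   sex, reproductive condition, standardized mass and forearm length) to the
   latent tendency of each plant species to appear in a fecal sample.  The
   correlation-scale coefficients are the per-covariate × per-plant
   *consumption indices*, summarized by posterior median, 95% HPD interval and
   a strong-response flag.  Supports presence/absence and fractional
   composition responses, DIC, covariate sensitivity, posterior-predictive
   richness/diversity checks, split-R̂ and ESS diagnostics.
2. **Hierarchical bite-force model** (`frugijam.biteforce`) — log-scale
   allometry of maximum bite force with species-level intercepts, half-Cauchy
   variance priors (sampled via inverse-gamma parameter expansion), OLS
   prechecks, Gelman–Pardoe variance explained and the head–forearm Pearson
   correlation.
3. **Phylogenetic trait regression** (`frugijam.phylo`) — per-plant consumption
   indices regressed on fruit and seed shape (length/width ratios) with a
   Brownian-motion phylogenetic random effect built from a Newick tree; run as
   a four-response battery (forearm, mass, and the two focal bat species).

A first-class synthetic-data module (`frugijam.synth`) emulates every input
table with known ground truth — bat cohorts, zero-inflated diet matrices,
pure-birth trees with Brownian traits, bite-force records — so the entire
chain is verifiable by parameter recovery without any download.

## CLI

Every stage is exposed through one executable:

```bash
frugijam simulate --scenario paper-shaped --seed 7 --out data/
frugijam prep --config cfg.yml --bats data/bats.csv --out prep/
frugijam fit-gjam --config cfg.yml --design prep/design.csv --diet prep/diet_fc.csv --out posterior/
frugijam summarize --posterior posterior/ --out indices.csv
frugijam fit-biteforce --data data/biteforce.csv --size-covariate ln_forearm --out bf/
frugijam fit-traits --indices indices.csv --traits data/traits.csv --tree data/tree.nwk --out traits.csv
frugijam run --config run.yml        # full pipeline with stage caching
```

`frugijam run` drives prep → joint model (both response modes, with DIC
comparison) → consumption indices/sensitivity/PPC → bite force → trait battery
from a single YAML config and writes a run manifest; completed stages are
skipped on re-run unless their input hashes change.  Exit codes: 0 ok,
2 validation error, 3 numerical failure.

Example `run.yml`:

```yaml
seed: 7
bats: data/bats.csv
biteforce_data: data/biteforce.csv
traits_data: data/traits.csv
tree: data/tree.nwk
out: runs/demo
gjam: {n_iterations: 20000, n_burnin: 4000, thin: 10, n_chains: 2}
biteforce: {size_covariate: ln_forearm}
traits: {n_iterations: 50000, n_burnin: 5000, thin: 10}
```

## Deposited-data schema (`data/external/`)

`data_s1_bats.csv` — one row per captured bat:
`bat_id, species, sex, age_class, repro, forearm_mm, mass_g` followed by one
`Piper_<name>` 0/1 column per plant species (use the plant names
`hispidum, colonense, silvivagum, aduncum, Type1, Type4, ...` so the headline
cells resolve).  Species ∈ {perspicillata, sowelli, castanea}; age ∈
{adult, subadult, juvenile}; repro ∈ {reproductive, non_reproductive}.
`frugijam.io.ColumnSchema` can remap column names and factor codes when
converting the original deposit.

`data_s1_biteforce.csv` — one row per measured adult:
`bat_id, species, sex, head_length_mm, head_width_mm, head_height_mm,
forearm_mm, mass_g, max_bite_force_n`.

## Layout

```
src/frugijam/
  io.py         # domain types, CSV/Newick/posterior-archive readers & writers
  design.py     # design-matrix encoding, rare-species filter, diet summaries
  gjam.py       # censored joint attribute model + posterior summaries
  biteforce.py  # OLS prechecks + hierarchical allometry
  phylo.py      # phylogenetic covariance + trait regression battery
  synth.py      # generators and named scenario fixtures
  cli.py        # click CLI and pipeline orchestration
```
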