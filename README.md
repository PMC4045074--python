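# aquadyn

Spatio-temporal analysis of drinking-water microbiomes.

Drinking water leaving a treatment plant (DWTP) carries a planktonic
bacterial community into the distribution system (DWDS) and on to the
tap. Monthly OTU-level monitoring campaigns of such systems pose a
recurring set of questions: how much does the community change along
the pipes (distance decay), how does it cycle over the year, which
groups of taxa move together (seasonal clusters), and can a taxon's
detection frequency be predicted from its abundance? `aquadyn` is a
library for answering them, aimed at microbial ecologists and water
engineers working with OTU count tables, sample metadata, a phylogeny
and a pipe inventory.

## What it computes

* **Rarefied diversity** — repeated subsampling to a common depth;
  richness, Shannon H, the Chao–Shen nonparametric Shannon and
  evenness; Bray–Curtis, Jaccard and (un)weighted UniFrac matrices
  averaged over subsampling events; PCoA with negative eigenvalues
  reported, not dropped.
* **Permutation statistics** — PERMANOVA, ANOSIM, Mantel and
  beta-dispersion (with ANOVA/Tukey), each with a seeded permutation
  p-value and an exhaustive small-sample mode; core-OTU selection
  curves (Mantel r of thresholded sub-communities vs the full table).
* **Distance decay** — shortest water paths on the pipe graph (total
  length, total surface π·d·L, age-weighted variants) correlated with
  month-matched community dissimilarity between locations;
  site-specific OTU summaries.
* **Time-lag dynamics** — within-location beta distance binned by
  month difference; divergence of each DWDS location from the
  same-month plant sample.
* **Association networks** — the maximal information coefficient
  (MIC), computed per rarefaction event under a co-occurrence gate,
  with edges kept only when repeatedly significant (Bonferroni-
  corrected permutation p) with a consistent slope sign; seasonal
  cluster extraction from the positive-edge subgraph; network
  statistics and cluster abundance time series; an unweighted-UniFrac
  contrast between clusters.
* **Occupancy–abundance models (IOAM)** — per-OTU-per-month points
  (μ, f) feed five classical laws (Poisson, Nachman,
  Hanski–Gyllenberg P = αμ/(1+αμ), power, negative binomial; β fixed
  at 1) fitted by maximum likelihood with a binomial likelihood on
  fractional occupancies; model ranking by log-likelihood and mean
  absolute deviance; a per-month α with a month-randomization
  permutation envelope.
* **Synthetic campaigns** — a generator that emulates a 15-month,
  10-location survey with planted anti-phase seasonal clusters, an
  occupancy law, along-pipe community drift, site-specific taxa and an
  881-section pipe inventory, with full ground-truth bookkeeping so
  every stage above can be validated end to end.

## Worked example

```python
from aquadyn import (RarefactionPlan, SyntheticSpec, average_distance,
                     beta_matrix, compare_models, generate,
                     occupancy_points, permanova, rarefy, time_lag_curve)

data = generate(SyntheticSpec(n_otus=300, seed=7))
depth = int(data.table.sample_totals().min())
plan = RarefactionPlan(depth=depth, n_events=5, base_seed=1)

bc = average_distance(beta_matrix(ev, "bray_curtis")
                      for ev in rarefy(data.table, plan))
month = data.metadata.column("month_index", bc.ids)
res = permanova(bc, month, n_perm=199, seed=0)
print(f"month R^2 = {res.extras['r_squared']:.3f}, p = {res.p_value:.3f}")

curve = time_lag_curve(bc, data.metadata)
print(f"lag curve peaks at {curve['mean'].idxmax()} months")

points = occupancy_points(rarefy(data.table, plan), data.metadata)
print(compare_models(points)[["model", "param", "loglik"]].head(2))
```

prints

```
month R^2 = 0.642, p = 0.005
lag curve peaks at 6 months
               model       param        loglik
0  hanski_gyllenberg  535.883994  -9645.904191
1            nachman  266.957873 -10049.399751
```

Month explains 64% of the community variation (seasonality dominates
space), the community is most dissimilar to itself 6 months apart (an
annual cycle), and the Hanski–Gyllenberg law — the one the generator
planted — outranks the alternatives, its fitted α pulled somewhat
below the planted 896 by the detection-conditioning of observed
occupancy points (see `docs/methods.md`).

Longer narrative scripts, one per capability, live in `examples/`.
A thin CLI mirrors the stages (`aquadyn simulate|rarefy|beta|betastats|
coreselect|spatial|temporal|associate|ioam|run`); `aquadyn run
--config run.yaml` executes the whole pipeline and writes a manifest
of content-hashed outputs.

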