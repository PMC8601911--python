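# grassnet

Detection-adjusted density surfaces for grassland songbirds, and a spatial
null model for asking whether an existing conservation-area network actually
sits on population hot spots.

Grassland birds are the fastest-declining avian group in North America, and
the conservation networks meant to protect them — large priority "Focal
Landscapes" holding smaller Grassland Bird Conservation Areas (GBCAs) — were
typically drawn from expert opinion before statewide abundance data existed.
`grassnet` implements the full evaluation chain needed to test such a
network against data, on fully synthetic landscapes with known ground truth:

1. **Simulation** — a four-class land-cover mosaic (grassland, agriculture,
   forest, urban) with patch structure, smooth climate surfaces, a nested
   Focal-Landscape/GBCA network placed in grass-rich habitat, survey sites
   >400 m apart, and removal-protocol point counts.
2. **Density modeling** — the removal multinomial-Poisson *N*-mixture model.
   Latent abundance at site *i* is `N_i ~ Poisson(λ_i · A)` with
   `log λ_i = x_iᵀβ` (λ a density per km², `A` the area of a 100-m-radius
   circle), and a 10-min count split into J = 5 two-minute bins records only
   newly detected birds, so bin *j* captures an individual with probability
   `π_j = p(1−p)^{j−1}` (`logit p` linear in Julian date). Marginalizing N
   gives the closed-form likelihood
   `T_i ~ Poisson(λ_i A (1−(1−p_i)^J))` × conditional multinomial.
   Fit by maximum likelihood; goodness of fit by parametric-bootstrap
   chi-square; overdispersion ĉ (floored at 1) inflates Wald SEs by √ĉ;
   validation by holdout AUC, RMSE/MAE, Spearman's ρ and a binned Moran's I
   residual correlogram.
3. **Prediction** — 1-km² density surfaces with ±1.96·SE error-propagation
   layers, evaluated independently.
4. **Conservation evaluation** — baseline mean densities per area (500-m
   boundary buffer), percent of the statewide population inside the network
   (vs the 20% planning target and 10% IUCN threshold), and the optimal
   minimum set of cells reaching a population target.
5. **RTR null model** — 1000 random translation–rotation replicates of each
   conservation area, shape- and size-preserving, constrained to suitable
   habitat (replicates with >20% of cells that are ≥50% forest+urban are
   redrawn). An area *represents* a species when its baseline density
   exceeds the empirical 90th percentile of the replicate means. Three
   scenarios: Focal Landscapes vs statewide, GBCA ensembles vs statewide,
   and GBCA ensembles vs their own Focal Landscape.

## Worked example

```python
import numpy as np
from grassnet import demo_config, run_pipeline

bundle = run_pipeline(demo_config(seed=1))

m = bundle.models["hotspot"]
print("grassland coefficient:", round(m.beta_abund[1], 3), "+/-", round(m.se[1], 3))
print("c-hat:", round(m.c_hat, 3),
      " mean AUC:", round(bundle.validation["hotspot"]["auc"]["mean_auc"], 3))
print(bundle.percent_network[["species", "percent_statewide"]].round(2).to_string(index=False))
print("focal-vs-state flags:",
      {(r.area, r.species): r.represented
       for r in bundle.scenario_results[("focal_vs_state", "point")].results})
```

prints (seed 1):

```
grassland coefficient: 0.42 +/- 0.055
c-hat: 1.097  mean AUC: 0.817
species  percent_statewide
hotspot              48.53
uniform               5.88
focal-vs-state flags: {('FL0', 'hotspot'): True, ('FL0', 'uniform'): False, ('FL1', 'hotspot'): False, ('FL1', 'uniform'): False, ('FL2', 'hotspot'): False, ('FL2', 'uniform'): False}
```

The demo simulates two species. The *hotspot* species tracks maximum
temperature, which has a warm bump centered on Focal Landscape 0 — its
fitted grassland coefficient recovers the true 0.4, almost half its
statewide population falls inside the 588-km² network, and the RTR test
flags exactly FL0 as holding significantly more of it than randomly placed
equal-shape areas. The *uniform* species has no habitat associations; its
fitted surface is exactly flat, only 5.88% of its population (the network's
areal share) is covered, and no area is flagged.

The same machinery is exposed piecewise — see `examples/` for short
narrative scripts per capability, and the `grassnet` CLI (`run-all`,
`stage`, `demo-config`) for shell-driven runs from a YAML config.

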