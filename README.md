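# kvflow

Quantitative analysis of left–right (L–R) organizer phenotypes in zebrafish:
multinomial permutation tests for phenotype distributions, Bayesian
malformation-probability estimates, bead-flow quantification inside the
Kupffer's vesicle (KV), and dorsal-forerunner-cell (DFC) migration
kinematics — with seeded synthetic-data generators so that the complete
pipeline runs and is testable without any external download.

## Who this is for

Developmental biology groups scoring L–R asymmetry readouts (heart looping,
visceral organ positioning, marker expression) across genotypes, and groups
quantifying the cilia-driven vortex flow of the L–R organizer from
fluorescent-microbead time-lapses.

## What it computes

**Phenotype statistics** (`kvflow.phenostats`). Each embryo contributes one
categorical outcome, so a condition is a multinomial count vector. Two
conditions α, β with counts (k<sub>α,c</sub>), (k<sub>β,c</sub>) and totals
N<sub>α</sub>, N<sub>β</sub> are compared with the dissimilarity

> δ = Σ<sub>c</sub> | k<sub>α,c</sub>/N<sub>α</sub> − k<sub>β,c</sub>/N<sub>β</sub> |,

i.e. twice the total-variation distance between the empirical
distributions. The p-value of the null hypothesis (one shared multinomial)
is estimated by pooling all N<sub>α</sub>+N<sub>β</sub> labelled
observations and re-splitting them at random into groups of the original
sizes K = 100,000 times; p is the frequency of re-splits with δ′ ≥ δ (ties
count; zero exceedances are reported as the bound p < 1/K). Binary
malformation outcomes get a Beta(k+1, n−k+1) posterior (uniform prior),
whose standard deviation is the error bar, plus a two-sided Fisher exact
test. `reconstruct_counts` rebuilds integer counts from percentages printed
to two decimals.

**Bead flow** (`kvflow.beadflow`). Detection of 0.75–1.25 µm fluorescent
spots (multi-scale Laplacian-of-Gaussian with size and brightness gates,
sub-pixel centroids), nearest-neighbour linking with a 2.5 µm per-frame
gate, time-averaged mean square displacement MSD(Δt), and model comparison

* directed: MSD = 4DΔt + v²Δt²
* confined: MSD = L²(1 − exp(−4DΔt/L²))
* diffusive: MSD = 4DΔt

selected by corrected Akaike score, plus mean per-track bead speed.

**DFC kinematics** (`kvflow.dfc_kinematics`). Convergence ratio (cluster
y-extent at recording start over end), mean migration speed (µm/min), and
migration index (position as percent of embryo length along the
animal-to-vegetal axis).

**Synthetic data** (`kvflow.synthetic_data`). Multinomial tables, beads in
a counter-clockwise vortex / confined / free-diffusion regime, rendered
Gaussian-spot stacks with ground truth, and converging DFC-style tracks.

## Worked example

```sh
$ kvflow reconstruct --percent 38.17,25.95,35.88
{
  "total": 131,
  "counts": [50, 34, 47],
  ...
}
```

The printed heart-looping percentages of the triple meteorin mutant are
consistent with exactly one total ≤ 1000: N = 131 with counts (50, 34, 47)
for (D-loop, mild/no-loop, S-loop). Comparing against the wild-type
distribution:

```sh
$ kvflow perm-test --table-a wt.csv --table-b triplmut.csv \
      --resamples 100000 --seed 1
{
  "delta_observed": 1.0052362626963598,
  "n_resamples": 100000,
  "exceedances": 0,
  "p_value": 0.0,
  "is_lower_bound": true,
  "reported_p": 1e-05,
  ...
}
```

δ = 1.005 means the two frequency vectors differ by a total of ~100
percentage points across categories; no random re-split of the pooled 252
embryos reached that dissimilarity, so the heart-looping distributions
differ with p < 10⁻⁵. The same machinery in Python:

```python
from kvflow import phenostats
res = phenostats.permutation_test((107, 14, 0), (50, 34, 47),
                                  n_resamples=100_000, seed=1)
print(res)           # p < 1e-05 (0/100000 exceedances)

post = phenostats.binomial_posterior(119, 182)
print(round(post.mle, 4), round(post.posterior_sd, 4))   # 0.6538 0.035
```

A full simulated flow analysis:

```sh
kvflow simulate-beads --mode directed --tangential-speed 1.0 --seed 1 \
    --tracks-out beads.csv
kvflow classify --tracks beads.csv      # -> "verdict": "directed"
kvflow speed --tracks beads.csv         # -> "mean_speed": ~1.0
```

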