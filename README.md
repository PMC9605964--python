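# microcolony

Mechanism-of-heterogeneity discrimination for single-cell lineage data.

Clonal microbial populations under stress often split into phenotypically
distinct subpopulations — for example, under glucose deprivation most
*E. coli* cells hold little intracellular ATP while a small subpopulation
retains a lot, producing a long-tailed ATP distribution. Four classes of
mechanism can generate such heterogeneity: stochastic state switching,
periodic oscillation, cellular (replicative) age, and intercellular
transmission. Given a time-lapse microcolony movie — a lineage table with
each cell's 2D centroid and a ratiometric ATP-biosensor readout per hourly
frame — this package runs one dedicated statistical test per mechanism and
reports which signature the data carry. It is aimed at quantitative
microbiologists analysing segmented/tracked single-cell time-lapse data.

## The statistics at its core

* **Diversity**: Fisher–Pearson skewness g₁ = m₃/m₂^{3/2} (population
  moments m_i = (1/N)Σ(x−x̄)^i) with a parametric randomization test
  (skewness of 100,000 normal samples matched in μ, σ, n; upper-tail
  fraction as p).
* **High/low classes**: a 2-component Gaussian mixture fitted by EM to the
  ATP distribution; the global threshold is the equal-posterior point
  between the component means.
* **Switching**: a 2-state Baum–Welch HMM on HIGH/LOW lineage sequences;
  each transition probability is compared with a 4000-replicate
  within-sequence shuffle null (significant below the 5th / above the 95th
  percentile).
* **Oscillation**: Gaussian-process regression per lineage
  (power-exponential correlation, β = log₁₀θ; fits with β > 4 excluded),
  then the dominant periodogram component (principal frequency and
  amplitude) compared between classes by Mann–Whitney.
* **Age**: replicative pole age (divisions the old pole has persisted),
  assigned geometrically at each division, compared between classes by
  Mann–Whitney.
* **Transmission**: a nearest-neighbour class-localization permutation
  test, plus the spatial-vs-lineage factor decomposition — per cell,
  phenotype differences to the nearest neighbour (dNB), its sister (dER),
  the closest relative (dCR), and a spatially equidistant cell (dED); mean
  dER/dNB and dED/dCR ratios carry 95% t-intervals (H₀: ratio = 1). A
  spatially transmitted phenotype shows dER/dNB > 1 with dED/dCR ≈ 1.
* **Growth**: the generalized Euler–Lotka equation
  (1/Δ)ln⟨e^{−ΛΣτᵢ}⟩ = −ln 2 solved for the population growth rate Λ from
  per-lineage interdivision times.

A generative microcolony simulator (binary fission, 2D geometry, one
regime per mechanism) provides ground-truth inputs for every stage.

## Worked example

Simulate a glucose-deficient-like colony (transmission regime, 6
generations, 3 founder microcolonies) and test it:

```
$ microcolony simulate --regime transmission --generations 6 --seed 1 --out colony.csv
wrote 381 cells to colony.csv

$ microcolony skewness colony.csv --n-draws 20000 --seed 2
n = 192
skewness g1 = 1.47023
randomization p = 0.00000

$ microcolony test-transmission colony.csv --n-perm 2000 --seed 3
localization p = 0
dER/dNB = 1.492 [1.197, 1.860] reject H0: True
dED/dCR = 0.922 [0.735, 1.158] reject H0: False

$ microcolony growth-rate colony.csv
Lambda = 0.26879 /h
Delta = 6, n_lineages = 192, residual = -3.44e-11
```

Reading the numbers: the 192 final-frame cells have a strongly
right-skewed ATP distribution (g₁ = 1.47; no null draw was as skewed, so
p = 0.00000) — a small high-ATP subpopulation exists. Same-class cells are
spatially clustered (localization p ≈ 0), the clustering is carried by
sheer spatial proximity (dER/dNB interval excludes 1 from above) and not
by lineage (dED/dCR interval contains 1) — the transmission signature.
The colony doubles roughly every ln 2/0.269 ≈ 2.6 h. The remaining stages
(`test-switching`, `test-oscillation`, `test-age`) and the one-shot
pipeline (`microcolony run --regime transmission --outdir out/`) follow the
same pattern; every subcommand also runs on your own lineage CSV (header
`cell_id,parent_id,frame,time_h,x_um,y_um,fluor_405,fluor_488,atp_mM,placeholder`).

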