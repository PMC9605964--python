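# Methods

This package discriminates between four candidate mechanisms of phenotypic
heterogeneity in clonal microcolonies — stochastic state switching, periodic
oscillation, cellular age, and intercellular transmission — from a single
kind of input: a time-lapse lineage table with per-cell positions and a
ratiometric-biosensor readout of intracellular ATP. This note records the
statistical models, the parameter choices that matter, and the places where
the design was genuinely open.

## Data model

A movie is a forest of binary-fission cell records; each cell carries
per-frame observations (time in hours, centroid in µm, ATP in mM or a
405-nm/488-nm fluorescence pair). Frames where segmentation failed upstream
are kept as *placeholders*: they preserve tree topology and are excluded
from every statistic. All analyses run on root-to-leaf *lineages* (paths),
the natural unit of temporal continuity across divisions.

## Calibration

The biosensor's 405/488 excitation ratio is mapped to ATP through a
monotone shape-preserving cubic (PCHIP) through the standard-curve points;
the inverse map is obtained by root-solving on the same interpolant, so the
two directions are numerically consistent over the whole calibrated range.
Ratios outside the calibrated range are clamped with a warning — the sensor
saturates, so extrapolation would be meaningless.

## Population diversity: skewness

Diversity of the per-cell ATP distribution is summarised by the
Fisher–Pearson coefficient g1 = m3 / m2^{3/2} with population moments
(divisor N). Significance comes from a parametric randomization test:
100,000 (default) normal samples with the observed mean, standard
deviation (divisor N−1) and size; the p-value is the raw upper-tail
fraction of null draws whose skewness is at least the observed one, so a
left-skewed sample reports p near 1 and a heavy right tail reports p near
0. Because g1 is location–scale invariant, this null is exact, and the
p-value is uniform under normal data (verified by a 200-seed
Kolmogorov–Smirnov check). The add-one corrected fraction (r+1)/(B+1) is
reported alongside for users who need a p-value bounded away from 0 and 1.

## Global high/low classification

The ATP distribution is split by a two-component univariate Gaussian
mixture fitted by EM (50 k-means-initialised restarts by default, tolerance
1e-8, deterministic seeding). The threshold is the equal-posterior point
between the two component means. Two practical notes:

* The 1-D mixture likelihood is unbounded, and on near-unimodal (control)
  data EM can wander on the ridge without reaching the strict tolerance.
  The fit then falls back to a relaxed tolerance and accepts a plateaued
  best fit with a warning; the hard error is reserved for degenerate input.
* With heavily overlapping components an exact equal-posterior crossing may
  not exist between the means; the threshold is then placed where the
  posteriors are closest to equal. On structureless data any threshold is
  scientifically equivalent — the mechanism tests below are calibrated
  against their own nulls.

A cell's class is its lifetime-mean ATP versus the threshold; a single
frame's class is that frame's ATP versus the threshold. The spatial
analyses (below) use frame classes, the age and oscillation comparisons use
cell classes. The distinction matters: lifetime means of cells observed for
different numbers of frames have different variances, and trace length
correlates with birth time and hence with position in a growing colony —
classifying a snapshot by lifetime means therefore manufactures spurious
spatial clustering (we measured a ~3× inflation of the localization test's
false-positive rate before switching the snapshot analyses to frame
classes).

## Mechanism test 1: stochastic switching (2-state HMM)

Each lineage is binarized into HIGH/LOW symbols and a single 2-state HMM is
fitted to the pooled lineages by Baum–Welch (5 random restarts, best
likelihood kept; states canonically ordered by their HIGH-emission
probability to resolve label switching). Significance of each transition
probability uses a randomization test: in each of 4000 (default)
replicates, every sequence's symbols are permuted in time — destroying
temporal order, preserving per-sequence symbol counts — and the HMM is
refitted; an observed edge below the null 5th percentile is *significantly
small*, above the 95th percentile *significantly large*.

Because the null refits thousands of HMMs, the Baum–Welch core is written
twice: a batched NumPy reference (recursions vectorised over replicates ×
restarts) and a compiled numba path with per-fit early stopping, ~15×
faster; the two are cross-checked against each other and against an
external HMM library in the test suite.

What this test detects deserves care: on lineage data any clonal or
temporal structure — inherited states, oscillation, age gradients —
produces significant edges, because the within-sequence shuffle only
destroys *temporal order within a lineage*. In our regime simulations the
test fires for the switching, age and oscillation regimes alike (and
occasionally for control/transmission colonies). It is therefore a test of
*temporal non-randomness*, not of switching specifically; mechanism calls
should rest on the pattern across all four tests. On exchangeable (iid)
sequences the 5th/95th rule is exactly calibrated (verified at 500
shuffles, 20 seeds).

## Mechanism test 2: periodic oscillation (GP + periodogram)

Each lineage's ATP trajectory is smoothed by a Gaussian process with a
power-exponential correlation (power 1.95) on inputs rescaled to [0, 1];
the constant mean and variance are profiled out and the single roughness
hyperparameter is optimised as beta = log10(theta) by multi-start L-BFGS-B
(bounds [−6, 8], ~10 starts, iteration budget 10,000). A fitted beta above
4 means the correlation length collapsed below the frame interval — the
regression is chasing noise — and that lineage is excluded from the
oscillation analysis (the exclusion log records it). The principal
frequency and amplitude are read off the discrete Fourier transform of the
mean-detrended posterior mean on a uniform 256-point grid (frequency of the
largest positive-frequency coefficient; amplitude 2|X_k|/N). Classes are
compared feature-wise by two-sided Mann–Whitney tests. Sinusoids with
periods 4–15 h under 10% noise are recovered within one periodogram bin in
≥18/20 seeds; a numerical jitter (1e-10, escalated on failure) keeps the
correlation matrix factorable.

## Mechanism test 3: cellular age (pole age)

Replicative age is the number of divisions a cell's older pole has
persisted. At each division the daughter whose first centroid lies farther
from the parent's own birth centroid inherits the old pole (age + 1); her
sister inherits the pole created at the parent's birth (age 1). Founder
poles start at age 0, so after g synchronous generations exactly two cells
carry age g — the induction oracle used in the tests. Exact distance ties
are broken toward the lower cell id and flagged. Ages are compared between
ATP classes by a two-sided, tie-corrected Mann–Whitney test.

## Mechanism test 4: intercellular transmission (spatial analysis)

Both analyses run on the final movie frame (largest colony). The
*localization test* asks whether cells' nearest neighbours share their
class more often than label permutations allow (upper-tail permutation
p-value, 10,000 permutations by default). The *factor decomposition*
computes per focal cell four absolute phenotype differences (phenotype =
lifetime-mean ATP):

* dNB — to the nearest spatial neighbour;
* dER — to that neighbour's sister; when the sister is the focal cell
  itself or absent from the snapshot, the neighbour's next-closest relative
  (cousin/niece) stands in, so the comparison cell is always drawn from the
  neighbour's sister lineage;
* dCR — to the closest relative by lineage-path distance (spatial
  proximity breaks ties);
* dED — to the cell (excluding the closest relative) whose distance to the
  focal cell best matches the focal–closest-relative distance, chosen as
  the minimiser of the distance mismatch so it always exists.

Per-cell ratios dER/dNB (spatial factor) and dED/dCR (lineage factor) are
averaged on the log scale with 95% t-intervals, back-transformed; H0
(ratio = 1) is rejected when the interval excludes 1; non-positive ratios
cannot be logged and are excluded with a count. A spatially transmitted
phenotype gives dER/dNB above 1 with dED/dCR at 1; a heritable phenotype
gives the reverse (in the age regime dED/dCR falls *below* 1, because
sisters differ sharply in pole age). One caveat is inherent: per-cell
ratios within one colony share the same field realisation, so the
t-interval is exact only across colonies; the simulator's default of three
founder microcolonies per run (the study design) keeps it honest.

## Growth rate

The population growth rate Λ solves the generalized Euler–Lotka relation
(1/Δ) ln⟨exp(−Λ Στ_i)⟩ = −ln 2 over root-to-leaf interdivision-time
sequences, with Δ the minimum division count across lineages (longer
lineages truncated, logged). The left-hand side is strictly decreasing in
Λ — asserted numerically on a grid before root acceptance — so
bracketing + Brent gives the unique root to 1e-10. Closed-form limits
(constant τ ⇒ Λ = ln 2/τ; the two-lineage Δ=1 case ⇒ u² + u = 1) are exact
test oracles. Conditions are compared by Mann–Whitney on per-lineage rates
(closed form Δ ln 2 / Στ).

## The synthetic microcolony simulator

The simulator generates what the analyses consume: hourly observations of
binary-fission microcolonies (default: 3 founders, 7 generations ≈ 20 h,
matching the 20–30 h hourly-imaging design and 3 replicate colonies per
condition), lognormal interdivision times (mean 2.5 h, CV 0.15), point-cell
geometry with daughters placed beside the mother along the axis away from
her birth site (old-pole daughter farther, so the pole-age rule is
recoverable) plus pairwise overlap relaxation to ~1 µm spacing, and ATP on
the 0–10 mM sensor scale with AR(1) frame noise (sd 0.15 mM).

Regimes: **control** — stationary noise around 4.5 mM, no inheritance
across division; **switching** — inherited two-state telegraph
(1.0 ↔ 4.5 mM, 0.15/h each way); **oscillation** — the two generation-1
branches carry distinct oscillators (6 h/2 mM at 4.5 mM vs 12 h/0.8 mM at
1 mM, random phases), linking features to classes; **age_biased** — mean
ATP = 1.0 + 0.8·(pole age) mM; **transmission** — 10% of cells are
producers (drawn independently of lineage) holding 4.5 mM; non-producers
relax toward 1.0 mM + 4.0 mM × Gaussian-kernel exposure (radius 1.2 µm)
summed over producers, creating steep local hills around isolated
producers, a long right tail, and spatially localized high-ATP cells.

What the simulator does **not** emulate: rod-shaped mechanics and
growth-induced flows (only centroid distances feed the analyses),
photobleaching or segmentation error beyond the placeholder mechanism, and
any real metabolic kinetics. Passing the recovery tests therefore shows
the statistical machinery discriminates the implanted generative
mechanisms at realistic colony sizes — not that real colonies satisfy the
generative assumptions.

Two off-diagonal entries of the regime × test matrix fire by construction
and are worth knowing about: (i) the HMM test fires under any temporally or
clonally structured regime (see above); (ii) the age test fires under the
transmission regime (~6/10 seeds), because the pole-age rule's geometry
makes age correlate with radial position, so any spatially structured
phenotype correlates with age — true of real rod-shaped colonies as well.
The discriminating signature for transmission is therefore the
*conjunction* used in the tests: localization significant AND dER/dNB
above 1 AND dED/dCR at 1, which fires in ≥9/10 transmission seeds and in
≤1/10 seeds of every other regime.

## Problem sizes and numerical defaults

The test suite and acceptance script run the randomization machinery at
reduced but statistically adequate sizes: 500 shuffle replicates for HMM
nulls (300 in the regime matrix), 1000–5000 permutations for localization,
2000–20,000 draws for skewness nulls, colonies of 6 generations × 3
founders (~190 leaves). Defaults in the API remain at the full sizes
(4000 shuffles, 10,000 permutations, 100,000 draws). All randomness flows
from explicit integer seeds through `numpy.random.SeedSequence` spawning;
every pipeline run is bit-reproducible given its seed. The pipeline reports
the four mechanism p-values uncorrected for multiple testing, and says so
in its report.
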