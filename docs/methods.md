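# Methods

## Pipeline definition

**Z-scoring.** Each node column is standardised to mean 0 and unit standard
deviation using the sample (n−1) denominator, applied identically everywhere
a standard deviation or correlation appears, so that the time mean of an edge
series times T/(T−1) equals the Pearson correlation of its nodes exactly.
Constant columns are an error naming the node. When a subject has multiple
scan runs, runs are concatenated first and z-scored once over the
concatenated series; per-run z-scoring before concatenation is a documented
alternative (`zscore_nodes` applied per run) that yields different output
whenever run means differ.

**Edges and RSS.** The edge index enumerates all unordered pairs i &lt; j in
lexicographic order (n(n−1)/2 pairs). RSS(t) is computed by default through
the power-sum identity 2·RSS(t)² = (Σ<sub>i</sub>z<sub>i</sub>(t)²)² −
Σ<sub>i</sub>z<sub>i</sub>(t)⁴, avoiding the timepoints × edges matrix
(~0.7 GB dense at 268 nodes × 2400 timepoints); `explicit_edges=True` forces
the direct enumeration, and the two paths are required to agree to 1e−10.
Subnetwork RSS uses only within-subset pairs. In the eFC matrix, constant
edge columns cannot be correlated and are excluded with a warning (their
rows are NaN) rather than crashing on degenerate input.

## Extrema conventions

* A trough is a **strict** local minimum: ties with a neighbour disqualify.
* The first and last timepoints are never troughs or peaks; the partial
  intervals before the first and after the last trough contribute no
  duration and no peak.
* The peak between two troughs is the maximum over the open interval;
  a tied maximum takes the earliest index.
* The percent test is boundary-inclusive — a trough exactly θ below its
  reference passes — implemented as `value ≤ (1−θ)·reference` with relative
  tolerance 1e−9 so the boundary survives floating-point rounding of
  (1−θ)·reference.
* `adjacent-sample` mode applies the test against the two neighbouring
  samples, one pass. `adjacent-peak` mode tests against the flanking peaks
  of the alternating extrema sequence and iteratively removes the violating
  trough of smallest relative depth (earliest index on ties), merging its
  segments, until all survivors pass; peaks are then recomputed between
  survivors. For the outermost troughs, the maxima of the boundary segments
  serve as flanking references even though endpoints are never reported as
  peaks. Exhaustive subset enumeration confirms the iterative rule returns a
  maximum-cardinality valid trough set on randomized series.
* Subjects with fewer than two surviving troughs under a strict criterion
  have undefined duration/height means; they are flagged and excluded from
  group fits with a logged count, never dropped silently.

Both percent modes are reported with their mode name because the underlying
definition ("preceding and successive critical values") admits either
reading; neither is silently preferred.

## Group model

Ordinary least squares of one outcome on intercept, a 0/1 group indicator
(alphabetically first level as reference), age in years and total brain
volume in ml. The group F is the extra-sum-of-squares statistic between the
full model and the reduced model dropping only the indicator, on (1, n−4)
df; it equals the squared t of the group coefficient, and that identity is
asserted in tests. Estimated marginal means are model predictions per group
with both covariates fixed at their grand means, with SEs from the
coefficient covariance of the prediction contrast; they are invariant to the
choice of reference level. Residual sums of squares at rounding-noise level
(≤ 1e−12 · Σy²) are treated as perfect fits with F = 0. One outcome is fitted
per model (durations and peak heights separately per criterion), with no
multiple-testing correction. Fitting is delegated to statsmodels OLS; a
from-scratch normal-equations solve exists only as an independent oracle in
the test suite.

## Synthetic cohort generator

The generator emulates parcellated resting-state BOLD at TR 0.72 s with a
hidden-Markov covariance-regime model:

* **Regime chain.** The first state is uniform; at every timepoint the chain
  stays with the group's stay probability, else jumps to a uniformly random
  *different* state. The realised path is recorded as ground truth.
* **States.** Default states are block-correlation matrices of graded
  amplitude: nodes split into n_states equal blocks, state k elevates the
  within-block correlation of block k to r (default 0.1, off-block 0) and
  scales the whole covariance by amplitude² with amplitudes running from 1.0
  to 2.5 across states. The high-amplitude state models the punctuated
  co-fluctuation events visible in empirical edge time series; entering and
  leaving it produces the rises and deep troughs of the RSS trace. Arbitrary
  user-supplied PSD covariances are accepted (validated per state).
* **Noise.** Per-node unit-variance AR(1) noise (φ default 0.97, matching
  the strong sample-to-sample correlation of bandpass-filtered BOLD at
  sub-second TR) is multiplied timepoint-wise by the current regime's
  covariance factor, so every sample is exactly N(0, Σ_state(t)) while
  regime changes take effect instantly. φ = 0 gives temporally independent
  draws.
* **Covariates.** Age and total brain volume are drawn per group from
  normals, independent of the series given group: means 27.9 / 29.5 years
  and 1215.13 / 1063.80 ml for the male-like (A) and female-like (B) groups,
  SDs 2.4 / 3.5 years and 110 / 100 ml — the volume SDs follow the typical
  within-sex spread of total brain volume rather than a tighter value, so
  that volume overlaps between groups and covariate adjustment remains
  well-conditioned despite the large mean offset.

**Why amplitude-graded states and autocorrelated noise.** With temporally
independent samples, or with equal-amplitude correlation-rotation states, the
RSS values are exchangeable in time with a state-independent marginal, so the
regime path — and therefore a group difference in switching rate — is
invisible to any RSS statistic. Amplitude-graded states give the regime path
an RSS signature; temporal smoothness keeps incidental noise minima from
drowning it. Under the defaults, slower switching yields monotonically longer
mean trough durations (verified over stay probabilities 0.90–0.99), which is
the generator's intended ground-truth direction of effect.

**What the generator does not emulate:** hemodynamic response shape, scanner
noise and drift, spatially realistic parcel geometry or atlas structure,
motion artifacts, spectral content beyond AR(1), family structure between
subjects, or any claim about the mechanism behind real group differences.
Passing tests show the pipeline recovers a known switching-rate contrast
under this model; they do not certify findings on real data.

## Problem sizes and runtime choices

Unit tests run at 10–60 nodes and a few hundred timepoints. The end-to-end
recovery check uses the full study-scale conditions — 30 subjects per group,
100 nodes, 1200 timepoints, stay probabilities 0.97 vs 0.93, 20 replicate
cohorts with a fixed seed bank — and requires the slow-switching group to
show the longer adjusted mean duration with p &lt; 0.05 in at least 80% of
cohorts. The null-calibration check runs 500 replicate cohorts at a reduced
scale (20 nodes, 300 timepoints, 10 + 10 subjects) chosen so the sweep stays
cheap while the ANCOVA has ample residual df; its rejection rate must fall in
the exact binomial 95% band around α = 0.05. Oracle comparisons cap
exhaustive enumeration at 12 base troughs (4096 subsets).

## Known limitations

* The adjacent-peak pruning's equivalence to the maximum-cardinality valid
  subset is established empirically on randomized series, not proven.
* Mean trough duration is not mathematically guaranteed to be monotone in θ
  (removing an outermost trough can shorten the spanned interval); it is
  monotone in practice and asserted on the tested conditions.
* The ANCOVA ignores dependence between subjects (e.g., family structure),
  as does the analysis it implements.
* RSS traces loaded from two-column TSV lose their edge count (`n_edges = 0`)
  since only the amplitude values are stored.
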