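# Methods

This note records the modelling assumptions, parameter defaults and
numerical choices behind `rapbeef`, and what the test suite does and does
not establish.

## Indicator engine

Each of the 20 indicators (11 farm-level, 9 slaughterhouse-level) is a
formula over named yearly measurements plus a 6-bin ordinal scale. Three
published conventions needed interpretation:

- **Bin contiguity.** The published scales print bins with small gaps
  (e.g. "0%–7%" then "8%–15%"). We implement contiguous half-open
  intervals `[lower_k, lower_{k+1})` built from the printed lower edges,
  with the top interval closed upward. This removes unmappable gaps while
  agreeing with every printed bin on printed data; a value exactly at a
  lower breakpoint belongs to that bin.
- **Clamping.** Values below the lowest printed edge or above the highest
  map to the adjacent extreme bin. The source data uses this convention
  implicitly (an added-value observation far below the lowest edge is
  scored 1; a self-sufficiency of 519% is scored 6).
- **Polarity.** The bin index itself encodes polarity: 6 is the best
  condition for every indicator, so cost and infection scales run
  descending along the value axis (`orientation: descending`).

Two formula-level choices:

- The fuel-cost indicators (farm and slaughterhouse transport) are
  printed as distance ÷ (litres per km) × price, which is not a currency.
  We default to distance ÷ fuel efficiency (km per litre) × price per
  litre, the only reading that yields USD; `pl3_as_printed=True` keeps the
  literal division for reproduction.
- The farm electricity indicator is computed exactly as printed
  (kWh/head/month × herd size × tariff, with no ×12), although the scale
  is described as yearly; the water and slaughterhouse utility formulas do
  print a ×12 and get one.

Gender-equality scales top out at the printed "50%" category and clamp
above it; no symmetric penalty is applied beyond parity because the source
defines none.

The shipped evaluation table carries a per-cell `consistent` flag: a cell
is consistent when its printed 1–6 score equals what the published bins
assign to its printed actual value. 46 of 60 cells are consistent; the
rest (the gender-equality and education rows, the reversed infection rows,
and three isolated cells) contradict their own scales, and no rule in the
source resolves which is authoritative, so tests and acceptance checks
assert only consistent cells. Mixed decimal conventions (decimal-comma
vs decimal-point currency strings) are handled by an explicit per-file
locale flag with an `auto` heuristic for mixed tables; the packaged
fixture stores already-normalized numbers.

Status bands partition [0, 100] as 0–25 / 26–50 / 51–75 / 76–100 with
interior boundaries attached to the lower band, which reproduces both
printed band assignments (56.14 moderately sustainable, 47.05 fairly
unsustainable).

## Anchored ordination

**Reference profiles.** GOOD (all 6) and BAD (all 1) define the index
axis. One complementary anchor pair — first half of the attributes best /
rest worst, and its complement, laid out over attributes in sorted-label
order so the reference set is independent of column order — pins the
second axis. More anchor pairs are configurable, but each extra pair adds
hypercube corners whose mutual distances are not 2-D-embeddable: with two
pairs the farm-dimension S-Stress on the packaged evaluation data rises to
0.33, past the 0.25 acceptability line, while one pair keeps it ≤ 0.10.
One pair is therefore the default.

**Embedding.** Metric SMACOF on Euclidean distances between worst=0 /
best=100 normalized rows: iterative majorization via the Guttman
transform, which guarantees a monotone non-increasing raw-stress trace
(kept on the result for verification). Restarts: one classical-scaling
(Torgerson) start plus `n_restarts − 1 = 3` random starts. Each random
start draws row i's coordinates from `default_rng([seed, restart,
crc32(row_label)])`, a counter-based scheme that makes the whole fit
reproducible from one integer *and* equivariant under row permutations, so
indices and leverage do not depend on entity ordering. The winner across
restarts is the configuration with the lowest raw stress. Convergence is
a relative raw-stress change below 1e−9 within 1000 iterations (the
packaged matrices need at most a few hundred); hitting the cap sets a
`converged=False` flag rather than raising.

**Fit statistics.** S is the ALSCAL-style S-Stress
√(Σ(d²−δ²)²/Σδ⁴) by default (`stress_formula="stress1"` switches to
Kruskal's stress-1); R² is the squared Pearson correlation between input
and configuration distances over all row pairs, the conventional reading
where the source defines none. Because the restart winner is chosen by
raw stress, S-Stress on the winner can exceed another restart's S-Stress
by ~1e−5; the min-over-restarts guarantee applies to raw stress.

**Index.** After rigid rotation placing BAD→GOOD along +x, index(e) =
100·(x_e − x_BAD)/(x_GOOD − x_BAD), clipped to [0, 100] so the status
bands always apply; the reference entries themselves are pinned to exactly
100 and 0 against float rounding. If GOOD and BAD ordinate at the same
point the run aborts with a degenerate-configuration error rather than
returning arbitrary output.

**Multidimension index.** The joint ordination over all attributes is the
default "multi" mode (the published multidimension values are not the mean
of the per-dimension values, which indicates joint ordination);
`multidimension_average` provides the averaging alternative.

The published per-entity index values themselves are not reproduction
targets: they depend on an unspecified ALSCAL implementation, anchor
scheme and run configuration. What the package reproduces is the
method's contract — pinned references, oracle-equivalent embeddings where
an exact 2-D solution exists, qualitative orderings on the packaged data,
and S-Stress within the acceptability line.

## Leverage

RMS_j is computed over real entities only (anchors are references, not
observations) within the dimension under analysis, re-ordinating with
identical configuration and seed after dropping attribute j (anchors are
rebuilt for the reduced attribute set). The profile is sorted descending
with stable ties in original column order. Absolute index units are used
(the source does not state a percentage-change convention). Attributes
with identical score columns are computationally indistinguishable under
drop-one analysis and receive exactly equal RMS. Dimensions with fewer
than three attributes are rejected, since a drop would leave a
non-ordinatable single attribute.

## Monte Carlo stability

Default noise is uniform on ±0.25 score units per cell — half a scale
step, the smallest perturbation consistent with scoring uncertainty while
keeping scores near their assigned bins — applied to real entities only
(references are definitional) and clipped back into [1, 6]; Gaussian noise
with sd = half-width is available. 25 replicates by default. The central
value is the per-entity median, robust to occasional
reflection/rotation outliers of individual replicates. The <5-point
sufficiency and <1-point tolerability thresholds are reported as flags,
never enforced.

## Delphi analysis

Tie-corrected Kendall's W from mid-ranks, χ² = m(n−1)W on n−1 df.
Consensus bands: W > 0.7 strong, 0.5 ≤ W ≤ 0.7 moderate, W < 0.3 weak;
the unlabelled (0.3, 0.5) range is reported `indeterminate` rather than
silently extended into a neighbour. Round stopping applies W ≥ 0.5 (the
boundary is made decidable by using ≥). Per-item means are rounded
half-up to one decimal, matching the published convention (3.67 → 3.7).
An all-constant matrix has a zero denominator; W is reported NaN with an
indeterminate consensus flag. The packaged round-2 matrix yields
W = 0.7508 (χ² = 27.03, df = 12): the statistics printed alongside it
(W = 0.795, df = 14) imply 15 ranked items, two more than the 13 printed
columns, and are therefore used only to check the χ² identity, not as a
reproduction target. Note that duplicating a single rater can lower W —
a dissenting voice counted twice weakens concordance — so no
monotonicity in panel composition is claimed; duplicating the entire
(tie-free) panel leaves W unchanged.

## Synthetic generator

Emulates scored survey matrices: latent sustainability `u_e ~ Uniform[0,1]`
per entity (or supplied explicitly), expected score `1 + 5 u_e` on every
attribute, i.i.d. Gaussian noise (sd 0.5 score units by default — about
the cell-level disagreement seen between duplicate raters on 5–6-point
instruments), round-half-up, clip to {1,…,6}. It reproduces the latent
one-factor structure the index presumes; it does not emulate
multidimensional trait structure, systematically missing cells,
rater-specific bias, or correlated attribute noise, so passing
parameter-recovery tests (Spearman ≥ 0.9 between latent order and index at
n = 50 entities × 8 attributes) demonstrates internal consistency of the
pipeline, not robustness to those real-data features.

## Problem sizes and determinism

The packaged analyses are small by construction — 3 entities × ≤ 11
attributes plus references, 25 Monte Carlo replicates, a 50-entity
synthetic benchmark — so the full test suite and the acceptance script
each run in well under a minute. All randomness flows from one integer
seed through counter-based `default_rng` streams (restart k, replicate r,
row label), so identical inputs and seed give bit-identical results, and
no global random state is touched.
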