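# Methods

This note records the statistical procedures `standassoc` implements, the
choices made where the literature leaves details open, and what the
synthetic-data validation does and does not establish.

## Data model and quadrat sampling

A stem map is a complete census of trees with DBH ≥ 5 cm in a rectangular
plot, with continuous coordinates in metres from the south-west corner.
Development stages are a pure function of DBH with left-closed/right-open
intervals and configurable breaks (defaults 5/10/25 cm). The plot is tiled
into square quadrats from the origin; the survey design this package
defaults to — 140 × 70 m with 14 m quadrats — gives N = 50 sampling units.
Quadrat membership is half-open, `[k·s, (k+1)·s)`, with points exactly on
the far east/north plot edge clamped into the last cell; the convention is
ours, since boundary assignment is rarely stated in survey protocols, and
it guarantees every in-plot tree belongs to exactly one quadrat. In strict
mode (the default) plot sides must divide evenly by the quadrat size — a
leftover margin would silently exclude trees from quadrat statistics.

Species with zero occurrences after a stage filter are kept as all-zero
matrix rows so that pair enumeration is identical across stages; degenerate
pairs are flagged downstream rather than silently dropped.

## Importance values

RD, RF and Rd divide each species' density, frequency and dominance by the
corresponding stand totals and therefore each sum to 100 %. Some survey
manuals print variant denominators for RD (raw count over total density)
and RF (frequency over the species count); those forms are dimensionally
inconsistent and cannot sum to 100 %, so the standard forms are the
default, with the printed variants behind `printed_variants=True` for
comparability. Dominance is per-stem basal area π(DBH/200)² summed per
species; each stage table self-normalises over that stage's totals.
Dominant species are selected by IV rank with ties broken by density and
then label, so the selection is deterministic.

## Pairwise association

The χ² statistic uses the Yates continuity correction with the correction
term clamped at zero (`max(|ad − bc| − N/2, 0)`), the standard textbook
form — the unclamped expression would manufacture a positive statistic for
tables already closer to independence than half a count. The statistic is
undefined (NaN) when any margin is zero, since the denominator vanishes;
such pairs are excluded from summary percentages. Band edges 3.841 and
6.635 are computed at runtime as χ²(df = 1) quantiles rather than
hard-coded.

The statistic is reported signed, with the sign of ad − bc, so positive
and negative associations of equal strength are distinguishable in one
number; the unsigned magnitude is available as `chi2_magnitude`.

The AC coefficient's piecewise denominator — (a+b)(b+d) when ad ≥ bc,
(a+b)(a+c) when ad < bc and d ≥ a, (b+d)(c+d) otherwise — is evaluated
exactly as published. One consequence worth knowing: the first branch's
denominator is not invariant under exchanging which species is called "A"
(b and c swap), so AC genuinely depends on the role assignment. To make
results well defined for an *unordered* pair, `pair_association` and
`pairwise_analysis` canonicalise roles by assigning the lexicographically
smaller label to A. χ² and the five-band category are role-symmetric
regardless. Equality ad = bc is routed to the first branch, consistent
with its "≥" condition.

Summary shares count direction by the sign of ad − bc (a pair is "no
association" only at exact equality), matching how semi-matrix counts of
positive/negative pairs are conventionally tallied; the five-band
significance categories are reported separately per pair.

## Overall association (variance ratio)

S²_T and δ²ᵢ use population (1/N) normalisation. The per-species variance
subtracts the *species* mean tᵢ (the only reading under which δ²ᵢ is a
variance; printed versions of the formula sometimes carry a stray
quadrat subscript). The test statistic is W = N·V with df = N, compared
against the central 90 % χ² band — quantiles at cumulative 0.05 and 0.95;
note that tables often label these by their upper-tail areas (0.95, 0.05).
Direction comes from V vs 1, significance from W leaving the band.
Calibration: over 500 independent-Bernoulli 11 × 50 presence matrices the
mean V is within 1 ± 0.05 and W leaves the band in 10 ± 3 % of replicates
(test-suite property).

## Uniform angle index

For each reference tree the four nearest neighbours (Euclidean distance,
ties broken by tree id for reproducibility; coincident coordinates are a
data error) define four azimuths; the index evaluates the circular gaps
between the azimuth-sorted directions — the standard construction — and
counts gaps strictly smaller than α₀ = 72°. Per-tree values therefore lie
in {0, 0.25, 0.5, 0.75, 1}. Edge correction restricts references to the
reduced window (plot inset by the 5 m buffer) while buffer trees remain
eligible neighbours.

For per-species summaries the references are conspecific but the
neighbours are by default *any* species — the index then describes the
stand structure around each population; `conspecific_neighbors=True`
switches to the population's own pattern. Note that with a 5 m buffer a
small fraction of fourth-nearest neighbours would in truth lie beyond the
plot boundary; the substitution of farther in-plot neighbours biases W̄
slightly downward (~0.49 observed for Poisson stands at the survey
density, against a band midpoint of 0.496). This is inherent to the
buffer method, and the simulated Poisson mean remains well inside the
random band (0.475, 0.517).

## Synthetic stands

The generator's default community emulates the surveyed stand: 0.98 ha,
~888 trees/ha, eleven dominant species with the observed density ranking
(190.8 down to 18.4 trees/ha) plus a tail of twelve minor species, and a
stage mixture of (0.413, 0.400, 0.187) — a reverse-J diameter structure
with the observed ~41 % juvenile share; the medium/large split continues
the declining trend. Within stages DBH follows truncated exponentials
(scales 3/7/12 cm, cap 90 cm). Juvenile-heavy species are Thomas-clustered
(Gaussian offspring; chosen over Matérn discs for simpler density math),
the rest Poisson. Offspring displaced outside the plot are discarded, and
the community generator inflates the offspring mean by the analytic
per-axis edge-retention factor so realised counts match the intended
densities.

Pairwise association is induced through habitat patches: a random half of
a coarse grid's cells forms the patch; each point of an associated species
is, with probability `strength`, relocated uniformly into the patch
(positive pairs share it, negative pairs take patch vs complement).
Coverage is fixed at ~50 % and `strength` is a mixture probability rather
than a coverage fraction: this interpolates cleanly from exact
independence at 0 to full constraint at 1, whereas tying coverage to
strength would shrink the complement — and with it the negative-association
geometry — exactly when the association should be strongest. Per-species
random substreams are keyed by (seed, label), so adding a species never
perturbs existing ones and output is byte-reproducible.

What the generator does *not* emulate: inhomogeneous habitat gradients,
DBH-dependent spatial interaction (e.g. larger trees more regular),
species-specific diameter distributions beyond the stage mixture, and
higher-order (3+ species) association. Passing recovery tests therefore
show the estimators detect planted pairwise/pattern structure at field
scale, not that they are robust to every real-data pathology.

## Problem sizes and tolerances

Exhaustive 2×2 checks enumerate all tables with N ≤ 12 (1 815 tables)
against scipy's corrected χ² and an exact-rational AC evaluation.
Independence calibration uses 500 replicates; Poisson uniform-angle
validation uses 50-replicate means and 100-replicate classification rates;
association-sign recovery uses 200 seeded two-species stands per sign at
strength 0.9. These sizes give Monte-Carlo standard errors comfortably
below the tolerances asserted (e.g. ±0.05 on mean V, where the observed
spread is ±0.015). Analytic quantile comparisons are asserted to 10⁻³.

## Known limitations

* The IV dispersion ("± value") sometimes printed alongside importance
  values in survey tables has no standard definition and is not computed.
* No multiple-testing correction is applied across the C(k, 2) pairwise
  tests; with 55 pairs at P < 0.05, ~3 false positives are expected under
  global independence. This matches standard practice for semi-matrix
  presentations but should temper interpretation.
* The variance-ratio test's χ² reference is asymptotic; for very sparse
  matrices (many near-constant species) the band is approximate.
* `simulate_inhibition` is simple sequential inhibition, not a stationary
  Gibbs hard-core process; densities near the packing limit fail rather
  than converge.
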