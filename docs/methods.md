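# Methods

## The pattern class

A structure is reduced to a labeled point cloud: one point per standard
amino-acid residue at its Cα coordinate and, when DNA is included, one point
per nucleotide at its N1 coordinate.  Formally a data object is
d = {v₁, …, v_l} with vᵢ = (aᵢ, cᵢ), aᵢ a label from the alphabet I (the 20
three-letter amino-acid codes and/or the bases A/C/G/T) and cᵢ ∈ ℝ³ in Å.

For a pattern X = {a₁, …, a_k} ⊆ I:

* **Support** — S(X) = |N(X)| / |D|, where N(X) is the set of data objects
  containing at least one occurrence of every label of X.
* **Per-structure radius** — R_g(X) is the minimum, over all ways of picking
  one occurrence of each label inside structure g, of the radius of the
  smallest enclosing ball (MEB) of the picked points.
* **Cohesive radius** — R(X) = (Σ_{g ∈ N(X)} R_g(X)) / |N(X)|.  The average
  runs over the whole support set, including structures whose best ball is
  large; a capped variant was considered and rejected because the plain
  average is the quantity the thresholds are defined on.

A pattern is reported when S(X) ≥ min_support and R(X) ≤ max_radius.  Both
comparisons are inclusive: boundary patterns are reported, which is the
deterministic reading of "passing a cut-off".  Patterns are sets — repeated
labels are not modelled.

## Mining

Enumeration is level-wise (Apriori): (k+1)-candidates are joins of frequent
k-patterns, pruned when any k-subset is infrequent.  Support is anti-monotone,
so this pruning is exact.  The cohesive radius is *not* anti-monotone (it is
an average over a shrinking support set), so by default it is applied only as
a report filter.  An opt-in lossy variant additionally stops extending
patterns whose radius exceeds `radius_prune_slack × max_radius` (slack 2.0);
it is off by default and the test suite demonstrates it changes nothing on
easy fixtures.

Singleton patterns (radius identically 0) are computed for candidate
generation but reported only when `report_min_size` is lowered to 1; the
interesting patterns start at pairs.

Default thresholds: support 0.60 and radius 4.5 Å in protein mode (4.5 Å is
the conventional Cα–Cα contact distance); support 0.70 and radius 7.0 Å in
protein–DNA complex mode, where a pattern must bridge two macromolecules and
is only reported if it contains at least one base and one amino acid.
Maximum pattern size defaults to 4.

## Geometry

The MEB is computed exactly with Welzl's algorithm (move-to-front over a
deterministically shuffled order; fixed internal seed so results and run
times are reproducible).  Degenerate boundary sets (collinear triples,
coplanar quadruples) fall back to direct support-set enumeration.  A
containment tolerance of 1e-10·(1+r) absorbs floating-point noise.

The best-match search is exact, never a heuristic:

* When the product of per-label occurrence counts is at most 5 000, all
  combinations are enumerated with vectorised closed-form MEB radii
  (half-diameter for pairs; for triples the circumradius via Heron's formula
  on squared side lengths, or the half-longest-side ball for right/obtuse
  and degenerate triangles; for quadruples support-subset enumeration plus
  the batched circumsphere).  All pair and triple patterns evaluated within
  one structure are fused into single vectorised computations over the
  structure's cached pairwise-distance matrix.
* Above that limit an anchor-based branch-and-bound runs: anchors are the
  occurrences of the rarest pattern label (ties broken lexicographically);
  for each anchor, half the largest anchor-to-nearest-occurrence distance
  over the other labels lower-bounds the achievable radius; anchors are
  visited in bound order, pruned against the incumbent, and refined by
  enumerating occurrences within twice the incumbent radius of the anchor
  (any ball through the anchor with a smaller radius lies inside that
  range).  This search provably returns the global optimum and is tested
  against exhaustive enumeration.

Label permutation leaves coordinates untouched, so permuted copies of a
structure share its cached distance matrix — this is what makes the
ten-round background affordable.

## Significance

Common labels produce small radii by chance, so each pattern is compared to
a background in which every structure's labels are shuffled over its own
coordinates (within molecule kind in complex mode: amino acids never swap
with bases).  Composition, and therefore every support value, is preserved
exactly — asserted in tests, not assumed.  Ten permutation rounds are the
default; round seeds derive from the master seed through a fixed counter
scheme so rounds are independent and reproducible.

The ten background cohesive radii are summarised by their mean and unbiased
(n−1) standard deviation, and the p-value is the lower-tail normal
probability Φ((R_obs − μ)/σ) — one-sided because only excess cohesion is of
interest.  A degenerate background (σ = 0) yields p = 1 at or above the mean
and p = 0 below it.  Significance is declared at α = 0.01 with Bonferroni
correction over the patterns tested in the run (all sizes pooled into one
family; a per-size-class option was considered and not taken — pooling is
the conservative default).

With only ten background values the normal σ is itself noisy, so extreme
p-values should be read as orders of magnitude, not precise probabilities;
the calibration tests check the operating characteristics (power on planted
motifs, false-positive fraction on exchangeable nulls) rather than exact
tail areas.

## Association analyses

* **Domain enrichment** — residue-level hypergeometric overlap between the
  distinct residues chosen by a pattern's best matches (set semantics: a
  residue inside overlapping domains counts once) and the residues covered
  by any annotated domain interval, over all protein residues of annotated
  structures.  Both tails are reported (enrichment and the "avoids domains"
  depletion direction), Bonferroni-corrected over patterns.
* **GO enrichment** — structure-level: because most patterns occur almost
  everywhere, a structure counts as carrying the pattern only when its
  best-match radius is *strictly* below 3 Å.  Terms annotated to fewer than
  10 structures are skipped.  Population = structures with any GO
  annotation.  Multiple tight matches within one structure count once
  (binary per structure).
* **OGT screen** — Spearman correlation (average ranks for ties; large-sample
  t approximation for p) between per-structure best-match radii and the
  source organism's optimal growth temperature.  Rows with OGT exactly
  37.0 °C are dropped first — that temperature is dominated by pathogens
  whose composition would bias the trend; the filter removes exact equality
  only.  Positive ρ (looser at high T) is read as low-temperature relevance,
  negative ρ as high-temperature relevance; direction is only assigned to
  Bonferroni-significant patterns.  Fewer than 5 usable pairs yields NA.
* **Sequence separation** — the mean |Δ seq_pos| over same-chain pairs of the
  best-match residues, classified short-range below 6, long-range above 10,
  intermediate between; any cross-chain pair makes the match cross-chain.
  Mean aggregation is the default; max-pairwise is available because the
  field's "distance along the chain" is not uniquely defined for k > 2.

## Synthetic data

The generator emulates the statistical setting the permutation null lives
in — labels exchangeable given coordinates — not protein physics.  Points
are uniform in a box (default 40 Å for 120 points) with a 3.8 Å minimum
separation, the Cα–Cα virtual-bond scale, so radii are on the same Å scale
as real chains and the 4.5 Å threshold is meaningful: random triplet best
matches at this density land well above it while planted motifs sit below.
Defaults (50 structures × 120 points, uniform composition over the 20 amino
acids) are the planted-motif benchmark conditions.

Planting moves the k points nearest a random anchor into a ball of the
requested radius and relabels them, guaranteeing a best-match radius at or
below the plant radius; the minimum-separation rule is waived inside the
motif, which models a contact site.  The OGT fixture draws temperatures
uniform on [15, 95] °C excluding a band around 37 °C (so the pathogen filter
removes nothing by construction) and plants the effect pattern with a radius
varying linearly with temperature plus Gaussian noise (σ = 0.25 Å).

What passing tests on these fixtures does **not** show: behaviour under
chain connectivity, secondary structure, compositional heterogeneity across
structures, or redundancy between structures — real-data effects outside
the generator's model.

## Numerical choices and problem sizes

* Tolerances: 1e-9 absolute for radius comparisons against oracles, 1e-10
  relative containment slack inside Welzl, 1e-12 for closed-form statistics.
* Determinism: every stochastic component (generator, permutation rounds,
  Welzl shuffle) takes an explicit seed; derived seeds come from
  `numpy.random.SeedSequence` spawn keys.
* Test-scale choices: oracle-equivalence suites run at up to 60 points and
  pattern size 4 (where exhaustive enumeration is itself affordable);
  planted-motif calibration runs 20 independent generations of the
  50 × 120 benchmark with 10 permutations each, and the growth-temperature
  screen 20 generations of 40 structures × 80 points.  These sizes were
  chosen so brute-force oracles remain the arbiter while the statistical
  claims are tested at the stated benchmark conditions.

## Known limitations

* The permutation background uses 10 rounds and a normal fit; rank-based
  p-values and larger permutation counts are out of scope.
* GO terms are treated as flat labels (no ancestor closure).
* Insertion codes are ignored (author residue number only); duplicate
  (chain, position) residues keep the first occurrence.
* Nonstandard residues (e.g. MSE) are skipped, not remapped.
* No sequence-redundancy reduction: identical chains count as independent
  data objects, which inflates support on redundant inputs.
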