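# Methods

This note records the model as implemented, the parameter defaults and
why they hold, the numerical conventions, and what the synthetic data
does and does not establish.

## Structure model

A structure is an ordered chain of residues; each residue carries its
α-carbon position and its heavy atoms (hydrogens discarded at parse
time).  Author numbering, insertion codes and chain gaps are collapsed
into a dense 0-based index at parse time, and *sequence adjacency means
adjacent internal indices everywhere* — a missing residue in the
crystal therefore joins its neighbors.  Alternate conformations keep
the highest-occupancy atom (ties: first in file); only the first model
of a multi-model file is read; amino-acid HETATM residues (e.g. MSE)
are mapped to their parent type; other heteroatoms are ignored.

## The aa-sphere

Residue *r* belongs to the sphere of center *c* iff any heavy atom of
*r* lies within the radius of **c's α-carbon** (closed ball, so the
boundary rule is deterministic).  Measuring from the center's α-carbon
rather than from all of the center's atoms is a fixed convention; the
membership test itself is directional and no symmetry is claimed or
relied upon.  Default radius: 9 Å — large enough that a sphere sees
one-to-two turns of helix plus spatial contacts, small enough that the
O(n²) neighborhood alignments stay cheap.  Membership is computed with
a k-d tree over all heavy atoms, and verified in the tests against an
exhaustive distance scan.

## Sphere similarity

Steps 1–3 build the spherical alignment (gapless backbone seed, Kabsch
superposition, zero-gap NW on the neighborhoods).  Numerical
conventions:

* Kabsch uses the SVD form with the reflection excluded
  (det R = +1); coincident or single-point inputs fall back to the
  identity rotation plus a pure translation.
* The match score is `1/(1 + (d/d_s)²)` with d_s = 2 Å.  The constant
  scale (rather than a length-dependent one) suits objects much
  smaller than whole chains; 2 Å sits below the 3.5–5 Å scales used
  for whole-model scores because sphere superpositions are tight.
* Neighborhood NW uses zero gap cost.  Match scores are positive and
  bounded by 1, so zero-cost gaps reduce NW to a maximum-weight
  order-preserving matching, which always pairs min(|x|, |y|)
  residues; the alignment length therefore always equals
  max₍ₓ₎₍ᵧ₎ = 1 + Σ_c min(q_c), and SM-raw ∈ (0, 1] with
  SM-raw(x, x) = 1 exactly.
* NW traceback prefers match over advancing in the first sequence over
  advancing in the second — determinism, not science.

The quantity factor is `f = Π_c (1 + min q_c)/(1 + max q_c)`.  The
requirements are: f = 1 iff all four counts agree, strictly decreasing
as any category diverges, and a real penalty for the subset-sphere case
(a sphere minus some members would otherwise look like a perfect match
against its parent).  The product-of-ratios form is the simplest map
with those properties; it lives in one function
(`sphere_similarity.quantity_factor`) precisely so it can be swapped,
and the final combination `SM-score = ECDF · f` is likewise a product
by choice.

## Calibration

SM-raw values that occur by chance depend strongly on sphere sizes, so
raw values are ranked within buckets of downsampled
quantity-characteristic pairs: neighborhoods halved (floor), backbone
counts 0 and 1 merged (both → 1), every component capped at 7 — in
that order, applied literally.  Note the halving makes the map
deliberately *not* idempotent (5 → 2, but 2 → 1 if reapplied); buckets
are bins, not fixed points.  The (x, y) order of the bucket key is
preserved because the full measure is asymmetric.

The table is built from all ordered cross-protein sphere pairs of a
calibration set, optionally thinned globally, with a per-bucket
reservoir cap (default 50 000) under a fixed seed.  ECDF evaluation is
the plain right-continuous empirical fraction P(X ≤ v), with a 1e-9
tie tolerance so that floating-point summation order cannot flip a
step, and 1 at or above the bucket maximum.  Empty buckets fall back
to the nearest populated bucket by L1 distance over the 8 key
components (ties: lexicographically smallest key).  Tables serialize
to versioned JSON with hex floats, so a round trip is bit-exact and
rebuilds are byte-identical.

## Global alignment and TM evaluation

The global score matrix is `log max(SM-score, 1e-8)`; the floor keeps
the dynamic programming finite when the ECDF bottoms out at 0.  The gap
penalty is `log 0.75` per gap position (linear gap model, no opening
cost): in log-probability space this demands that matched spheres be
distinctly more significant than chance before they pay for a gap.

The TM evaluation uses the standard scale `d₀(L_T) = 1.24(L_T − 15)^⅓
− 1.8`, clamped below at 0.5 Å, with L_T the query length — an
external convention adopted as-is.  The superposition search is a
documented deterministic variant of the usual heuristic: seed windows
of the aligned pairs at lengths L_A, L_A/2, L_A/4 (minimum 4), window
starts stepped by half the window; Kabsch on each seed; then for each
distance cutoff from d₀ up to 8 Å in 1 Å steps, iterate {keep pairs
under the cutoff, re-superpose} to a fixed point (minimum 3 pairs);
every candidate is scored on *all* pairs and the maximum wins (first
encountered on ties).  Different window/cutoff micro-schedules shift
scores in the third decimal; nothing downstream depends on that level.

`d(x, y) = 1 − TM` is asymmetric through L_T; both directions of a
pair share one sphere alignment (the dominant cost), so the second
direction is nearly free (`SProtMeasure.distance_pair`).

Iterative TM refinement alternates {NW with match score
`1/(1 + (d/d₀)²)`, matches beyond 3 d₀ forbidden (−∞), zero gap cost}
with the TM evaluation, stops when the score improves by less than
1e-6 or after 20 iterations, and returns the best-so-far, making the
score sequence non-decreasing by construction.

## Access method

The index stores both directed distances pivot↔object because the
measure is asymmetric; the lower bound on d(q, o) through pivot p is
`max(d(q,p) − d(o,p), d(p,o) − d(p,q), 0)` — exactly the two directed
triangle bounds available without symmetry, reducing to
|d(q,p) − d(p,o)| in the symmetric case.  On a true metric space the
search with v = r = 0 is exact (tested against a sequential scan).

Because the measure also violates the triangle inequality on a small
fraction of triplets, a single overvalued bound corrupts an estimation
(probability 1 − (1 − p)ⁿ over n pivots), so two tolerances make the
search robust: elimination requires the estimation to exceed the
threshold θ by more than v percent, and after the candidate set
empties, eliminated objects with the smallest estimations are
re-processed until the result set has been stable for r consecutive
iterations.  Defaults v = 2.5%, r = 128 at the CLI; the index-fidelity
check uses r = 16, scaled with its 100-object database (r counts
confirmation iterations, and 128 of them would re-scan a database of
this size outright).  Pivots are protected from elimination for the
first ⌈#pivots/2⌉ iterations (the fraction is a package default).
Other determinism rules: the first selected pivot is the one with the
lowest id; all selection and result ties break by object id; θ is +∞
until R holds k objects.

The RBQ(0.7, 0.15)(w) modifier is the rational quadratic Bézier curve
through (0,0), (0.7, 0.15), (1,1) with middle weight w, evaluated by
monotone bisection on the curve parameter (60 halvings, well past
1e-9); w = 0 degenerates to the identity.  It is applied consistently
to stored and query-time distances, so θ and v operate in modified
space.  Pivot selection is one object per family label when labels
exist, otherwise seeded max-min farthest-point sampling.

## Synthetic data

The generator emulates: CA-resolution chain geometry (consecutive
CA–CA 3.8 ± 0.05 Å), secondary-structure segments (ideal helix:
radius 2.3 Å, rise 1.5 Å, 100°/residue; extended strand zigzag) joined
by seeded turns into family-specific layouts, one synthetic side-chain
centroid per residue 1.5–2.5 Å off the CA (so heavy-atom membership
genuinely differs from a CA-only test), within-family divergence by
Gaussian coordinate noise applied *before* a random rigid motion
(σ reads as structural noise), and a family < superfamily < fold label
hierarchy.  Pure single-segment ideal templates are deliberately
avoided: they make every local neighborhood generic, which the
calibrated score correctly treats as chance-level similarity — real
folds are heterogeneous, and the segmented layouts model that.

It does not emulate real side chains, Ramachandran statistics,
sequence–structure correlation, or domain boundaries.  Green tests on
these fixtures establish that the machinery is correct and internally
consistent (invariances, oracle equalities, separation of generated
families); they do not certify classification accuracy on real
protein databases.

## Problem sizes

The standard benchmark is 3 families × 4 members (σ = 0.5 Å, chains of
30–45 residues); the index-fidelity experiment uses 10 families × 10
members with one pivot per family and three queries; calibration uses
3 families × 2 members with 20 000 sampled sphere pairs.  These sizes
keep the full pipeline at desk scale while leaving the family
separation far from degenerate.

## Known limitations

* The ECDF needs a reasonably diverse calibration set; calibrating on
  a single homogeneous fold family collapses the score distributions
  and the global alignment loses contrast.
* The quantity-factor form and the ECDF·f combination are package
  choices satisfying the stated constraints, not uniquely determined.
* The distance is approximate under the index by design; exactness is
  only guaranteed for true metrics with v = r = 0.
* mmCIF input, multi-chain queries and sequence-order-independent
  alignment are out of scope.
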