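# Methods

## Terminology model

A terminology is a rooted DAG of classes. Each class has `parents` (direct
is-a superclasses) and `references` — the classes appearing on the right-hand
side of its axiomatic definition, i.e. fillers of existential restrictions,
possibly nested inside intersections and role groups. Two loaders exist: a
line-diffable native JSON format (`format_version: 1`, order-insensitive,
round-trip exact) and a reader for the restricted OWL functional-syntax
subset that matches SNOMED CT's official OWL-EL conversion (`SubClassOf` /
`EquivalentClasses` over named classes, `ObjectIntersectionOf`,
`ObjectSomeValuesFrom`; everything else is ignored and counted). The OWL
reader requires exactly one parentless class, which becomes the root.

A *sub-hierarchy* is identified by a direct child of the root; every non-root
class is assigned to exactly one. In a general DAG a class can sit under
several top-level classes; the assignment then takes the lexicographically
smallest sub-hierarchy id and validation emits a warning. This situation does
not arise in SNOMED-shaped inputs (its top hierarchies are disjoint), but the
tie-break keeps the generic loader deterministic and auditable. The root
belongs to no sub-hierarchy and is excluded from all counts and frequencies:
the published per-hierarchy tables partition concepts below the root, and the
root itself is structural.

## Extraction closure

`extract_module` computes the least fixpoint of two rules starting from the
seed set: add all parents of every included class, and add the references of
included classes. Two policies govern the second rule:

* `all` (default): references of *every* included class are followed,
  including classes that entered only as ancestors. This is the only policy
  under which every module class provably keeps its complete definition, so
  modules verify clean by construction.
* `seeds_and_references`: references are followed only from seeds and from
  classes that themselves entered as references. Ancestor-only classes
  contribute just their ancestors. Modules are smaller but ancestor classes
  may reference classes outside the module; `verify_module` reports each such
  gap. The option exists for experimentation with the trade-off between
  module size and definitional completeness.

Traversal is upward-only: descendants of included classes are never added.
Provenance labels each class with the highest-priority rule that includes it
(`seed` > `reference` > `ancestor`); the labels are computed set-wise from
the final module, so they are independent of traversal order.

`verify_module` checks the two well-formedness requirements directly —
every module class's full ancestor set and full reference set lie inside the
module — and `materialize_module` refuses to write a module that fails them.

## Shape metric

Frequencies and errors are expressed in percent / percentage points, not
fractions. This makes the conventional convergence threshold `RSS < 1`
meaningful: it is an RMS shape error below one percentage point. `K` in the
RSS denominator is the number of sub-hierarchies of the *reference*
terminology (18 for SNOMED-shaped inputs), so a module missing a
sub-hierarchy entirely is penalized (its frequency counts as 0 %) rather than
silently dropped, and the metric is comparable across ontologies with other
K. Convergence is strict (`<`): an RSS of exactly 1.0 repeats.

## Signature sampling

Seats per sub-hierarchy are apportioned by the largest-remainder (Hamilton)
method with two constraints: every sub-hierarchy gets at least one seat
(without it a stratum can vanish from the module and the reweighting factor
becomes undefined), and no stratum gets more seats than it has classes
(relevant for the smallest hierarchies under down-scaling). The
implementation starts from the clipped integer parts of the exact quotas
`n·w_k` and moves single seats toward the largest remaining deviation; since
the objective `Σ|seats_k − n·w_k|` is separable convex, the greedy unit steps
attain the exhaustive optimum (property-tested against full enumeration).
Within each stratum, classes are drawn uniformly without replacement from the
sorted id list with a seeded numpy generator, so signatures are reproducible
bit-for-bit.

## Rebalancing loop

Initial weights are the source terminology's own relative frequencies. Each
iteration draws a *fresh* signature (the previous one is discarded, not
edited) with child seed `rng_seed + i`, extracts the module, profiles it
against the full source, and applies the multiplicative update
`w_k ← w_k · f(S_SHk)/f(M_SHk)` followed by renormalization onto the
simplex. Renormalization is required for the seat allocation of the next
round to be well-defined; without it the weights drift off the simplex.
The loop stops at `RSS < threshold` (default 1.0) or after `max_iter`
(default 25) iterations, and always returns the iteration with the lowest
RSS, so the oscillating regime — where compensating one sub-hierarchy's
deficit re-inflates a coupled one and the RSS cannot fall further — still
yields the best module seen, never worse than iteration 1. The signature
size is re-used unchanged every iteration.

## Synthetic terminologies

Real SNOMED CT is license-restricted, so all tests and the acceptance script
run on generated stand-ins emulating its two load-bearing features: the
skewed sub-hierarchy size spectrum (the published 18 counts, scaled), and
cross-hierarchy definition coupling. Generation is count-exact — requested
sizes are hard constraints, so shape assertions are deterministic — and only
the wiring is random: within each sub-hierarchy a random tree grows with a
tent-shaped preference for attaching new classes near `depth_mean` (default
6, decay factor `branching`, default 3), a `multiparent_prob` (default 0.10)
chance of a second same-hierarchy parent (acyclic by creation order), and
Poisson-distributed reference edges per class at the coupling rate, truncated
at `refs_per_class_max` (default 4), targeting uniformly random classes of
the target sub-hierarchy. Top-level classes stay primitive (no references).

The default coupling matrix is this package's invention (no quantitative
coupling figures are published): it concentrates reference mass on the
dependencies a terminologist would expect — findings and procedures onto body
structures, drug products onto substances, situations onto findings,
observables onto qualifier values — with rates (0.03–0.20 expected references
per class) chosen once from a feasibility argument: the reference inflow into
a target sub-hierarchy must stay below that sub-hierarchy's share of the
terminology, because beyond that point *no* seed distribution can balance the
module and the loop can only oscillate. The generator does not emulate
SNOMED's label semantics, its attribute vocabulary, or its true depth
distribution (unpublished); conclusions from synthetic runs are therefore
about the algorithm's behaviour under SNOMED-like shape and coupling, not
about any particular SNOMED release.

## Problem sizes

The test suite and the acceptance script run the full loop on an
~10,000-class terminology (`snomed_like_spec(0.0334)`, all 18 sub-hierarchies
at the published proportions) with 500-seed signatures — the same
signature-to-terminology ratio reasoning as a 2000-seed signature on a much
larger source, kept at a size where the whole 20-run convergence study
completes in seconds. At these settings all 20 independently seeded runs
converge, typically in 3–8 iterations, with worst per-sub-hierarchy errors of
2–3 percentage points at convergence; modules come out near 16 % of the
source, larger in relative terms than a production-scale extraction because
the 5 % seed fraction is itself much larger. Oracle-equivalence and
property suites run on hundreds of smaller random terminologies (≤ 500
classes).

## Numerical choices and edge cases

* Weight vectors are validated to sum to 1 within 1e-6; frequencies are
  exact ratios of integer counts.
* Apportionment tie-breaks are lexicographic by sub-hierarchy id in both
  directions (adding and removing seats), so allocations are deterministic.
* A module frequency of zero against a positive target raises a guard error
  in the update rather than dividing by zero; the minimum-one seat rule makes
  this unreachable in the loop.
* `profile` over an empty subset returns all-zero counts and an empty
  frequency map; `shape_error` rejects empty profiles.
* The treemap uses the squarified layout (areas exactly proportional to
  counts; zero-count strata omitted); the choice over slice-and-dice is
  cosmetic and affects nothing downstream.
* The extractor seeded with the root alone returns the singleton root module;
  empty seed sets are rejected.

## Known limitations

* The `seeds_and_references` policy intentionally yields modules that can
  fail definitional completeness; it is a comparison baseline, not a
  recommended output.
* Signature size is a parameter, not optimized: how small a signature can be
  while preserving shape, and how size influences final module size, are
  open questions.
* Sampling is uniform within strata; depth- or degree-stratified sampling is
  not implemented.
* No description-logic reasoning: modules are operational fixpoints of the
  traversal rules, with no logical minimality or conservativity guarantee.
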