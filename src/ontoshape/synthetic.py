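"""Synthetic SNOMED-like terminology generator.

SNOMED CT itself is license-restricted, so extraction and rebalancing are
exercised on generated stand-ins that emulate its two load-bearing features:

* the very skewed sub-hierarchy size spectrum — 18 top-level hierarchies
  ranging from Clinical Finding (100,893 classes, ~34 %) down to Physical
  Force (171 classes, 0.06 %); and
* cross-hierarchy definition coupling — e.g. clinical findings referencing
  body structures as finding sites, or drug products referencing substances —
  which is exactly what inflates some sub-hierarchies during module extraction
  and makes rebalancing non-trivial.

Generation is count-exact: the requested sub-hierarchy sizes are hard
constraints, so shape assertions are deterministic; only the wiring (parent
choices, extra parents, reference edges) is random, driven by a single seeded
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ArgumentError
from .model import ClassRecord, OntologyGraph

#: Published class counts of SNOMED CT's 18 main sub-hierarchies (metadata
#: concepts excluded), keyed by the customary abbreviation.
SNOMED_SUBHIERARCHY_COUNTS: dict[str, int] = {
    "CF": 100893,  # Clinical Finding
    "PR": 53914,   # Procedure
    "OR": 33273,   # Organism
    "BS": 30685,   # Body Structure
    "SU": 24021,   # Substance
    "PB": 16881,   # Pharmaceutical / Biologic Product
    "QV": 9055,    # Qualifier Value
    "OE": 8307,    # Observable Entity
    "SO": 4703,    # Social Context
    "PO": 4522,    # Physical Object
    "SI": 3695,    # Situation with Explicit Context
    "EV": 3673,    # Event
    "EG": 1814,    # Environment / Geographic Location
    "SN": 1447,    # Specimen
    "ST": 1309,    # Staging and Scales
    "SP": 649,     # Special Concept
    "RA": 227,     # Record Artifact
    "PF": 171,     # Physical Force
}

#: Default cross-hierarchy coupling: expected reference edges per source-class
#: into the target sub-hierarchy.  The pairs mirror SNOMED's dominant
#: definitional dependencies (findings/procedures -> body structures, products
#: -> substances, situations -> findings, observables -> qualifier values).
#: The rates are this package's synthetic invention, set so that the reference
#: inflow into any target sub-hierarchy stays below that sub-hierarchy's share
#: of the terminology — beyond that point no seed distribution can balance the
#: module and the loop can only oscillate.
DEFAULT_COUPLING: dict[tuple[str, str], float] = {
    ("CF", "BS"): 0.15,
    ("CF", "OR"): 0.05,
    ("CF", "SU"): 0.03,
    ("PR", "BS"): 0.08,
    ("PR", "PO"): 0.03,
    ("PB", "SU"): 0.20,
    ("SI", "CF"): 0.10,
    ("OE", "QV"): 0.05,
}

ROOT_ID = "ROOT"


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic terminology.

    ``depth_mean`` and ``branching`` shape the is-a trees: new classes prefer
    parents whose children would sit near ``depth_mean``, with preference
    decaying by a factor ``branching`` per level away from it.
    ``multiparent_prob`` is the chance a class gains a second is-a parent
    (within its own sub-hierarchy; acyclic by construction).  ``coupling``
    maps (source, target) sub-hierarchy pairs to the expected number of
    reference edges per source class, truncated at ``refs_per_class_max``.
    """

    subhierarchy_sizes: Mapping[str, int]
    depth_mean: float = 6.0
    branching: float = 3.0
    multiparent_prob: float = 0.10
    coupling: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    refs_per_class_max: int = 4
    rng_seed: int = 0

    def __post_init__(self):
        if not self.subhierarchy_sizes:
            raise ArgumentError("at least one sub-hierarchy is required")
        if any(s < 1 for s in self.subhierarchy_sizes.values()):
            raise ArgumentError("every sub-hierarchy size must be >= 1")
        if self.depth_mean <= 0 or self.branching <= 0:
            raise ArgumentError("depth_mean and branching must be positive")
        if not 0.0 <= self.multiparent_prob <= 1.0:
            raise ArgumentError("multiparent_prob must lie in [0, 1]")
        if any(v < 0 for v in self.coupling.values()):
            raise ArgumentError("coupling rates must be non-negative")


def snomed_like_spec(scale: float, rng_seed: int = 0) -> GeneratorSpec:
    """Spec with the 18 published sub-hierarchy counts scaled by ``scale``.

    Every sub-hierarchy keeps at least one class, so even Physical Force
    survives aggressive down-scaling.  ``scale=1`` reproduces the full
    299,239-class spectrum; ``scale≈0.0334`` gives a ~10,000-class
    terminology with the same proportions.
    """
    if not 0 < scale <= 1:
        raise ArgumentError("scale must lie in (0, 1]")
    sizes = {
        sh: max(1, round(scale * count))
        for sh, count in SNOMED_SUBHIERARCHY_COUNTS.items()
    }
    return GeneratorSpec(subhierarchy_sizes=sizes, rng_seed=rng_seed)


def with_seed(spec: GeneratorSpec, rng_seed: int) -> GeneratorSpec:
    return replace(spec, rng_seed=rng_seed)


def _id(sh: str, i: int) -> str:
    # The top-level class IS the sub-hierarchy identifier.
    return sh if i == 0 else f"{sh}{i:06d}"


def generate_ontology(spec: GeneratorSpec) -> OntologyGraph:
    """Generate a validated terminology graph from ``spec``."""
    rng = np.random.default_rng(spec.rng_seed)
    shs = sorted(spec.subhierarchy_sizes)
    parents: dict[str, set[str]] = {ROOT_ID: set()}
    depth_levels: dict[str, list[list[str]]] = {}
    order: dict[str, list[str]] = {}

    # Tent-shaped preference over the child's depth, peaking at depth_mean.
    def level_weight(child_depth: int) -> float:
        return float(spec.branching) ** (-abs(child_depth - spec.depth_mean))

    for sh in shs:
        size = spec.subhierarchy_sizes[sh]
        top = _id(sh, 0)
        parents[top] = {ROOT_ID}
        levels = [[top]]
        created = [top]
        for i in range(1, size):
            cid = _id(sh, i)
            weights = np.array(
                [len(lv) * level_weight(d + 1) for d, lv in enumerate(levels)]
            )
            d = int(rng.choice(len(levels), p=weights / weights.sum()))
            parent = levels[d][int(rng.integers(len(levels[d])))]
            parents[cid] = {parent}
            if d + 1 == len(levels):
                levels.append([])
            levels[d + 1].append(cid)
            # Optional second parent among earlier classes keeps it a DAG.
            if i > 1 and rng.random() < spec.multiparent_prob:
                extra = created[int(rng.integers(1, len(created)))]
                if extra != parent:
                    parents[cid].add(extra)
            created.append(cid)
        depth_levels[sh] = levels
        order[sh] = created

    references: dict[str, set[str]] = {cid: set() for cid in parents}
    by_source: dict[str, list[tuple[str, float]]] = {}
    for (src, tgt), rate in sorted(spec.coupling.items()):
        if src in shs and tgt in shs and rate > 0:
            by_source.setdefault(src, []).append((tgt, rate))
    for sh in shs:
        pairs = by_source.get(sh)
        if not pairs:
            continue
        for cid in order[sh][1:]:  # the top class stays primitive
            budget = spec.refs_per_class_max
            for tgt, rate in pairs:
                if budget <= 0:
                    break
                k = min(int(rng.poisson(rate)), budget)
                if k == 0:
                    continue
                pool = order[tgt]
                picks = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
                chosen = {pool[i] for i in picks} - {cid}
                references[cid] |= chosen
                budget -= len(chosen)

    records = [
        ClassRecord(cid, frozenset(ps), frozenset(references[cid]))
        for cid, ps in parents.items()
    ]
    return OntologyGraph(ROOT_ID, records)


def flat_ontology(sizes: Mapping[str, int], rng_seed: int = 0) -> OntologyGraph:
    """Degenerate fixture: every class a direct child of its sub-hierarchy
    top, no reference edges.  Extraction of any signature then adds exactly
    the sub-hierarchy tops and the root, nothing else."""
    spec = GeneratorSpec(
        subhierarchy_sizes=dict(sizes),
        depth_mean=1.0,
        branching=1.0,
        multiparent_prob=0.0,
        coupling={},
        rng_seed=rng_seed,
    )
    shs = sorted(sizes)
    parents: dict[str, set[str]] = {ROOT_ID: set()}
    for sh in shs:
        top = _id(sh, 0)
        parents[top] = {ROOT_ID}
        for i in range(1, spec.subhierarchy_sizes[sh]):
            parents[_id(sh, i)] = {top}
    records = [ClassRecord(cid, frozenset(ps)) for cid, ps in parents.items()]
    return OntologyGraph(ROOT_ID, records)
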