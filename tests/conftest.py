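"""Shared fixtures: the toy two-hierarchy ontology, random graphs, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ontoshape import ClassRecord, OntologyGraph
from ontoshape.synthetic import GeneratorSpec, generate_ontology


def build_graph(root, spec):
    """Build a graph from {id: (parents, references)} shorthand."""
    records = [
        ClassRecord(cid, frozenset(ps), frozenset(rs))
        for cid, (ps, rs) in spec.items()
    ]
    return OntologyGraph(root, records)


@pytest.fixture
def toy1():
    """Two sub-hierarchies: A (chain of 3) and B (4, fan-out), one cross
    reference A2 -> B2.  Used throughout as the hand-traceable fixture."""
    return build_graph(
        "R",
        {
            "R": ((), ()),
            "A": (("R",), ()),
            "A1": (("A",), ()),
            "A2": (("A1",), ("B2",)),
            "B": (("R",), ()),
            "B1": (("B",), ()),
            "B2": (("B1",), ()),
            "B3": (("B1",), ()),
        },
    )


def random_spec(rng: np.random.Generator, max_classes: int = 500) -> GeneratorSpec:
    """A small random generator spec for property/oracle tests."""
    k = int(rng.integers(2, 6))
    names = [f"S{chr(65 + i)}" for i in range(k)]
    budget = int(rng.integers(2 * k, max_classes))
    raw = rng.dirichlet(np.ones(k))
    sizes = {nm: max(1, int(round(budget * w))) for nm, w in zip(names, raw)}
    coupling = {}
    for _ in range(int(rng.integers(0, 2 * k))):
        src, tgt = rng.choice(names, size=2, replace=False)
        coupling[(str(src), str(tgt))] = float(rng.uniform(0.05, 0.6))
    return GeneratorSpec(
        subhierarchy_sizes=sizes,
        depth_mean=float(rng.uniform(1.5, 6.0)),
        branching=float(rng.uniform(1.2, 4.0)),
        multiparent_prob=float(rng.uniform(0.0, 0.3)),
        coupling=coupling,
        refs_per_class_max=int(rng.integers(1, 5)),
        rng_seed=int(rng.integers(2**31 - 1)),
    )


def random_graph(rng: np.random.Generator, max_classes: int = 500) -> OntologyGraph:
    return generate_ontology(random_spec(rng, max_classes))


def oracle_extract(graph, seeds, policy="all"):
    """Brute-force repeat-until-stable set expansion (independent of the
    worklist implementation): full rescans until nothing changes."""
    included = set(seeds)
    # Classes whose references must be followed.
    followers = set(seeds) if policy == "seeds_and_references" else None
    while True:
        before = len(included), None if followers is None else len(followers)
        additions = set()
        for cid in included:
            additions |= graph.classes[cid].parents
            if followers is None:
                additions |= graph.classes[cid].references
        if followers is not None:
            ref_targets = set()
            for cid in followers:
                ref_targets |= graph.classes[cid].references
            additions |= ref_targets
            followers |= ref_targets
        included |= additions
        if (len(included), None if followers is None else len(followers)) == before:
            return included
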