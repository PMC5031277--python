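"""Signature-driven module extraction by graph-traversal closure.

Starting from a set of seed classes (the *signature*), the extractor adds
every class needed so that each module class (a) keeps all of its paths up the
is-a hierarchy to the root, and (b) keeps its axiomatic definition intact —
i.e. every class appearing on the right-hand side of a definition (a
*reference*, such as a finding site) is carried along.  Newly added classes
become traversal targets themselves, so the module is the least fixpoint of
the two rules.

Two closure policies exist.  Under ``"all"`` (default) the references of
*every* module class are followed, including classes that entered only as
ancestors; this is the only policy under which every module class is
guaranteed a complete definition.  Under ``"seeds_and_references"`` only seeds
and reference-included classes propagate their references; ancestor-only
classes contribute just their own ancestors, giving smaller modules whose
ancestor classes may have dangling definitions (flagged by
:func:`verify_module`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ArgumentError, ValidationError
from .model import OntologyGraph, ValidationReport

POLICIES = ("all", "seeds_and_references")


@dataclass(frozen=True)
class ModuleResult:
    """An extracted module with per-class inclusion provenance.

    ``provenance`` maps each class to the highest-priority rule that includes
    it: ``"seed"`` > ``"reference"`` > ``"ancestor"``.
    """

    classes: frozenset[str]
    provenance: dict[str, str]
    source: str | None = None

    @property
    def seeds(self) -> frozenset[str]:
        return frozenset(c for c, p in self.provenance.items() if p == "seed")

    def __len__(self) -> int:
        return len(self.classes)


def ancestors(graph: OntologyGraph, class_id: str) -> set[str]:
    """All classes reachable from ``class_id`` via parent edges (exclusive)."""
    return set(graph.ancestors_of(class_id))


def _check_seeds(graph: OntologyGraph, seeds: Iterable[str]) -> set[str]:
    seeds = set(seeds)
    if not seeds:
        raise ArgumentError("seed set is empty")
    unknown = sorted(s for s in seeds if s not in graph.classes)
    if unknown:
        raise ArgumentError("unknown seed id(s): " + ", ".join(unknown))
    return seeds


def extract_module(
    graph: OntologyGraph,
    seeds: Iterable[str],
    closure_policy: str = "all",
) -> ModuleResult:
    """Extract the least module containing ``seeds`` under the chosen policy."""
    if closure_policy not in POLICIES:
        raise ArgumentError(f"unknown closure policy: {closure_policy!r}")
    seeds = _check_seeds(graph, seeds)
    classes = graph.classes

    if closure_policy == "all":
        # Fixpoint over both edge kinds from every included class.
        included: set[str] = set()
        stack = sorted(seeds, reverse=True)
        while stack:
            cid = stack.pop()
            if cid in included:
                continue
            included.add(cid)
            rec = classes[cid]
            stack.extend(rec.parents - included)
            stack.extend(rec.references - included)
        referenced = set()
        for cid in included:
            referenced |= classes[cid].references
        ref_included = (referenced & included) - seeds
    else:
        # References propagate only through seeds and reference-included
        # classes ("active" set); ancestors are then closed over separately.
        active: set[str] = set()
        stack = sorted(seeds, reverse=True)
        while stack:
            cid = stack.pop()
            if cid in active:
                continue
            active.add(cid)
            stack.extend(classes[cid].references - active)
        included = set(active)
        for cid in active:
            included |= graph.ancestors_of(cid)
        ref_included = active - seeds

    provenance = {}
    for cid in included:
        if cid in seeds:
            provenance[cid] = "seed"
        elif cid in ref_included:
            provenance[cid] = "reference"
        else:
            provenance[cid] = "ancestor"
    return ModuleResult(frozenset(included), provenance, source=graph.root)


def verify_module(graph: OntologyGraph, module: ModuleResult) -> ValidationReport:
    """Check the two balanced-module well-formedness requirements.

    (a) every module class keeps all its paths to the root: its complete
    ancestor set is inside the module; (b) every module class keeps its full
    definition: all its references are inside the module.  Violations are
    report entries, never exceptions.
    """
    unknown = sorted(c for c in module.classes if c not in graph.classes)
    if unknown:
        raise ArgumentError("module contains unknown class(es): " + ", ".join(unknown))
    report = ValidationReport()
    for cid in sorted(module.classes):
        missing_anc = graph.ancestors_of(cid) - module.classes
        if missing_anc:
            report.error(
                "missing-ancestor",
                cid,
                "ancestors outside module: " + ", ".join(sorted(missing_anc)),
            )
        missing_ref = graph.classes[cid].references - module.classes
        if missing_ref:
            report.error(
                "missing-reference",
                cid,
                "references outside module: " + ", ".join(sorted(missing_ref)),
            )
    return report


def materialize_module(graph: OntologyGraph, module: ModuleResult) -> OntologyGraph:
    """Write out the module as a standalone, loadable ontology graph."""
    if not module.classes:
        raise ArgumentError("cannot materialize an empty module")
    report = verify_module(graph, module)
    if not report.ok:
        code, cid, msg = report.errors[0]
        raise ValidationError(
            f"module fails verification ({len(report.errors)} error(s)); "
            f"first: [{code}] {cid}: {msg}",
            report=report,
        )
    records = [graph.classes[cid] for cid in module.classes]
    return OntologyGraph(graph.root, records)
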