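"""Rooted-DAG terminology model: classes, is-a edges and definition references.

A terminology (SNOMED CT being the motivating case) is modelled as a rooted
directed acyclic graph.  Each class carries two edge sets:

* ``parents`` — direct is-a superclasses (the subsumption hierarchy), and
* ``references`` — classes appearing on the right-hand side of the class's
  axiomatic definition (e.g. fillers of existential restrictions such as a
  clinical finding's finding site).

A *sub-hierarchy* is the set of classes below one direct child of the root;
every non-root class is assigned to exactly one sub-hierarchy.  The root is
structural and belongs to none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import ArgumentError, FormatError, ValidationError

NATIVE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ClassRecord:
    """One terminology class: identifier, optional label, and its edges."""

    id: str
    parents: frozenset[str] = frozenset()
    references: frozenset[str] = frozenset()
    label: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "parents", frozenset(self.parents))
        object.__setattr__(self, "references", frozenset(self.references))


@dataclass
class ValidationReport:
    """Structural findings: ``errors`` block use, ``warnings`` do not."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def error(self, code: str, class_id: str, message: str) -> None:
        self.errors.append((code, class_id, message))

    def warn(self, code: str, class_id: str, message: str) -> None:
        self.warnings.append((code, class_id, message))


class OntologyGraph:
    """A validated, rooted terminology DAG.

    Parameters
    ----------
    root:
        Identifier of the root class.
    classes:
        ``ClassRecord`` instances (any iterable), or a mapping id -> record.
        Must include the root.
    validate:
        When true (default) the graph is validated on construction and a
        :class:`~ontoshape.errors.ValidationError` is raised if any structural
        invariant fails.
    """

    def __init__(self, root: str, classes, validate: bool = True):
        if isinstance(classes, Mapping):
            self.classes: dict[str, ClassRecord] = dict(classes)
        else:
            self.classes = {c.id: c for c in classes}
        self.root = root
        self._subhierarchy_of: dict[str, str] | None = None
        self._anc_cache: dict[str, frozenset[str]] = {}
        if validate:
            report = self.validate()
            if not report.ok:
                code, cid, msg = report.errors[0]
                raise ValidationError(
                    f"invalid ontology ({len(report.errors)} error(s)); "
                    f"first: [{code}] {cid}: {msg}",
                    report=report,
                )

    # -- basic queries -----------------------------------------------------

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes

    def subhierarchies(self) -> list[str]:
        """Direct children of the root, sorted: the sub-hierarchy identifiers."""
        return sorted(
            c.id for c in self.classes.values() if self.root in c.parents
        )

    @property
    def subhierarchy_of(self) -> dict[str, str]:
        """Map of every non-root class to its sub-hierarchy (lazily computed)."""
        if self._subhierarchy_of is None:
            self._subhierarchy_of = assign_subhierarchies(self)
        return self._subhierarchy_of

    def ancestors_of(self, class_id: str) -> frozenset[str]:
        """All classes reachable from ``class_id`` via parent edges (cached)."""
        if class_id not in self.classes:
            raise ArgumentError(f"unknown class: {class_id!r}")
        cached = self._anc_cache.get(class_id)
        if cached is not None:
            return cached
        # Iterative DFS with memoisation; parent DAGs are shallow in practice.
        out: set[str] = set()
        stack = list(self.classes[class_id].parents)
        while stack:
            p = stack.pop()
            if p in out:
                continue
            hit = self._anc_cache.get(p)
            if hit is not None:
                out.add(p)
                out |= hit
                continue
            out.add(p)
            stack.extend(self.classes[p].parents)
        result = frozenset(out)
        self._anc_cache[class_id] = result
        return result

    # -- validation --------------------------------------------------------

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        if self.root not in self.classes:
            report.error("missing-root", self.root, "root class not present")
            return report
        rootrec = self.classes[self.root]
        if rootrec.parents:
            report.error("root-has-parents", self.root, "root must have no parents")
        if rootrec.references:
            report.error("root-has-references", self.root, "root must have no references")

        dangling = False
        for rec in self.classes.values():
            if rec.id in rec.parents:
                report.error("self-parent", rec.id, "class lists itself as a parent")
            if rec.id in rec.references:
                report.error("self-reference", rec.id, "class references itself")
            for p in rec.parents:
                if p not in self.classes:
                    report.error("dangling-parent", rec.id, f"unknown parent {p!r}")
                    dangling = True
            for r in rec.references:
                if r not in self.classes:
                    report.error("dangling-reference", rec.id, f"unknown reference {r!r}")
                    dangling = True
            if rec.id != self.root and not rec.parents:
                report.error("orphan", rec.id, "non-root class has no parents")
        if dangling:
            return report

        dag = nx.DiGraph()
        dag.add_nodes_from(self.classes)
        for rec in self.classes.values():
            for p in rec.parents:
                dag.add_edge(rec.id, p)  # child -> parent
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            names = " -> ".join(u for u, _ in cycle) + f" -> {cycle[0][0]}"
            report.error("cycle", cycle[0][0], f"parent cycle: {names}")
            return report

        reaches_root = nx.ancestors(dag, self.root)
        for cid in self.classes:
            if cid != self.root and cid not in reaches_root:
                report.error("unreachable", cid, "class does not reach the root")
        if not report.ok:
            return report

        # Multi-top-level-ancestor classes resolve by tie-break but are flagged.
        tops = set(self.subhierarchies())
        for cid in sorted(self.classes):
            if cid == self.root:
                continue
            hit = (self.ancestors_of(cid) | {cid}) & tops
            if len(hit) > 1:
                report.warn(
                    "multi-subhierarchy",
                    cid,
                    "reachable from top-level classes "
                    + ", ".join(sorted(hit))
                    + "; assigned to " + min(hit),
                )
        return report


def assign_subhierarchies(graph: OntologyGraph) -> dict[str, str]:
    """Map every non-root class to a direct child of the root.

    A class reachable from several top-level classes (possible in a general
    DAG, though SNOMED CT's top hierarchies are disjoint in practice) is
    assigned to the lexicographically smallest of them — deterministic and
    auditable; :meth:`OntologyGraph.validate` emits a warning for each such
    class.  The root is absent from the returned map.
    """
    tops = set(graph.subhierarchies())
    out: dict[str, str] = {}
    for cid in graph.classes:
        if cid == graph.root:
            continue
        if cid in tops:
            out[cid] = cid
            continue
        hit = graph.ancestors_of(cid) & tops
        out[cid] = min(hit)
    return out


def strip_subhierarchy(graph: OntologyGraph, sh: str) -> OntologyGraph:
    """Remove one sub-hierarchy (e.g. SNOMED's metadata concepts) entirely.

    Returns a new graph without ``sh`` and all its descendants; references
    from surviving classes into the removed set are dropped (their count is
    recorded on the returned graph as ``dropped_references``).
    """
    if sh not in graph.subhierarchies():
        raise ArgumentError(f"{sh!r} is not a direct child of the root")
    doomed = {cid for cid, s in graph.subhierarchy_of.items() if s == sh}
    dropped = 0
    survivors = []
    for rec in graph.classes.values():
        if rec.id in doomed:
            continue
        refs = rec.references - doomed
        dropped += len(rec.references) - len(refs)
        survivors.append(
            ClassRecord(rec.id, rec.parents - doomed, refs, rec.label)
        )
    out = OntologyGraph(graph.root, survivors)
    out.dropped_references = dropped
    return out


# -- native serialization --------------------------------------------------


def load_ontology(path, format: str | None = None) -> OntologyGraph:
    """Load a terminology from ``path``.

    ``format`` is ``"native"`` (the package's line-diffable JSON interchange
    format) or ``"owl-functional"`` (the restricted OWL functional-syntax
    subset matching SNOMED CT's official OWL-EL conversion).  When omitted it
    is inferred from the file extension (.owl/.ofn -> owl-functional,
    otherwise native).
    """
    path = str(path)
    if format is None:
        format = (
            "owl-functional"
            if path.endswith((".owl", ".ofn"))
            else "native"
        )
    if format == "owl-functional":
        from .owl import load_owl_functional

        return load_owl_functional(path)
    if format != "native":
        raise ArgumentError(f"unknown format: {format!r}")

    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON (line {exc.lineno}): {exc.msg}") from exc
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return ontology_from_dict(doc, source=path)


def ontology_from_dict(doc: dict, source: str = "<dict>") -> OntologyGraph:
    """Build a validated graph from a native-format document."""
    if not isinstance(doc, dict):
        raise FormatError(f"{source}: top-level value must be an object")
    version = doc.get("format_version")
    if version != NATIVE_FORMAT_VERSION:
        raise FormatError(
            f"{source}: unsupported format_version {version!r} "
            f"(expected {NATIVE_FORMAT_VERSION})"
        )
    if "root" not in doc or "classes" not in doc:
        raise FormatError(f"{source}: missing required key 'root' or 'classes'")
    records = []
    seen = set()
    for entry in doc["classes"]:
        cid = entry["id"]
        if cid in seen:
            raise FormatError(f"{source}: duplicate class id {cid!r}")
        seen.add(cid)
        records.append(
            ClassRecord(
                cid,
                frozenset(entry.get("parents", ())),
                frozenset(entry.get("references", ())),
                entry.get("label"),
            )
        )
    return OntologyGraph(doc["root"], records)


def ontology_to_dict(graph: OntologyGraph) -> dict:
    return {
        "format_version": NATIVE_FORMAT_VERSION,
        "root": graph.root,
        "classes": [
            {
                "id": rec.id,
                "label": rec.label,
                "parents": sorted(rec.parents),
                "references": sorted(rec.references),
            }
            for rec in (graph.classes[k] for k in sorted(graph.classes))
        ],
    }


def write_ontology(graph: OntologyGraph, path, format: str = "native") -> None:
    """Serialize to the native format; ``load(write(g))`` is the identity."""
    if format != "native":
        raise ArgumentError(f"unsupported output format: {format!r}")
    text = json.dumps(ontology_to_dict(graph), ensure_ascii=False, indent=1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text + "\n")


def read_seed_list(path) -> list[str]:
    """Read a seed-list file: one class id per line, '#' starts a comment."""
    seeds = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                seeds.append(line)
    return seeds
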