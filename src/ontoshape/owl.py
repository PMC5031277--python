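"""Reader for a restricted OWL 2 functional-syntax subset.

The subset is the shape of SNOMED CT's official OWL-EL conversion: class-level
``SubClassOf`` / ``EquivalentClasses`` axioms whose right-hand sides are named
classes, ``ObjectIntersectionOf`` and ``ObjectSomeValuesFrom`` (arbitrarily
nested, which covers SNOMED role groups).  Named superclasses and intersection
conjuncts become ``parents``; named classes inside existential-restriction
fillers (recursively) become ``references``.  Object-property axioms,
declarations of non-classes, annotations and anything else are ignored and
counted.
"""

from __future__ import annotations

import re

from .errors import FormatError, ValidationError
from .model import ClassRecord, OntologyGraph

_TOKEN = re.compile(r"<[^>\s]*>|[()]|[^\s()]+")
_COMMENT = re.compile(r"^\s*#")


class _Node:
    """An s-expression: ``name(args...)``; leaves are plain strings."""

    __slots__ = ("name", "args")

    def __init__(self, name, args):
        self.name = name
        self.args = args


def _tokenize(text: str):
    for lineno, line in enumerate(text.splitlines(), 1):
        if _COMMENT.match(line):
            continue
        for m in _TOKEN.finditer(line):
            yield lineno, m.group(0)


def _parse_forms(tokens):
    """Parse the token stream into a list of top-level s-expressions."""
    stack: list[_Node] = []
    forms: list = []
    pending: str | None = None
    pending_line = 0

    def emit(item):
        if stack:
            stack[-1].args.append(item)
        else:
            forms.append(item)

    def flush_pending():
        nonlocal pending
        if pending is not None:
            if not stack:
                raise FormatError(f"line {pending_line}: stray token {pending!r}")
            stack[-1].args.append(pending)
            pending = None

    for lineno, tok in tokens:
        if tok == "(":
            if pending is None:
                raise FormatError(f"line {lineno}: '(' without a preceding name")
            stack.append(_Node(pending, []))
            pending = None
        elif tok == ")":
            flush_pending()
            if not stack:
                raise FormatError(f"line {lineno}: unbalanced ')'")
            emit(stack.pop())
        else:
            flush_pending()
            pending = tok
            pending_line = lineno
    if pending is not None:
        raise FormatError(f"line {pending_line}: stray token {pending!r}")
    if stack:
        raise FormatError(f"unclosed '(' in form {stack[0].name!r}")
    return forms


def _local_name(token: str) -> str:
    """Reduce an IRI or prefixed name to its local identifier."""
    if token.startswith("<") and token.endswith(">"):
        iri = token[1:-1]
        for sep in ("#", "/", ":"):
            if sep in iri:
                return iri.rsplit(sep, 1)[1]
        return iri
    if ":" in token:
        return token.rsplit(":", 1)[1]
    return token


def _is_named(expr) -> bool:
    return isinstance(expr, str)


def _collect_refs(expr, refs: set[str], ignored: list) -> None:
    """Named classes anywhere inside an existential filler are references."""
    if _is_named(expr):
        refs.add(_local_name(expr))
    elif expr.name == "ObjectIntersectionOf":
        for a in expr.args:
            _collect_refs(a, refs, ignored)
    elif expr.name == "ObjectSomeValuesFrom" and len(expr.args) == 2:
        _collect_refs(expr.args[1], refs, ignored)
    else:
        ignored.append(expr.name)


def _extract(expr, parents: set[str], refs: set[str], ignored: list) -> None:
    """Split a right-hand class expression into parents and references."""
    if _is_named(expr):
        parents.add(_local_name(expr))
    elif expr.name == "ObjectIntersectionOf":
        for a in expr.args:
            _extract(a, parents, refs, ignored)
    elif expr.name == "ObjectSomeValuesFrom" and len(expr.args) == 2:
        _collect_refs(expr.args[1], refs, ignored)
    else:
        ignored.append(expr.name)


def load_owl_functional(path) -> OntologyGraph:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    forms = _parse_forms(_tokenize(text))

    axioms = []
    for form in forms:
        if isinstance(form, _Node) and form.name == "Ontology":
            axioms.extend(a for a in form.args if isinstance(a, _Node))
        elif isinstance(form, _Node) and form.name != "Prefix":
            axioms.append(form)

    parents: dict[str, set[str]] = {}
    refs: dict[str, set[str]] = {}
    ignored: list[str] = []

    def rec(cid: str):
        parents.setdefault(cid, set())
        refs.setdefault(cid, set())

    for ax in axioms:
        if ax.name == "Declaration":
            inner = ax.args[0] if ax.args else None
            if isinstance(inner, _Node) and inner.name == "Class" and inner.args:
                rec(_local_name(inner.args[0]))
            else:
                ignored.append(ax.name)
        elif ax.name == "SubClassOf" and len(ax.args) == 2 and _is_named(ax.args[0]):
            cid = _local_name(ax.args[0])
            rec(cid)
            _extract(ax.args[1], parents[cid], refs[cid], ignored)
        elif ax.name == "EquivalentClasses" and len(ax.args) == 2 and _is_named(ax.args[0]):
            cid = _local_name(ax.args[0])
            rec(cid)
            _extract(ax.args[1], parents[cid], refs[cid], ignored)
        else:
            ignored.append(ax.name)

    for ids in list(parents.values()) + list(refs.values()):
        for cid in ids:
            rec(cid)

    if not parents:
        raise FormatError(f"{path}: no class axioms found in the supported subset")

    roots = sorted(cid for cid, ps in parents.items() if not ps)
    if len(roots) != 1:
        raise ValidationError(
            f"{path}: expected exactly one parentless (root) class, found "
            f"{len(roots)}: {', '.join(roots[:5])}"
        )
    root = roots[0]
    records = [
        ClassRecord(cid, frozenset(parents[cid] - {cid}), frozenset(refs[cid] - {cid}))
        for cid in parents
    ]
    graph = OntologyGraph(root, records)
    graph.ignored_axioms = len(ignored)
    return graph
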