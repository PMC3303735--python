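"""Concept hierarchies for the query ontology.

A *term tree* (term id + preferred name, nested) stands in for a subtree
pulled out of a pre-defined terminology — here a breast-lesion morphology
branch rooted at "neoplasm and hamartoma".  The tree is flattened into
hierarchical ``ConceptRecord`` paths: concept names form the path segments
(the human-browsable tree), term ids become concept codes.

The packaged fixture is a lexicon of plausibly-shaped morphology codes; it
is not asserted against any terminology release.  An optional OWL reader
(``rdflib``) accepts an RDF/XML subclass hierarchy instead of the nested
text format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .model import PATH_SEP, ConceptRecord, path_level

__all__ = [
    "TermNode",
    "OntologySource",
    "TermNotFoundError",
    "DuplicateSiblingError",
    "load_term_tree",
    "load_packaged_tree",
    "load_owl_tree",
    "extract_view",
    "build_concepts",
    "descendants",
    "make_branch_root",
    "tree_from_concepts",
]


class TermNotFoundError(KeyError):
    """The requested root term id does not occur in the tree."""


class DuplicateSiblingError(ValueError):
    """Two sibling terms share a preferred name; paths would collide."""


@dataclass
class TermNode:
    term_id: str
    preferred_name: str
    children: list["TermNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def find(self, term_id: str) -> "TermNode | None":
        for node in self.walk():
            if node.term_id == term_id:
                return node
        return None


@dataclass
class OntologySource:
    source_name: str
    root: TermNode


def load_term_tree(source: str | Path) -> TermNode:
    """Parse an indentation-nested term list (two spaces per level,
    ``term_id<TAB>name`` per line) into a single-rooted tree.

    ``source`` is the text itself, or a :class:`~pathlib.Path` to a file
    holding it.  Term ids must be unique; nesting jumps of more than one
    level are malformed.
    """
    text = source.read_text(encoding="utf-8") if isinstance(source, Path) else source

    seen: set[str] = set()
    stack: list[tuple[int, TermNode]] = []
    root: TermNode | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        indent = len(raw) - len(raw.lstrip(" "))
        if indent % 2:
            raise ValueError(f"line {lineno}: odd indentation")
        depth = indent // 2
        try:
            term_id, name = raw.strip().split("\t", 1)
        except ValueError:
            raise ValueError(f"line {lineno}: expected 'term_id<TAB>name'") from None
        if term_id in seen:
            raise ValueError(f"line {lineno}: duplicate term_id {term_id!r}")
        seen.add(term_id)
        node = TermNode(term_id, name.strip())
        if depth == 0:
            if root is not None:
                raise ValueError(f"line {lineno}: multiple roots")
            root = node
            stack = [(0, node)]
            continue
        while stack and stack[-1][0] >= depth:
            stack.pop()
        if not stack or stack[-1][0] != depth - 1:
            raise ValueError(f"line {lineno}: nesting jumps a level")
        stack[-1][1].children.append(node)
        stack.append((depth, node))
    if root is None:
        raise ValueError("empty term tree")
    return root


def load_packaged_tree() -> OntologySource:
    """The shipped breast-lesion morphology fixture."""
    text = (
        resources.files("oncostar.data").joinpath("morphology_terms.txt").read_text("utf-8")
    )
    return OntologySource("Morphologically Abnormal Structure (fixture)", load_term_tree(text))


def load_owl_tree(path: str | Path, root_uri: str) -> TermNode:
    """Read a subclass hierarchy from an RDF/XML (OWL) file.

    Labels come from ``rdfs:label``; the local part of each class URI is the
    term id.  Requires ``rdflib``.
    """
    from rdflib import Graph, RDFS, URIRef

    g = Graph()
    g.parse(str(path))
    children: dict[URIRef, list[URIRef]] = {}
    for sub, _, sup in g.triples((None, RDFS.subClassOf, None)):
        children.setdefault(sup, []).append(sub)

    def label(uri: URIRef) -> str:
        for _, _, lab in g.triples((uri, RDFS.label, None)):
            return str(lab)
        return _local(uri)

    def _local(uri: URIRef) -> str:
        s = str(uri)
        return s.rsplit("#", 1)[-1].rsplit("/", 1)[-1]

    def build(uri: URIRef, seen: frozenset) -> TermNode:
        if uri in seen:
            raise ValueError(f"cycle through {uri}")
        kids = sorted(children.get(uri, []), key=str)
        return TermNode(
            _local(uri), label(uri),
            [build(k, seen | {uri}) for k in kids],
        )

    return build(URIRef(root_uri), frozenset())


def extract_view(source: OntologySource, root_id: str) -> TermNode:
    """Return the branch rooted at ``root_id``, descendants included."""
    node = source.root.find(root_id)
    if node is None:
        raise TermNotFoundError(
            f"term {root_id!r} not found in {source.source_name!r}"
        )
    return node


def build_concepts(
    subtree: TermNode, base_path: str, source: str = "OTHER"
) -> list[ConceptRecord]:
    """Flatten a term subtree into concept records under ``base_path``.

    ``concept_path`` = base path + ancestor names + node name, each a path
    segment; duplicate sibling names are rejected because they would
    produce colliding paths.
    """
    if not (base_path.startswith(PATH_SEP) and base_path.endswith(PATH_SEP)):
        raise ValueError(f"base_path must begin and end with {PATH_SEP!r}")
    out: list[ConceptRecord] = []

    def visit(node: TermNode, prefix: str) -> None:
        names = [c.preferred_name for c in node.children]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateSiblingError(
                f"duplicate sibling name(s) {dupes} under {node.term_id!r}"
            )
        path = prefix + node.preferred_name + PATH_SEP
        out.append(
            ConceptRecord(node.term_id, path, node.preferred_name,
                          path_level(path), source)
        )
        for child in node.children:
            visit(child, path)

    visit(subtree, base_path)
    return out


def descendants(concepts: Iterable[ConceptRecord], path: str) -> list[ConceptRecord]:
    """Concepts at or below ``path`` (segment-aligned prefix match).

    Paths carry a trailing delimiter, so a plain prefix test is already
    segment-aligned: ``\\A\\B\\`` never matches ``\\A\\BC\\``.
    """
    if not path.endswith(PATH_SEP):
        path = path + PATH_SEP
    return [c for c in concepts if c.concept_path.startswith(path)]


def make_branch_root(name: str, source: str, code: str | None = None) -> ConceptRecord:
    """A level-1 concept anchoring an internal-hierarchy branch."""
    path = PATH_SEP + name + PATH_SEP
    return ConceptRecord(code or f"ROOT:{name}", path, name, 1, source)


def tree_from_concepts(concepts: Iterable[ConceptRecord]) -> TermNode:
    """Rebuild the term tree from flattened concept paths (inverse of
    :func:`build_concepts` up to the base-path prefix)."""
    recs = sorted(concepts, key=lambda c: c.concept_path)
    if not recs:
        raise ValueError("no concepts")
    root_rec = min(recs, key=lambda c: c.level)
    nodes = {root_rec.concept_path: TermNode(root_rec.concept_code, root_rec.name)}
    for rec in recs:
        if rec.concept_path == root_rec.concept_path:
            continue
        node = TermNode(rec.concept_code, rec.name)
        nodes[rec.concept_path] = node
        parent = rec.concept_path[: -len(rec.name + PATH_SEP)]
        if parent not in nodes:
            raise ValueError(f"orphan path {rec.concept_path!r}")
        nodes[parent].children.append(node)
    return nodes[root_rec.concept_path]
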