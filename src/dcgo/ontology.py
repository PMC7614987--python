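"""Ontology DAGs: OBO parsing, ancestor queries and term-set closure.

An ontology (GO, HPO, MPO, EFO, ...) is a set of terms connected by
``is_a`` relations into a directed acyclic graph (DAG).  Everything the
rest of the package does — building correspondence matrices, propagating
inferred annotations, enrichment — rests on two queries provided here:

* :meth:`OntologyDAG.ancestors` — all strict ancestors of a term, i.e.
  the transitive closure of the child→parent relation;
* :meth:`OntologyDAG.close_term_set` — a term set closed under
  ancestors, which is how the True Path Rule ("annotated to a term ⇒
  annotated to all its parents up to the root") is applied to data.

Only ``is_a`` edges are used by default; ``part_of`` edges can be opted
in at parse time.  Obsolete terms are excluded, and ``alt_id`` aliases
are retained so that annotations using superseded identifiers still
resolve.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Dict, Iterable, List, Set, Tuple, Union

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OboParseError",
    "OntologyCycleError",
    "OntologyTerm",
    "OntologyDAG",
    "parse_obo",
]


class OboParseError(ValueError):
    """Raised when an OBO document cannot be parsed into a valid DAG."""


class OntologyCycleError(OboParseError):
    """Raised when the is_a relation of a parsed ontology contains a cycle."""

    def __init__(self, cycle: List[str]):
        self.cycle = cycle
        super().__init__(
            "ontology is not acyclic; one cycle: " + " -> ".join(cycle + cycle[:1])
        )


@dataclass(frozen=True)
class OntologyTerm:
    """A single non-obsolete ontology term.

    Parameters
    ----------
    term_id:
        Primary CURIE identifier, e.g. ``"GO:0002376"``.
    name:
        Human-readable term name.
    namespace:
        Sub-ontology the term belongs to (e.g. ``biological_process``),
        or the ontology name when the file defines no namespaces.
    parent_ids:
        Identifiers of the direct parents (the relations kept at parse
        time, ``is_a`` and optionally ``part_of``).
    alt_ids:
        Alternative (superseded) identifiers resolving to this term.
    """

    term_id: str
    name: str = ""
    namespace: str = ""
    parent_ids: Tuple[str, ...] = ()
    alt_ids: Tuple[str, ...] = ()
    obsolete: bool = False


class OntologyDAG:
    """Terms plus child→parent edges of one ontology, guaranteed acyclic.

    The constructor validates the structural invariants: every referenced
    parent resolves to a known term, the graph is acyclic, and (for a
    non-empty ontology) at least one root exists.  Terms flagged obsolete
    must not be passed in; they are removed during parsing.
    """

    def __init__(self, terms: Dict[str, OntologyTerm]):
        self.terms: Dict[str, OntologyTerm] = dict(terms)
        self._alt: Dict[str, str] = {}
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term in self.terms.values():
            if term.obsolete:
                raise OboParseError(
                    f"obsolete term {term.term_id} cannot be part of the DAG"
                )
            for alt in term.alt_ids:
                self._alt[alt] = term.term_id
            for parent in term.parent_ids:
                if parent not in self.terms:
                    raise OboParseError(
                        f"term {term.term_id} references undefined parent {parent}"
                    )
                graph.add_edge(term.term_id, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle_edges = nx.find_cycle(graph)
            raise OntologyCycleError([u for u, _ in cycle_edges])
        self._graph = graph

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self._alt

    def __iter__(self):
        return iter(self.terms)

    # -- queries -------------------------------------------------------------------

    def resolve(self, term_id: str) -> str:
        """Map a primary or alternative identifier to the primary one.

        Raises ``KeyError`` for identifiers unknown to the ontology.
        """
        if term_id in self.terms:
            return term_id
        if term_id in self._alt:
            return self._alt[term_id]
        raise KeyError(f"unknown ontology term: {term_id}")

    @property
    def roots(self) -> Set[str]:
        """Terms with no parents; one per sub-ontology namespace in GO."""
        return {t for t in self._graph if self._graph.out_degree(t) == 0}

    @property
    def leaves(self) -> Set[str]:
        """Terms with no children."""
        return {t for t in self._graph if self._graph.in_degree(t) == 0}

    def edges(self) -> List[Tuple[str, str]]:
        """All (child, parent) pairs."""
        return list(self._graph.edges())

    def parents(self, term_id: str) -> Set[str]:
        return set(self._graph.successors(self.resolve(term_id)))

    def children(self, term_id: str) -> Set[str]:
        return set(self._graph.predecessors(self.resolve(term_id)))

    def ancestors(self, term_id: str) -> Set[str]:
        """All strict ancestors of ``term_id`` (the term itself excluded)."""
        return set(nx.descendants(self._graph, self.resolve(term_id)))

    def close_term_set(self, term_ids: Iterable[str]) -> Set[str]:
        """Close a term set under ancestors (True Path Rule closure).

        The result contains every input term (alt_ids resolved to their
        primary identifier) together with all of its ancestors.  The
        operation is idempotent and monotone in the input set.
        """
        closed: Set[str] = set()
        for tid in term_ids:
            primary = self.resolve(tid)
            closed.add(primary)
            closed.update(self.ancestors(primary))
        return closed

    def topological_order(self) -> List[str]:
        """Terms ordered children-before-parents; succeeds iff acyclic."""
        return list(nx.topological_sort(self._graph))

    def namespaces(self) -> Set[str]:
        return {t.namespace for t in self.terms.values()}

    # -- output --------------------------------------------------------------------

    def write_edge_list(self, path: Union[str, Path]) -> None:
        """Dump the DAG as a two-column (child_id, parent_id) TSV."""
        lines = ["child_id\tparent_id"]
        lines += [f"{c}\t{p}" for c, p in sorted(self._graph.edges())]
        Path(path).write_text("\n".join(lines) + "\n")


def _validate_obo_text(text: str, source_name: str) -> None:
    """Cheap line-level sanity check so malformed input fails with a line number."""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("[") and line.endswith("]"):
            continue
        if ":" not in line:
            raise OboParseError(
                f"{source_name}:{lineno}: malformed OBO line (no 'tag: value'): {line!r}"
            )


def parse_obo(
    source: Union[str, Path, IO[str]],
    include_part_of: bool = False,
) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyDAG`.

    One term is created per non-obsolete ``[Term]`` stanza; ``is_a``
    lines (and, with ``include_part_of=True``, ``relationship: part_of``
    lines) become child→parent edges.  Obsolete stanzas are dropped
    entirely.  Multiple roots are allowed and kept as separate
    sub-DAGs — no artificial super-root is added.

    Raises
    ------
    OboParseError
        For malformed stanza lines (with the offending line number) or
        parents that resolve to no term.
    OntologyCycleError
        If the kept relations contain a cycle; the message lists one.
    """
    if hasattr(source, "read"):
        text = source.read()
        source_name = getattr(source, "name", "<stream>")
    else:
        text = Path(source).read_text()
        source_name = str(source)
    _validate_obo_text(text, source_name)
    try:
        multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueError subclasses
        raise OboParseError(f"{source_name}: failed to parse OBO: {exc}") from exc

    relations = {"is_a"} | ({"part_of"} if include_part_of else set())
    default_ns = multigraph.graph.get("ontology", "") or ""

    terms: Dict[str, OntologyTerm] = {}
    for node, data in multigraph.nodes(data=True):
        if not data:
            # edge target with no stanza of its own (e.g. an obsolete or
            # missing parent): structurally invalid input
            raise OboParseError(
                f"{source_name}: term {node} is referenced as a parent "
                "but has no [Term] stanza (or is obsolete)"
            )
        parents: List[str] = []
        for child, parent, key in multigraph.out_edges(node, keys=True):
            if key in relations:
                parents.append(parent)
        terms[node] = OntologyTerm(
            term_id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", default_ns),
            parent_ids=tuple(sorted(set(parents))),
            alt_ids=tuple(sorted(data.get("alt_id", []))),
        )
    dag = OntologyDAG(terms)
    logger.info(
        "parsed %s: %d terms, %d edges, %d root(s)",
        source_name, len(dag), len(dag.edges()), len(dag.roots),
    )
    return dag
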