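"""Protein corpus ingestion and the term × domain correspondence matrix.

The statistical input to domain-centric annotation is a corpus of
proteins for which we know both (a) which ontology terms annotate each
protein and (b) which structural domains (SCOP superfamilies/families,
Pfam or InterPro entries) each protein carries.  This module reads the
two standard inputs — GAF 2.x association files and SUPERFAMILY /
InterProScan-style per-domain TSVs — and condenses them into the
correspondence matrix: for every (term t, domain d) pair the number of
proteins ``k(t, d)`` carrying both, together with the marginals
``K(t)`` (proteins with the term), ``n(d)`` (proteins with the domain)
and the universe size ``N``.

Two conventions matter and are applied here:

* protein term sets are closed under ancestors *before* counting, so
  that ``K(parent) >= K(child)`` always holds (True Path Rule);
* a protein contributes at most once to any count, however many copies
  of a domain it carries — the matrix counts proteins, not domain
  occurrences.

The universe ``N`` is the set of proteins present in *both* inputs,
which is the common background Fisher's 2×2 table requires.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Dict, FrozenSet, Iterable, List, Optional, Set, Tuple, Union

from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "GafFormatError",
    "ProteinTermMap",
    "ProteinDomainMap",
    "CorrespondenceMatrix",
    "read_gaf",
    "read_domain_assignments",
    "build_correspondence_matrix",
]

#: recognised domain classification systems
DOMAIN_TYPES = ("SCOP-SF", "SCOP-FA", "Pfam", "InterPro", "other")


class GafFormatError(ValueError):
    """Raised for structurally invalid GAF input, with the line number."""


@dataclass
class ProteinTermMap:
    """protein_id → set of ontology term identifiers (direct annotations)."""

    annotations: Dict[str, Set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.annotations)

    def proteins(self) -> Set[str]:
        return set(self.annotations)


@dataclass
class ProteinDomainMap:
    """protein_id → set of domain identifiers (presence/absence).

    ``n_rejected`` counts input rows dropped for having a blank protein
    or domain field.
    """

    assignments: Dict[str, Set[str]] = field(default_factory=dict)
    domain_type: str = "other"
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.assignments)

    def proteins(self) -> Set[str]:
        return set(self.assignments)


@dataclass
class CorrespondenceMatrix:
    """Sparse term × domain co-occurrence counts with marginals.

    ``k[(t, d)]`` — proteins annotated with term ``t`` AND carrying
    domain ``d``; ``K[t]`` and ``n[d]`` are the marginal protein counts
    and ``N`` the size of the joint protein universe.  Zero cells are
    not stored.
    """

    term_ids: List[str]
    domain_ids: List[str]
    k: Dict[Tuple[str, str], int]
    K: Dict[str, int]
    n: Dict[str, int]
    N: int
    domain_type: str = "other"

    def get_k(self, term_id: str, domain_id: str) -> int:
        return self.k.get((term_id, domain_id), 0)

    def validate(self) -> None:
        """Check the count consistency invariants; raise ``ValueError`` if violated."""
        for (t, d), kv in self.k.items():
            if not (0 <= kv <= min(self.K[t], self.n[d]) <= self.N):
                raise ValueError(
                    f"inconsistent counts for ({t}, {d}): "
                    f"k={kv}, K={self.K[t]}, n={self.n[d]}, N={self.N}"
                )

    def write_triplets(self, path: Union[str, Path]) -> None:
        """Dump non-zero cells as a (term_id, domain_id, k) TSV."""
        lines = ["term_id\tdomain_id\tk"]
        lines += [f"{t}\t{d}\t{v}" for (t, d), v in sorted(self.k.items())]
        Path(path).write_text("\n".join(lines) + "\n")

    def write_marginals(self, path: Union[str, Path]) -> None:
        """Dump K and n marginals plus N as a three-column TSV."""
        lines = [f"# N={self.N}", "kind\tid\tcount"]
        lines += [f"term\t{t}\t{v}" for t, v in sorted(self.K.items())]
        lines += [f"domain\t{d}\t{v}" for d, v in sorted(self.n.items())]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _iter_lines(source: Union[str, Path, IO[str]]):
    if hasattr(source, "read"):
        yield from source
    else:
        with open(source, "rt") as fh:
            yield from fh


def read_gaf(
    source: Union[str, Path, IO[str]],
    evidence_exclude: Iterable[str] = (),
) -> ProteinTermMap:
    """Read a GAF 2.x association file into a :class:`ProteinTermMap`.

    The protein identifier is taken from column 2 (DB Object ID) and the
    term from column 5.  Rows whose qualifier (column 4) contains the
    ``NOT`` operator are negative annotations and are dropped, as are
    rows whose evidence code (column 7) is in ``evidence_exclude``
    (e.g. ``{"IEA"}`` to ignore electronic annotations).  Comment lines
    starting with ``!`` are skipped.

    Raises
    ------
    GafFormatError
        If a data row has fewer than the 15 tab-separated columns every
        GAF version guarantees; the message names the line number.
    """
    excluded = frozenset(evidence_exclude)
    annotations: Dict[str, Set[str]] = {}
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.split("\t")
        if len(fields) < 15:
            raise GafFormatError(
                f"line {lineno}: expected >= 15 tab-separated GAF columns, "
                f"got {len(fields)}"
            )
        protein, qualifier, term, evidence = (
            fields[1], fields[3], fields[4], fields[6],
        )
        if not protein or not term:
            raise GafFormatError(
                f"line {lineno}: empty protein or term identifier"
            )
        if "NOT" in qualifier.split("|"):
            continue
        if evidence in excluded:
            continue
        annotations.setdefault(protein, set()).add(term)
    return ProteinTermMap(annotations=annotations)


_HEADER_TOKENS = {
    "protein", "protein_id", "proteinid", "seqid", "accession",
    "domain", "domain_id", "domainid", "family", "superfamily",
}


def _looks_like_header(fields: List[str]) -> bool:
    return any(f.strip().lower() in _HEADER_TOKENS for f in fields[:2])


def read_domain_assignments(
    source: Union[str, Path, IO[str]],
    domain_type: str = "other",
) -> ProteinDomainMap:
    """Read a protein→domain assignment TSV into a :class:`ProteinDomainMap`.

    Expects one row per domain occurrence with ``protein_id`` in the
    first column and ``domain_id`` in the second; any further columns
    (coordinates, e-values, ...) are ignored.  A header row is detected
    by its field names and skipped.  Repeated (protein, domain) rows
    collapse to a single presence — the downstream model counts
    proteins, not copies.  Rows with a blank protein or domain field are
    rejected and counted in ``n_rejected``.

    Raises
    ------
    ValueError
        If the input contains no usable data rows.
    """
    assignments: Dict[str, Set[str]] = {}
    n_rejected = 0
    first_data_row = True
    for raw in _iter_lines(source):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if first_data_row:
            first_data_row = False
            if _looks_like_header(fields):
                continue
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            n_rejected += 1
            continue
        assignments.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    if not assignments:
        raise ValueError("domain assignment input contains no usable rows")
    if n_rejected:
        logger.warning("rejected %d malformed domain assignment row(s)", n_rejected)
    return ProteinDomainMap(
        assignments=assignments, domain_type=domain_type, n_rejected=n_rejected
    )


# ---------------------------------------------------------------------------
# correspondence matrix
# ---------------------------------------------------------------------------

def build_correspondence_matrix(
    ptm: ProteinTermMap,
    pdm: ProteinDomainMap,
    dag: Optional[OntologyDAG] = None,
    close_terms: bool = True,
) -> CorrespondenceMatrix:
    """Count protein co-occurrence of terms and domains over the joint universe.

    The universe is the set of proteins present in both maps.  When an
    ontology is supplied, each protein's term set is first resolved
    (alt_ids mapped to primary identifiers) and closed under ancestors,
    so the resulting marginals respect the True Path Rule.

    Raises
    ------
    ValueError
        If the two maps share no protein.
    KeyError
        If a protein annotation references a term unknown to ``dag``.
    """
    joint = sorted(ptm.proteins() & pdm.proteins())
    if not joint:
        raise ValueError(
            "protein universes of annotations and domain assignments are disjoint"
        )
    k: Counter = Counter()
    K: Counter = Counter()
    n: Counter = Counter()
    for protein in joint:
        term_set = set(ptm.annotations[protein])
        if dag is not None:
            term_set = {dag.resolve(t) for t in term_set}
            if close_terms:
                term_set = dag.close_term_set(term_set)
        domain_set = pdm.assignments[protein]
        for t in term_set:
            K[t] += 1
        for d in domain_set:
            n[d] += 1
        for t in term_set:
            for d in domain_set:
                k[(t, d)] += 1
    matrix = CorrespondenceMatrix(
        term_ids=sorted(K),
        domain_ids=sorted(n),
        k=dict(k),
        K=dict(K),
        n=dict(n),
        N=len(joint),
        domain_type=pdm.domain_type,
    )
    matrix.validate()
    logger.info(
        "correspondence matrix: %d terms x %d domains over %d proteins "
        "(%d non-zero cells)",
        len(matrix.term_ids), len(matrix.domain_ids), matrix.N, len(matrix.k),
    )
    return matrix
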