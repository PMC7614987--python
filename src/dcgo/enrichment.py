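"""Domain-based ontology enrichment analysis.

Given a user list of protein domains and a reference annotation table
(domain → term mappings, e.g. a dcGO-style build), find the ontology
terms whose annotated-domain sets are over-represented in the input.
The statistical machinery is the same hypergeometric model used during
annotation inference, with the roles recast: the universe ``N`` is the
set of reference-annotated domains (of the matched domain type), each
term contributes ``K`` annotated domains, the usable input is the draw
of size ``n``, and ``k`` is the overlap.  Terms are reported with a
z-score, one-sided p-value, BH FDR, the overlap count and the member
domains realising it.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, IO, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .inference import AnnotationTable, bh_adjust, fisher_one_sided, hypergeom_strength
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRequest",
    "EnrichmentResult",
    "read_domain_list",
    "resolve_input",
    "enrich",
    "top_terms",
    "write_report",
    "read_report",
]

REPORT_COLUMNS = ("term_id", "term_name", "z", "p", "fdr", "num", "members")


@dataclass
class EnrichmentRequest:
    """Parameters of one enrichment run.

    ``background`` optionally replaces the default universe (all
    reference-annotated domains) with a user-supplied domain set.
    ``test_all_terms`` includes terms with zero input overlap in the BH
    family; by default only terms annotating at least one usable input
    domain are tested.
    """

    input_domains: Sequence[str]
    domain_type: str = "other"
    namespace: Optional[str] = None
    fdr_threshold: float = 0.05
    min_overlap: int = 1
    top_n: int = 5
    background: Optional[Sequence[str]] = None
    test_all_terms: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold <= 1.0):
            raise ValueError(
                f"fdr_threshold must be in (0, 1], got {self.fdr_threshold}"
            )
        if self.min_overlap < 1:
            raise ValueError(f"min_overlap must be >= 1, got {self.min_overlap}")
        if not self.deduplicated_input():
            raise ValueError("input domain list is empty after deduplication")

    def deduplicated_input(self) -> List[str]:
        """Input identifiers, first-occurrence order, duplicates removed."""
        seen: Set[str] = set()
        out: List[str] = []
        for d in self.input_domains:
            d = d.strip()
            if d and d not in seen:
                seen.add(d)
                out.append(d)
        return out


@dataclass
class EnrichmentResult:
    """One enriched term: statistics plus the overlapping member domains."""

    term_id: str
    term_name: str
    z: float
    p: float
    fdr: float
    num: int
    members: List[str] = field(default_factory=list)


def read_domain_list(source: Union[str, Path, IO[str]]) -> List[str]:
    """Read a plain-text domain list (one identifier per line, ``#`` comments)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    out: List[str] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def resolve_input(
    request: EnrichmentRequest, reference: AnnotationTable
) -> Tuple[List[str], List[str]]:
    """Split the deduplicated input into reference-known and unknown domains.

    Unknown identifiers are returned (and logged), never silently
    dropped — a large dropped set usually signals a mismatched domain
    type.

    Raises
    ------
    ValueError
        If the reference is empty or no input domain is usable.
    """
    if len(reference) == 0:
        raise ValueError("reference annotation table is empty")
    known = set(reference.domains())
    deduped = request.deduplicated_input()
    usable = [d for d in deduped if d in known]
    dropped = [d for d in deduped if d not in known]
    if dropped:
        logger.warning(
            "%d input domain(s) absent from the reference: %s",
            len(dropped), ", ".join(dropped),
        )
    if not usable:
        raise ValueError(
            "none of the input domains occur in the reference annotation table"
        )
    return usable, dropped


def _term_annotation_sets(
    reference: AnnotationTable,
    dag: Optional[OntologyDAG],
    namespace: Optional[str],
) -> Tuple[Dict[str, Set[str]], Dict[str, str]]:
    """term → annotated domain set and term → name, namespace-filtered."""
    domains_by_term: Dict[str, Set[str]] = {}
    names: Dict[str, str] = {}
    for (d, t), rec in reference.records.items():
        if namespace is not None and dag is not None:
            term = dag.terms.get(t)
            if term is None or term.namespace != namespace:
                continue
        domains_by_term.setdefault(t, set()).add(d)
        names.setdefault(t, rec.term_name)
    return domains_by_term, names


def enrich(
    request: EnrichmentRequest,
    reference: AnnotationTable,
    dag: Optional[OntologyDAG] = None,
) -> List[EnrichmentResult]:
    """Run the domain-based enrichment analysis.

    Returns the terms with ``fdr < request.fdr_threshold`` and overlap
    ``k >= request.min_overlap``, sorted by FDR ascending, ties broken
    by z-score descending and then term identifier.  A threshold of
    exactly 1 disables the significance filter and reports every tested
    term (useful for overlap inspection).  Passing ``dag`` together
    with ``request.namespace`` restricts the tested terms to one
    sub-ontology.

    Raises
    ------
    ValueError
        If no input domain is usable, or the usable input is larger
        than the domain universe (wrong domain type or background).
    """
    usable, _dropped = resolve_input(request, reference)
    domains_by_term, names = _term_annotation_sets(
        reference, dag, request.namespace
    )
    if request.background is not None:
        universe = {d.strip() for d in request.background if d.strip()}
        outside = [d for d in usable if d not in universe]
        if outside:
            raise ValueError(
                f"{len(outside)} usable input domain(s) exceed the background "
                f"universe ({', '.join(outside)}); check the domain type or "
                "background list"
            )
        domains_by_term = {
            t: ds & universe for t, ds in domains_by_term.items() if ds & universe
        }
    else:
        universe = set().union(*domains_by_term.values()) if domains_by_term else set()
    if not domains_by_term:
        # nothing annotated in the requested namespace/background
        return []
    N = len(universe)
    n = len(usable)
    if N < n:
        raise ValueError(
            f"usable input ({n} domains) exceeds the reference universe ({N}); "
            "check the domain type"
        )
    input_set = set(usable)

    tested: List[Tuple[str, Set[str]]] = sorted(
        (
            (t, ds & input_set)
            for t, ds in domains_by_term.items()
            if request.test_all_terms or (ds & input_set)
        ),
        key=lambda item: item[0],
    )
    if not tested:
        return []

    pvalues: List[float] = []
    zscores: List[float] = []
    for t, overlap in tested:
        K = len(domains_by_term[t])
        k = len(overlap)
        pvalues.append(fisher_one_sided(k, K, n, N))
        zscores.append(hypergeom_strength(k, K, n, N))
    fdrs = bh_adjust(pvalues)

    results = [
        EnrichmentResult(
            term_id=t,
            term_name=names.get(t, ""),
            z=z,
            p=p,
            fdr=q,
            num=len(overlap),
            members=sorted(overlap),
        )
        for (t, overlap), p, q, z in zip(tested, pvalues, fdrs, zscores)
        if (q < request.fdr_threshold or request.fdr_threshold >= 1.0)
        and len(overlap) >= request.min_overlap
    ]
    results.sort(key=lambda r: (r.fdr, -r.z, r.term_id))
    logger.info(
        "enrichment: %d/%d tested terms significant at FDR < %s (n=%d, N=%d)",
        len(results), len(tested), request.fdr_threshold, n, N,
    )
    return results


def top_terms(
    results: Sequence[EnrichmentResult], top_n: int
) -> List[EnrichmentResult]:
    """First ``min(top_n, len(results))`` entries of an already-sorted result list."""
    if top_n < 0:
        raise ValueError("top_n must be non-negative")
    return list(results[:top_n])


# ---------------------------------------------------------------------------
# report I/O
# ---------------------------------------------------------------------------

def _dotplot_path(path: Path) -> Path:
    if path.suffix:
        return path.with_suffix(".dotplot" + path.suffix)
    return path.with_name(path.name + ".dotplot")


def write_report(
    results: Sequence[EnrichmentResult],
    request: EnrichmentRequest,
    path: Union[str, Path],
) -> Tuple[Path, Path]:
    """Write the enrichment report TSV plus dot-plot companion data.

    The main TSV has one row per enriched term with members comma
    joined; the companion ``*.dotplot.tsv`` carries (term_id, z, fdr)
    for the ``request.top_n`` leading terms, ready for plotting.  Empty
    result lists produce header-only files.  Writes are atomic.
    Returns the two paths written.
    """
    path = Path(path)
    lines = ["\t".join(REPORT_COLUMNS)]
    for r in results:
        lines.append(
            "\t".join(
                (
                    r.term_id,
                    r.term_name,
                    repr(r.z),
                    repr(r.p),
                    repr(r.fdr),
                    str(r.num),
                    ",".join(r.members),
                )
            )
        )
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text("\n".join(lines) + "\n")
    os.replace(tmp, path)

    dot_path = _dotplot_path(path)
    dot_lines = ["term_id\tz\tfdr"]
    for r in top_terms(results, request.top_n):
        dot_lines.append(f"{r.term_id}\t{r.z!r}\t{r.fdr!r}")
    tmp = dot_path.with_name(dot_path.name + ".tmp")
    tmp.write_text("\n".join(dot_lines) + "\n")
    os.replace(tmp, dot_path)
    return path, dot_path


def read_report(path: Union[str, Path]) -> List[EnrichmentResult]:
    """Parse a report TSV back into :class:`EnrichmentResult` objects."""
    results: List[EnrichmentResult] = []
    lines = Path(path).read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != REPORT_COLUMNS:
        raise ValueError(f"{path}: not an enrichment report")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(REPORT_COLUMNS):
            raise ValueError(
                f"{path}:{lineno}: expected {len(REPORT_COLUMNS)} columns"
            )
        members = fields[6].split(",") if fields[6] else []
        results.append(
            EnrichmentResult(
                term_id=fields[0],
                term_name=fields[1],
                z=float(fields[2]),
                p=float(fields[3]),
                fdr=float(fields[4]),
                num=int(fields[5]),
                members=members,
            )
        )
    return results
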