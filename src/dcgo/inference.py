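"""Inference of domain→term annotations from a correspondence matrix.

For every (term, domain) cell of the correspondence matrix the null
hypothesis is that the ``n`` proteins carrying the domain are an
unbiased draw from the ``N``-protein universe with respect to the
``K`` proteins annotated with the term.  The observed overlap ``k``
is then hypergeometric, and three quantities summarise the evidence
for a genuine domain→term association:

* a one-sided Fisher's exact p-value, ``p = P(X >= k)`` with
  ``X ~ Hypergeometric(N, K, n)`` — an exact tail sum, no normal
  approximation;
* a Benjamini–Hochberg FDR across all tested cells of the build;
* a hypergeometric strength ``s = (k - mu) / sigma`` (the z-form of the
  same distribution), min–max rescaled over the significant records
  into an annotation score in [1, 100].

Significant direct annotations are finally propagated to all ancestor
terms under the True Path Rule, carrying the maximal supporting score
upward so scores never decrease toward the ontology root.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .corpus import CorrespondenceMatrix
from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationRecord",
    "AnnotationTable",
    "fisher_one_sided",
    "bh_adjust",
    "hypergeom_strength",
    "rescale_scores",
    "infer_annotations",
    "propagate_annotations",
    "write_annotation_table",
    "read_annotation_table",
]

#: column order of the annotation-table TSV
TABLE_COLUMNS = (
    "domain_id", "domain_type", "term_id", "term_name", "p", "fdr", "score", "origin",
)


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def _check_counts(k: int, K: int, n: int, N: int) -> None:
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    if N < 1:
        raise ValueError(f"universe size N must be >= 1, got {N}")
    if K > N or n > N:
        raise ValueError(f"marginals exceed universe: K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K={K}, n={n})")


def fisher_one_sided(k: int, K: int, n: int, N: int) -> float:
    """One-sided (over-representation) Fisher exact p-value.

    Returns ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``: the
    probability that ``n`` proteins drawn without replacement from a
    universe of ``N`` (of which ``K`` carry the term) share at least
    ``k`` with the term.  Computed as an exact tail sum via
    ``scipy.stats.hypergeom``.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    ``adj_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    capped at 1; each adjusted value is attached to its own p, so the
    output is invariant (up to matching reorder) under permutation of
    the input.
    """
    ps = list(pvalues)
    if not ps:
        return []
    arr = np.asarray(ps, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1) or np.any(~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = multipletests(arr, method="fdr_bh")[1]
    return [float(a) for a in adjusted]


def hypergeom_strength(k: int, K: int, n: int, N: int) -> float:
    """Hypergeometric z-form strength ``s = (k - mu) / sigma``.

    ``mu = nK/N`` and ``sigma^2 = n (K/N)(1 - K/N)(N - n)/(N - 1)`` are
    the mean and variance of the hypergeometric overlap.  Degenerate
    cells (``sigma = 0``, including ``N < 2``) return ``s = 0``.
    """
    _check_counts(k, K, n, N)
    if N < 2:
        return 0.0
    frac = K / N
    var = n * frac * (1.0 - frac) * (N - n) / (N - 1)
    if var <= 0.0:
        return 0.0
    return (k - n * frac) / math.sqrt(var)


def rescale_scores(strengths: Sequence[float]) -> List[float]:
    """Min–max rescale raw strengths into annotation scores in [1, 100].

    ``score = 1 + 99 (s - s_min) / (s_max - s_min)`` over the given
    (significant) set; if all strengths coincide every score is 100.
    """
    ss = list(strengths)
    if not ss:
        raise ValueError("cannot rescale an empty strength list")
    s_min, s_max = min(ss), max(ss)
    if s_max == s_min:
        return [100.0] * len(ss)
    return [1.0 + 99.0 * (s - s_min) / (s_max - s_min) for s in ss]


# ---------------------------------------------------------------------------
# annotation records and tables
# ---------------------------------------------------------------------------

@dataclass
class AnnotationRecord:
    """One inferred domain→term mapping.

    ``origin`` is ``"direct"`` for associations that were themselves
    significant in the Fisher screen and ``"propagated"`` for records
    created by True-Path-Rule inheritance from a descendant term.
    """

    domain_id: str
    domain_type: str
    term_id: str
    term_name: str = ""
    p: float = 1.0
    fdr: float = 1.0
    s: float = 0.0
    score: float = 1.0
    origin: str = "direct"


@dataclass
class AnnotationTable:
    """All inferred (domain, term) records of one build, ancestor-closed.

    Keys are ``(domain_id, term_id)`` pairs; metadata records build
    provenance (ontology name, domain type, FDR threshold, corpus size
    and bookkeeping counts).
    """

    records: Dict[Tuple[str, str], AnnotationRecord] = field(default_factory=dict)
    metadata: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def add(self, record: AnnotationRecord) -> None:
        self.records[(record.domain_id, record.term_id)] = record

    def domains(self) -> List[str]:
        return sorted({d for d, _ in self.records})

    def terms(self) -> List[str]:
        return sorted({t for _, t in self.records})

    def terms_for_domain(self, domain_id: str) -> List[str]:
        return sorted(t for d, t in self.records if d == domain_id)

    def domains_for_term(self, term_id: str) -> List[str]:
        return sorted(d for d, t in self.records if t == term_id)

    def sorted_records(self) -> List[AnnotationRecord]:
        return [self.records[key] for key in sorted(self.records)]


# ---------------------------------------------------------------------------
# the build: Fisher screen, FDR, scoring, propagation
# ---------------------------------------------------------------------------

def infer_annotations(
    matrix: CorrespondenceMatrix,
    dag: OntologyDAG,
    fdr_threshold: float = 1e-3,
    min_k: int = 1,
    min_K: Optional[int] = None,
    min_n: Optional[int] = None,
    ontology_name: str = "",
) -> AnnotationTable:
    """Infer domain→term annotations from a correspondence matrix.

    Every matrix cell with ``k >= min_k`` (and, when set, marginals
    ``K >= min_K`` and ``n >= min_n``) is Fisher-tested; BH adjustment
    is applied jointly across all tested cells; records with
    ``fdr < fdr_threshold`` are kept as direct annotations, scored
    (strength rescaled to [1, 100] over the significant set) and then
    propagated to all ancestor terms.

    Cells with ``k = 0`` have one-sided p exactly 1 and are never
    tested.  An empty tested set yields an empty table with a warning.
    """
    if not (0.0 < fdr_threshold <= 1.0):
        raise ValueError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    min_k = max(min_k, 1)
    tested: List[Tuple[str, str]] = [
        (t, d)
        for (t, d), kv in sorted(matrix.k.items())
        if kv >= min_k
        and (min_K is None or matrix.K[t] >= min_K)
        and (min_n is None or matrix.n[d] >= min_n)
    ]
    table = AnnotationTable(
        metadata={
            "ontology": ontology_name,
            "domain_type": matrix.domain_type,
            "fdr_threshold": repr(fdr_threshold),
            "corpus_N": str(matrix.N),
            "n_tested_pairs": str(len(tested)),
        }
    )
    if not tested:
        logger.warning("no (term, domain) pairs to test; returning empty table")
        table.metadata["n_direct"] = "0"
        table.metadata["n_total"] = "0"
        return table

    pvalues = [
        fisher_one_sided(matrix.k[(t, d)], matrix.K[t], matrix.n[d], matrix.N)
        for t, d in tested
    ]
    fdrs = bh_adjust(pvalues)

    significant = [
        (pair, p, q)
        for pair, p, q in zip(tested, pvalues, fdrs)
        if q < fdr_threshold
    ]
    if significant:
        strengths = [
            hypergeom_strength(matrix.k[pair], matrix.K[pair[0]], matrix.n[pair[1]], matrix.N)
            for pair, _, _ in significant
        ]
        scores = rescale_scores(strengths)
        for (pair, p, q), s, score in zip(significant, strengths, scores):
            t, d = pair
            table.add(
                AnnotationRecord(
                    domain_id=d,
                    domain_type=matrix.domain_type,
                    term_id=t,
                    term_name=dag.terms[t].name if t in dag.terms else "",
                    p=p,
                    fdr=q,
                    s=s,
                    score=score,
                    origin="direct",
                )
            )
    table.metadata["n_direct"] = str(len(table))
    result = propagate_annotations(table, dag)
    result.metadata["n_total"] = str(len(result))
    logger.info(
        "tested %d pairs, %d direct annotations at FDR < %s, %d after propagation",
        len(tested), len(significant), fdr_threshold, len(result),
    )
    return result


def propagate_annotations(table: AnnotationTable, dag: OntologyDAG) -> AnnotationTable:
    """Propagate annotations to all ancestor terms (True Path Rule).

    For each domain, every strict ancestor of an annotated term receives
    a record.  A propagated record carries the *maximum* score (and
    strength) and the *minimum* p/FDR over the domain's annotated
    descendants of that ancestor — it never understates the support
    below it, so scores are non-decreasing toward the root.  Terms that
    already hold a direct record keep it, with the score raised to the
    propagated value where that is larger.

    Raises
    ------
    KeyError
        If a record references a term absent from the ontology.
    """
    result = AnnotationTable(metadata=dict(table.metadata))
    by_domain: Dict[str, List[AnnotationRecord]] = {}
    for (d, t), rec in table.records.items():
        if t not in dag:
            raise KeyError(f"annotation references unknown ontology term: {t}")
        by_domain.setdefault(d, []).append(rec)

    for domain_id, recs in sorted(by_domain.items()):
        # support arriving at each ancestor from annotated descendants
        inherited: Dict[str, AnnotationRecord] = {}
        for rec in recs:
            for anc in dag.ancestors(rec.term_id):
                prev = inherited.get(anc)
                if prev is None:
                    inherited[anc] = replace(
                        rec,
                        term_id=anc,
                        term_name=dag.terms[anc].name,
                        origin="propagated",
                    )
                else:
                    inherited[anc] = replace(
                        prev,
                        p=min(prev.p, rec.p),
                        fdr=min(prev.fdr, rec.fdr),
                        s=max(prev.s, rec.s),
                        score=max(prev.score, rec.score),
                    )
        direct = {rec.term_id: rec for rec in recs}
        for term_id, rec in direct.items():
            inh = inherited.get(term_id)
            if inh is not None and inh.score > rec.score:
                rec = replace(rec, score=inh.score, s=max(rec.s, inh.s))
            result.add(rec)
        for term_id, rec in inherited.items():
            if term_id not in direct:
                result.add(rec)
    return result


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_annotation_table(table: AnnotationTable, path: Union[str, Path]) -> None:
    """Write an annotation table as TSV with ``#`` provenance headers.

    Rows are sorted by (domain_id, term_id) so re-runs are byte
    identical.  Floats are written with full ``repr`` precision; the
    raw strength ``s`` is derivable from the counts and not serialized.
    The write is atomic (temp file + rename).
    """
    path = Path(path)
    lines = [f"# {key}={value}" for key, value in table.metadata.items()]
    lines.append("\t".join(TABLE_COLUMNS))
    for rec in table.sorted_records():
        lines.append(
            "\t".join(
                (
                    rec.domain_id,
                    rec.domain_type,
                    rec.term_id,
                    rec.term_name,
                    repr(rec.p),
                    repr(rec.fdr),
                    repr(rec.score),
                    rec.origin,
                )
            )
        )
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text("\n".join(lines) + "\n")
    os.replace(tmp, path)


def read_annotation_table(path: Union[str, Path]) -> AnnotationTable:
    """Read an annotation table written by :func:`write_annotation_table`.

    The raw strength column is not stored on disk, so read-back records
    carry ``s = nan``.
    """
    table = AnnotationTable()
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        if raw.startswith("#"):
            body = raw.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                table.metadata[key.strip()] = value.strip()
            continue
        fields = raw.split("\t")
        if not header_seen:
            if tuple(fields) != TABLE_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: unexpected annotation table header: {fields}"
                )
            header_seen = True
            continue
        if len(fields) != len(TABLE_COLUMNS):
            raise ValueError(
                f"{path}:{lineno}: expected {len(TABLE_COLUMNS)} columns, "
                f"got {len(fields)}"
            )
        table.add(
            AnnotationRecord(
                domain_id=fields[0],
                domain_type=fields[1],
                term_id=fields[2],
                term_name=fields[3],
                p=float(fields[4]),
                fdr=float(fields[5]),
                s=float("nan"),
                score=float(fields[6]),
                origin=fields[7],
            )
        )
    if not header_seen:
        raise ValueError(f"{path}: no annotation table header found")
    return table
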