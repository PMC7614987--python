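"""Shared fixtures: tiny hand-built DAGs and random DAG/table generators."""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pytest

from dcgo.inference import AnnotationRecord, AnnotationTable
from dcgo.ontology import OntologyDAG, OntologyTerm


def make_dag(parents: Dict[str, Sequence[str]], namespace: str = "test") -> OntologyDAG:
    """Build an OntologyDAG from a {term: [parent, ...]} description."""
    terms = {
        tid: OntologyTerm(
            term_id=tid, name=f"name of {tid}", namespace=namespace,
            parent_ids=tuple(ps),
        )
        for tid, ps in parents.items()
    }
    return OntologyDAG(terms)


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """c is_a b is_a a."""
    return make_dag({"a": [], "b": ["a"], "c": ["b"]})


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """d is_a {b, c}, b is_a a, c is_a a."""
    return make_dag({"a": [], "b": ["a"], "c": ["a"], "d": ["b", "c"]})


def random_dag(rng: np.random.Generator, n_nodes: int) -> OntologyDAG:
    """A random single-root DAG: each later node picks 1-2 earlier parents."""
    ids = [f"T{i:03d}" for i in range(n_nodes)]
    parents: Dict[str, List[str]] = {ids[0]: []}
    for i in range(1, n_nodes):
        n_par = int(rng.integers(1, min(i, 2) + 1))
        chosen = rng.choice(i, size=n_par, replace=False)
        parents[ids[i]] = [ids[int(j)] for j in chosen]
    return make_dag(parents)


def random_annotation_table(
    rng: np.random.Generator, dag: OntologyDAG, n_domains: int = 3
) -> AnnotationTable:
    """Random direct-only table over the DAG's terms, scores in [1, 100]."""
    table = AnnotationTable(metadata={"domain_type": "other"})
    terms = sorted(dag.terms)
    for i in range(n_domains):
        domain = f"D{i:02d}"
        n_terms = int(rng.integers(1, max(2, len(terms) // 2)))
        chosen = rng.choice(len(terms), size=min(n_terms, len(terms)), replace=False)
        for j in chosen:
            p = float(rng.uniform(0, 1e-3))
            table.add(
                AnnotationRecord(
                    domain_id=domain,
                    domain_type="other",
                    term_id=terms[int(j)],
                    term_name=terms[int(j)],
                    p=p,
                    fdr=min(1.0, p * 10),
                    s=float(rng.uniform(0, 10)),
                    score=float(rng.uniform(1, 100)),
                    origin="direct",
                )
            )
    return table
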