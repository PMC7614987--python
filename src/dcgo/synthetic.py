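"""Synthetic corpora with planted domain–term associations.

Generates a toy ontology (a rooted tree) plus a protein corpus in which
chosen (domain, term) pairs are genuinely associated: proteins carrying
the planted domain receive the planted term at a high within-domain
rate, all other proteins at a low background rate, and unplanted leaf
terms are attached at an independent base rate.  Because the truth is
known, the full build→enrich pipeline can be benchmarked for recovery
of the planted pairs without downloading any real ontology or corpus.

Defaults model a small but statistically honest corpus: 500 proteins,
six domains at 30% prevalence, a depth-3 binary term tree (15 terms,
8 leaves), three planted pairs at within-rate 0.9 versus background
0.05, and a 5% base rate for unplanted leaves.  Planted terms are
always leaves so that ancestor terms acquire their annotations only
through propagation, making the True Path Rule itself testable.

The emitted fixture files use exactly the GAF and domain-TSV dialects
the corpus readers consume, so tests exercise the real parsers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .corpus import ProteinDomainMap, ProteinTermMap
from .ontology import OntologyDAG, OntologyTerm

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedPair",
    "SyntheticSpec",
    "generate_dag",
    "generate_corpus",
    "write_obo",
    "write_gaf",
    "write_domain_tsv",
    "simulate_to_dir",
]

_TERM_FMT = "SYN:{:07d}"


@dataclass(frozen=True)
class PlantedPair:
    """A genuine domain–term association planted into the corpus."""

    domain_id: str
    term_id: str
    within_rate: float = 0.9
    background_rate: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_rate < self.within_rate <= 1.0):
            raise ValueError(
                f"planted pair ({self.domain_id}, {self.term_id}) requires "
                f"0 <= background_rate < within_rate <= 1, got "
                f"{self.background_rate} / {self.within_rate}"
            )


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic corpus.

    ``domain_prevalence`` maps each catalogue domain to its marginal
    probability of occurring on a protein; domains are drawn
    independently (no architecture correlation is modelled) and
    proteins drawing zero domains are redrawn.  All randomness flows
    from ``seed`` through a single generator, so equal specs produce
    byte-identical corpora.
    """

    n_proteins: int = 500
    depth: int = 3
    branching: int = 2
    domain_prevalence: Dict[str, float] = field(
        default_factory=lambda: {f"DM{i:05d}": 0.3 for i in range(1, 7)}
    )
    planted: List[PlantedPair] = field(default_factory=list)
    base_rate: float = 0.05
    domain_type: str = "other"
    seed: int = 0
    max_redraws: int = 100

    @classmethod
    def default(cls, seed: int = 0) -> "SyntheticSpec":
        """The standard benchmark spec: three planted pairs on distinct leaves."""
        spec = cls(seed=seed)
        leaves = sorted(generate_dag(spec.depth, spec.branching).leaves)
        domains = sorted(spec.domain_prevalence)
        spec.planted = [
            PlantedPair(domains[i], leaves[i]) for i in range(3)
        ]
        spec.validate()
        return spec

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not self.domain_prevalence:
            raise ValueError("domain catalogue is empty")
        for d, prev in self.domain_prevalence.items():
            if not (0.0 < prev < 1.0):
                raise ValueError(f"prevalence of {d} must be in (0, 1), got {prev}")
        if not (0.0 <= self.base_rate <= 1.0):
            raise ValueError("base_rate must be in [0, 1]")
        term_ids = set(generate_dag(self.depth, self.branching).terms)
        for pair in self.planted:
            if pair.domain_id not in self.domain_prevalence:
                raise ValueError(f"planted domain {pair.domain_id} not in catalogue")
            if pair.term_id not in term_ids:
                raise ValueError(f"planted term {pair.term_id} not in generated DAG")


def generate_dag(depth: int, branching: int, seed: int = 0) -> OntologyDAG:
    """Generate a complete rooted tree ontology of the given shape.

    The tree has ``sum_{i=0..depth} branching**i`` terms numbered in
    breadth-first order (``SYN:0000001`` is the root).  The structure is
    fully determined by ``depth`` and ``branching``; ``seed`` is
    accepted for interface symmetry with the corpus generator.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must both be >= 1")
    terms: Dict[str, OntologyTerm] = {}
    total = sum(branching**i for i in range(depth + 1))
    for idx in range(1, total + 1):
        tid = _TERM_FMT.format(idx)
        parent_idx = (idx - 2) // branching + 1 if idx > 1 else None
        terms[tid] = OntologyTerm(
            term_id=tid,
            name=f"synthetic term {idx}",
            namespace="synthetic",
            parent_ids=(_TERM_FMT.format(parent_idx),) if parent_idx else (),
        )
    return OntologyDAG(terms)


def generate_corpus(
    spec: SyntheticSpec,
) -> Tuple[ProteinTermMap, ProteinDomainMap, pd.DataFrame]:
    """Draw a protein corpus with the spec's planted associations.

    Each protein independently draws its domain set from the catalogue
    prevalences (redrawn up to ``max_redraws`` times if empty); each
    planted term is then attached with ``within_rate`` to carriers of
    its planted domain and ``background_rate`` to non-carriers, and
    every unplanted leaf term with ``base_rate``.  Proteins ending up
    with no term are present in the domain map but absent from the term
    map (annotation inputs never contain empty term sets).

    Returns the term map, the domain map and the truth table of planted
    pairs as a DataFrame with columns ``domain_id``, ``term_id``,
    ``within_rate``, ``background_rate``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    domains = sorted(spec.domain_prevalence)
    prevalences = np.array([spec.domain_prevalence[d] for d in domains])
    dag = generate_dag(spec.depth, spec.branching)
    planted_terms = {p.term_id for p in spec.planted}
    free_leaves = sorted(dag.leaves - planted_terms)

    term_map: Dict[str, Set[str]] = {}
    domain_map: Dict[str, Set[str]] = {}
    for i in range(spec.n_proteins):
        protein = f"SP{i:06d}"
        for attempt in range(spec.max_redraws + 1):
            mask = rng.random(len(domains)) < prevalences
            if mask.any():
                break
        else:
            raise RuntimeError(
                f"failed to draw a non-empty domain set for {protein} "
                f"after {spec.max_redraws} redraws"
            )
        carried = {d for d, hit in zip(domains, mask) if hit}
        domain_map[protein] = carried
        terms: Set[str] = set()
        for pair in spec.planted:
            rate = pair.within_rate if pair.domain_id in carried else pair.background_rate
            if rng.random() < rate:
                terms.add(pair.term_id)
        for leaf in free_leaves:
            if rng.random() < spec.base_rate:
                terms.add(leaf)
        if terms:
            term_map[protein] = terms

    truth = pd.DataFrame(
        [
            {
                "domain_id": p.domain_id,
                "term_id": p.term_id,
                "within_rate": p.within_rate,
                "background_rate": p.background_rate,
            }
            for p in spec.planted
        ],
        columns=["domain_id", "term_id", "within_rate", "background_rate"],
    )
    logger.info(
        "synthetic corpus: %d proteins (%d annotated), %d domains, %d planted pairs",
        spec.n_proteins, len(term_map), len(domains), len(spec.planted),
    )
    return ProteinTermMap(annotations=term_map), ProteinDomainMap(
        assignments=domain_map, domain_type=spec.domain_type
    ), truth


# ---------------------------------------------------------------------------
# fixture writers (same dialects the corpus readers consume)
# ---------------------------------------------------------------------------

def write_obo(dag: OntologyDAG, path: Union[str, Path]) -> None:
    """Serialize a DAG as a minimal OBO 1.2 flat file."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {term.term_id}")
        lines.append(f"name: {term.name}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        for parent in sorted(term.parent_ids):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_gaf(ptm: ProteinTermMap, path: Union[str, Path]) -> None:
    """Serialize a protein→term map as a 17-column GAF 2.2 file."""
    lines = ["!gaf-version: 2.2"]
    for protein in sorted(ptm.annotations):
        for term in sorted(ptm.annotations[protein]):
            lines.append(
                "\t".join(
                    (
                        "SYN", protein, protein, "", term,
                        "SYN:0000000", "IDA", "", "P", "", "",
                        "protein", "taxon:0", "20230101", "dcgo-synthetic",
                        "", "",
                    )
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_domain_tsv(pdm: ProteinDomainMap, path: Union[str, Path]) -> None:
    """Serialize a protein→domain map as a headered two-column TSV."""
    lines = ["protein_id\tdomain_id"]
    for protein in sorted(pdm.assignments):
        for domain in sorted(pdm.assignments[protein]):
            lines.append(f"{protein}\t{domain}")
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_to_dir(spec: SyntheticSpec, outdir: Union[str, Path]) -> Dict[str, Path]:
    """Generate a corpus and write the four fixture files into ``outdir``.

    Writes ``ontology.obo``, ``corpus.gaf``, ``domains.tsv`` and
    ``truth.tsv``; returns the paths keyed by those names.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag = generate_dag(spec.depth, spec.branching)
    ptm, pdm, truth = generate_corpus(spec)
    paths = {
        "ontology.obo": outdir / "ontology.obo",
        "corpus.gaf": outdir / "corpus.gaf",
        "domains.tsv": outdir / "domains.tsv",
        "truth.tsv": outdir / "truth.tsv",
    }
    write_obo(dag, paths["ontology.obo"])
    write_gaf(ptm, paths["corpus.gaf"])
    write_domain_tsv(pdm, paths["domains.tsv"])
    truth.to_csv(paths["truth.tsv"], sep="\t", index=False)
    return paths
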