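"""Small packaged example datasets.

Ships the dcGO website's enrichment example showcase in machine-usable
form: the 33 Pfam domains annotated to the EFO term 'immune system
disease', and a miniature GOBP reference in which each of the five top
enriched biological-process terms annotates exactly its member domains
from that example.  The mini reference is a stand-in for the full dcGO
Pfam–GOBP annotation table — it contains five terms only and is meant
for demonstrations and overlap-count checks, not for real analyses.
"""

from __future__ import annotations

from importlib import resources
from typing import List

from .enrichment import read_domain_list
from .inference import AnnotationRecord, AnnotationTable

__all__ = ["load_example_pfam_domains", "load_example_gobp_reference"]


def _data_text(name: str) -> str:
    return (resources.files("dcgo") / "data" / name).read_text()


def load_example_pfam_domains() -> List[str]:
    """The 33 Pfam domains of the immune-system-disease example input."""
    import io

    return read_domain_list(io.StringIO(_data_text("immune_pfam_domains.txt")))


def load_example_gobp_reference() -> AnnotationTable:
    """Miniature Pfam→GOBP reference covering the five example terms.

    Statistical fields of the records are placeholders (the mini
    reference stores memberships only); enrichment against it
    reproduces the example's overlap counts and member domains, but not
    the z-scores and FDRs of the full resource, which depend on the
    complete annotation corpus.
    """
    table = AnnotationTable(
        metadata={"ontology": "GOBP (example subset)", "domain_type": "Pfam"}
    )
    for raw in _data_text("gobp_mini_reference.tsv").splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        term_id, term_name, domain_id = raw.split("\t")
        if term_id == "term_id":
            continue
        table.add(
            AnnotationRecord(
                domain_id=domain_id,
                domain_type="Pfam",
                term_id=term_id,
                term_name=term_name,
                p=0.0,
                fdr=0.0,
                s=0.0,
                score=100.0,
                origin="direct",
            )
        )
    return table
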