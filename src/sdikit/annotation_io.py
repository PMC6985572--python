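"""Readers for NCBI gene2go-style annotation tables, label lists and feature TSVs."""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from sdikit.ontology_io import OntologyDag

logger = logging.getLogger(__name__)

#: species name -> NCBI taxonomy identifier(s); first entry is preferred.
TAXON_IDS: dict[str, tuple[str, ...]] = {
    "human": ("9606",),
    "mouse": ("10090",),
    "rat": ("10116",),
    "fly": ("7227",),
    "worm": ("6239",),
    "zebrafish": ("7955",),
    "arabidopsis": ("3702",),
    "yeast": ("559292", "4932"),
}


@dataclass
class GeneAnnotation:
    """A gene's deduplicated set of cellular-component terms."""

    gene_id: str
    terms: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.terms)

    def __post_init__(self):
        if not isinstance(self.terms, frozenset):
            object.__setattr__(self, "terms", frozenset(self.terms))
        if self.n < 1:
            raise ValueError(f"gene {self.gene_id!r} has no terms")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def resolve_taxon(taxon: str) -> tuple[str, ...]:
    """Accept either a species alias from :data:`TAXON_IDS` or a raw tax_id."""
    return TAXON_IDS.get(taxon.lower(), (taxon,))


def parse_gene2go(
    path: str | Path,
    taxon: str,
    dag: OntologyDag,
    exclude_iea: bool = False,
    exclude_not: bool = True,
) -> dict[str, GeneAnnotation]:
    """Parse a gene2go-format file into per-gene deduplicated term sets.

    Column layout: tax_id, GeneID, GO_ID, Evidence, Qualifier, GO_term,
    PubMed, Category (tab-separated, optional leading ``#`` header line).

    A row survives when its tax_id matches `taxon` (species alias or raw
    id), its term resolves (after alt_id mapping) to a node of `dag`, and
    it passes the evidence/qualifier filters. Duplicate (gene, term) pairs
    collapse to one. Genes with zero surviving terms are not emitted.

    Parameters
    ----------
    exclude_iea:
        Drop rows with the IEA (electronic annotation) evidence code.
        Off by default: the headline configuration keeps every code.
    exclude_not:
        Drop NOT-qualified rows (they assert *non*-localization). Default on.
    """
    taxa = set(resolve_taxon(taxon))
    terms_by_gene: dict[str, set[str]] = {}
    malformed = 0

    with _open_text(path) as handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                malformed += 1
                continue
            tax_id, gene_id, go_id, evidence = fields[:4]
            qualifier = fields[4] if len(fields) > 4 else ""
            category = fields[7] if len(fields) > 7 else ""
            if tax_id not in taxa:
                continue
            if category and category != "Component":
                continue
            if exclude_iea and evidence == "IEA":
                continue
            if exclude_not and "NOT" in qualifier.split("|"):
                continue
            canonical = dag.resolve(go_id)
            if canonical is None:
                continue
            terms_by_gene.setdefault(gene_id, set()).add(canonical)

    if malformed:
        logger.warning("skipped %d malformed gene2go rows", malformed)
    if not terms_by_gene:
        logger.warning("no genes with surviving CC terms for taxon %r", taxon)

    return {
        gene: GeneAnnotation(gene_id=gene, terms=frozenset(terms))
        for gene, terms in terms_by_gene.items()
    }


def read_label_list(path: str | Path) -> set[str]:
    """One gene identifier per line; blank lines and ``#`` comments ignored."""
    labels = set()
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                labels.add(line)
    return labels


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Tab-separated feature table with a header row; first column = gene id."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    return df.set_index(df.columns[0])
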