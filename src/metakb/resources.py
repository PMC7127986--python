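"""Loaders for the bundled reference tables.

All external services used for harmonization (gene nomenclature, variant
catalog, ontology lookup, drug registries) are replaced by small bundled
tables with identical lookup semantics, so the whole pipeline runs offline
and reproducibly. Every loader here reads a file shipped under
``metakb/data``; callers may substitute their own paths.
"""

from __future__ import annotations

import csv
from importlib import resources as importlib_resources
from pathlib import Path

from .diseases import OntologyGraph
from .drugs import DrugSynonymChain
from .evidence import EvidenceMap
from .genes import GeneTable
from .model import GenomicInterval
from .variants import ProteinContext


def data_path(name: str) -> Path:
    return Path(str(importlib_resources.files("metakb").joinpath("data", name)))


def _tsv_rows(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"))


def load_gene_table(path=None) -> GeneTable:
    return GeneTable.from_hgnc_json(path or data_path("gene_table.json"))


def load_ontology(path=None) -> OntologyGraph:
    return OntologyGraph.from_json(path or data_path("ontology.json"))


def load_evidence_map(path=None) -> EvidenceMap:
    return EvidenceMap.from_tsv(path or data_path("evidence_map.tsv"))


def load_drug_chain(paths=None) -> DrugSynonymChain:
    if paths is None:
        paths = [data_path("drug_synonyms_primary.tsv"),
                 data_path("drug_synonyms_secondary.tsv")]
    return DrugSynonymChain.from_tsv_paths(paths)


def _interval_from_row(row: dict) -> GenomicInterval:
    """Decode one coordinate row (1-based inclusive) to an internal interval."""
    start, end = int(row["start"]), int(row["end"])
    ref = row.get("ref", "").strip()
    alt = row.get("alt", "").strip()
    ref = "" if ref == "-" else ref.upper()
    alt = "" if alt == "-" else alt.upper()
    if not ref and alt:  # insertion after 1-based `start`
        return GenomicInterval(row["assembly"], row["chromosome"], start, start,
                               "", alt)
    return GenomicInterval(row["assembly"], row["chromosome"], start - 1, end,
                           ref, alt)


def load_coordinate_lookup(path=None) -> dict[tuple[str, str], GenomicInterval]:
    """(gene symbol, lower-cased variant label) -> interval."""
    lookup = {}
    for row in _tsv_rows(path or data_path("coordinate_lookup.tsv")):
        lookup[(row["gene"], row["variant"].strip().lower())] = _interval_from_row(row)
    return lookup


def load_gene_loci(path=None) -> dict[str, GenomicInterval]:
    loci = {}
    for row in _tsv_rows(path or data_path("gene_loci.tsv")):
        loci[row["gene"]] = GenomicInterval(
            row["assembly"], row["chromosome"],
            int(row["start"]) - 1, int(row["end"]))
    return loci


def load_accessions(path=None) -> dict[tuple[str, str], str]:
    return {(r["assembly"], r["chromosome"]): r["accession"]
            for r in _tsv_rows(path or data_path("accessions.tsv"))}


def load_oncotree_map(path=None) -> dict[str, list[tuple[str, bool]]]:
    """Oncotree code -> [(doid, needs_review), ...]; several rows = ambiguous."""
    mapping: dict[str, list[tuple[str, bool]]] = {}
    for row in _tsv_rows(path or data_path("oncotree_doid.tsv")):
        mapping.setdefault(row["oncotree_code"], []).append(
            (row["doid"], row["needs_review"].strip() == "1"))
    return mapping


def load_shorthand(path=None) -> dict[str, dict[str, str]]:
    """source name -> {shorthand -> doid}."""
    table: dict[str, dict[str, str]] = {}
    for row in _tsv_rows(path or data_path("disease_shorthand.tsv")):
        table.setdefault(row["source"], {})[row["shorthand"]] = row["doid"]
    return table


def load_table2_rows(path=None) -> list[dict]:
    """The ERBB2 exon-20 duplication worked-example rows, one per evidence item."""
    return _tsv_rows(path or data_path("table2_erbb2.tsv"))


#: Protein context for the ERBB2 kinase-domain window around the exon-20
#: duplication: residues 770-776 read EAYVMAG.
ERBB2_KINASE_WINDOW = ProteinContext("EAYVMAG", 770)
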