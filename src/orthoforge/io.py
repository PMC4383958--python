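"""Readers and writers for the standard formats.

Protein FASTA (header dialect ``geneID[.variantIndex]``, configurable to
``geneID_variantIndex``), the tab-separated gene table, rooted Newick trees,
OBO ontologies, GAF 2.x annotation files, OrthoXML 0.3 group documents.
Coordinates are 1-based inclusive throughout.  Parsers reject invalid input
rather than repairing it; the only silent-ish normalisation — uppercasing
and '*'-stripping of protein sequences — is logged.
"""

from __future__ import annotations

import io as _stdio
import logging
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.UniProt import GOA
from lxml import etree

from .gofunc import Annotation, GeneOntology
from .groups import HOG
from .types import FormatError, Gene, Genome, SpeciesTree, clean_protein

logger = logging.getLogger(__name__)

ORTHOXML_NS = "http://orthoXML.org/2011/"


# -- FASTA ------------------------------------------------------------------

def _split_header(header: str, variant_sep: str) -> tuple[str, int]:
    if variant_sep in header:
        stem, _, suffix = header.rpartition(variant_sep)
        if stem and suffix.isdigit():
            return stem, int(suffix)
    return header, 1


def read_fasta(path, genome_id: Optional[str] = None,
               variant_sep: str = ".") -> list[tuple[str, int, str]]:
    """Parse protein FASTA into (gene id, variant index, sequence) records.

    Headers follow ``geneID[.variantIndex]``; a missing suffix means variant
    1.  Duplicated (gene, variant) headers and empty sequences are format
    errors.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, variant = _split_header(rec.id, variant_sep)
        if (gene_id, variant) in seen:
            raise FormatError(
                f"{path}: duplicate header for gene {gene_id} variant {variant}")
        seen.add((gene_id, variant))
        seq = clean_protein(str(rec.seq), context=f"{path}:{rec.id}")
        records.append((gene_id, variant, seq))
    return records


def write_fasta(path, genome: Genome) -> None:
    with open(path, "w") as fh:
        for g in sorted(genome.genes, key=lambda g: g.id):
            for vi, seq in enumerate(g.variants):
                header = g.id if len(g.variants) == 1 else f"{g.id}.{vi + 1}"
                fh.write(f">{header}\n{seq}\n")


def attach_sequences(genomes: list[Genome],
                     records: list[tuple[str, int, str]]) -> None:
    """Attach FASTA records to gene-table genes, grouping splice variants."""
    by_gene: dict[str, list[tuple[int, str]]] = {}
    for gene_id, variant, seq in records:
        by_gene.setdefault(gene_id, []).append((variant, seq))
    for gm in genomes:
        for g in gm.genes:
            if g.id in by_gene:
                g.variants = [s for _, s in sorted(by_gene[g.id])]
                if len(g.variants) == 1:
                    g.selected_variant = 0


# -- gene table -------------------------------------------------------------

_REQUIRED_COLUMNS = ["id", "genome", "chromosome", "start", "end", "strand"]


def read_gene_table(path) -> list[Genome]:
    """Read the TSV gene table into Genome objects (sequences unattached).

    Required columns: id, genome, chromosome, start, end, strand; optional:
    subgenome, chr_group.  Rows violating gene invariants raise a row error
    with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    genomes: dict[str, Genome] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            gene = Gene(
                id=row["id"], genome_id=row["genome"],
                chromosome=row["chromosome"],
                start=int(row["start"]), end=int(row["end"]),
                strand=row["strand"],
                subgenome=(row["subgenome"]
                           if "subgenome" in df.columns
                           and pd.notna(row["subgenome"]) else None),
                chromosome_group=(int(row["chr_group"])
                                  if "chr_group" in df.columns
                                  and pd.notna(row["chr_group"]) else None),
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}: line {line}: {exc}") from exc
        gm = genomes.setdefault(gene.genome_id,
                                Genome(id=gene.genome_id,
                                       species_name=gene.genome_id))
        gm.genes.append(gene)
    out = [genomes[k] for k in sorted(genomes)]
    seen: set[str] = set()
    for gm in out:
        gm.sort_genes()
        for g in gm.genes:
            if g.id in seen:
                raise FormatError(f"{path}: duplicate gene id {g.id}")
            seen.add(g.id)
    return out


def write_gene_table(path, genomes: Iterable[Genome]) -> None:
    rows = []
    for gm in genomes:
        for g in gm.genes:
            rows.append({
                "id": g.id, "genome": g.genome_id,
                "chromosome": g.chromosome, "start": g.start, "end": g.end,
                "strand": g.strand, "subgenome": g.subgenome or "",
                "chr_group": g.chromosome_group
                if g.chromosome_group is not None else "",
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- trees ------------------------------------------------------------------

def read_newick(path) -> SpeciesTree:
    """Read a rooted Newick species tree; polytomies and names preserved."""
    text = Path(path).read_text()
    return SpeciesTree.from_newick(text)


# -- OBO --------------------------------------------------------------------

def read_obo(path) -> GeneOntology:
    """Read an OBO 1.2/1.4 ontology into the GO DAG.

    Obsolete terms are excluded; alt_ids resolve to their primary id; both
    is_a and ``relationship: part_of`` edges are kept.  Cycles are an error.
    """
    import obonet

    graph = obonet.read_obo(str(path))
    terms: dict[str, dict] = {}
    is_a: dict[str, set[str]] = {}
    part_of: dict[str, set[str]] = {}
    alt: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        terms[term] = {"name": data.get("name", ""),
                       "namespace": data.get("namespace", "")}
        for a in data.get("alt_id", []):
            alt[a] = term
    for child, parent, kind in graph.edges(keys=True):
        if kind == "is_a":
            is_a.setdefault(child, set()).add(parent)
        elif kind == "part_of":
            part_of.setdefault(child, set()).add(parent)
    return GeneOntology(terms=terms, is_a=is_a, part_of=part_of, alt_ids=alt)


# -- GAF --------------------------------------------------------------------

def read_gaf(path) -> list[Annotation]:
    """Read GAF 2.x annotations; NOT-qualified rows dropped, evidence kept.

    Lines with fewer than 15 columns are skipped with a logged line number.
    """
    good_lines = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("!"):
                good_lines.append(line)
                continue
            if len(line.rstrip("\n").split("\t")) < 15:
                logger.warning("%s: line %d malformed, skipped", path, lineno)
                continue
            good_lines.append(line)
    out = []
    for rec in GOA.gafiterator(_stdio.StringIO("".join(good_lines))):
        if any(q.upper().startswith("NOT") for q in rec["Qualifier"] if q):
            continue
        out.append(Annotation(
            gene_id=rec["DB_Object_ID"], term_id=rec["GO_ID"],
            evidence=rec["Evidence"], origin="curated",
            aspect=rec["Aspect"]))
    return out


def write_gaf(path, annotations: Iterable[Annotation],
              db: str = "orthoforge") -> None:
    """Write annotations as GAF 2.1; inferred rows are flagged in assigned_by."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for a in annotations:
            assigned = "orthoforge-propagation" if a.origin == "inferred" else db
            withfrom = (f"{a.source_gene}:{a.source_term}"
                        if a.origin == "inferred" else "")
            cols = [db, a.gene_id, a.gene_id, "", a.term_id, "", a.evidence,
                    withfrom, a.aspect or "P", "", "", "protein", "", "",
                    assigned, "", ""]
            fh.write("\t".join(cols) + "\n")


# -- OrthoXML ---------------------------------------------------------------

def write_orthoxml(hogs: list[HOG], genomes: list[Genome], path) -> None:
    """Serialize a HOG forest as an OrthoXML 0.3 document.

    The species/database/gene index section is followed by nested
    orthologGroup elements mirroring the HOG structure; two or more sub-HOGs
    under one species child are wrapped in a paralogGroup.  Every member gene
    must belong to one of the supplied genomes.
    """
    known = {g.id for gm in genomes for g in gm.genes}
    for h in hogs:
        missing = h.members - known
        if missing:
            raise FormatError(
                f"HOG {h.id or '?'} members missing from gene index: "
                f"{sorted(missing)[:5]}")

    nsmap = {None: ORTHOXML_NS}
    root = etree.Element("orthoXML", nsmap=nsmap, origin="orthoforge",
                         originVersion="0.1", version="0.3")
    int_id: dict[str, int] = {}
    for gm in sorted(genomes, key=lambda g: g.id):
        sp = etree.SubElement(root, "species", name=gm.id, NCBITaxId="0")
        db = etree.SubElement(sp, "database", name="orthoforge", version="0.1")
        genes_el = etree.SubElement(db, "genes")
        for g in sorted(gm.genes, key=lambda g: g.id):
            int_id[g.id] = len(int_id) + 1
            etree.SubElement(genes_el, "gene", id=str(int_id[g.id]),
                             geneId=g.id, protId=g.id)

    groups_el = etree.SubElement(root, "groups")

    def emit(hog: HOG, parent, top: bool = False) -> None:
        if hog.gene is not None:
            if top:
                # singleton family: wrap so the leaf-level range survives
                el = etree.SubElement(parent, "orthologGroup")
                if hog.id:
                    el.set("id", hog.id)
                etree.SubElement(el, "property", name="TaxRange",
                                 value=hog.root_level)
                parent = el
            etree.SubElement(parent, "geneRef", id=str(int_id[hog.gene]))
            return
        el = etree.SubElement(parent, "orthologGroup")
        if hog.id:
            el.set("id", hog.id)
        etree.SubElement(el, "property", name="TaxRange", value=hog.root_level)
        for child in sorted(hog.children):
            subs = sorted(hog.children[child], key=lambda h: min(h.members))
            if len(subs) == 1:
                emit(subs[0], el)
            else:
                pg = etree.SubElement(el, "paralogGroup")
                for sub in subs:
                    emit(sub, pg)

    for h in hogs:
        emit(h, groups_el, top=True)
    etree.ElementTree(root).write(str(path), xml_declaration=True,
                                  encoding="utf-8", pretty_print=True)


def read_orthoxml(path, species_tree: SpeciesTree) -> list[HOG]:
    """Parse an OrthoXML 0.3 document back into a HOG forest.

    The species tree is needed to re-attach each sub-HOG to the species-tree
    child it descends from; ``read(write(x))`` is structurally identical to
    ``x``.
    """
    ns = {"o": ORTHOXML_NS}
    doc = etree.parse(str(path))
    gene_by_int: dict[str, str] = {}
    genome_by_int: dict[str, str] = {}
    for sp in doc.findall("o:species", ns):
        for g in sp.findall(".//o:gene", ns):
            gene_by_int[g.get("id")] = g.get("geneId")
            genome_by_int[g.get("id")] = sp.get("name")

    nodes = {n.name: n for n in species_tree.preorder()}

    def level_of(hog: HOG) -> str:
        return hog.root_level

    def child_under(parent_level: str, sub: HOG) -> str:
        target = nodes[level_of(sub)]
        for child in nodes[parent_level].children:
            ancestors = species_tree.ancestors(target)
            if child in ancestors:
                return child.name
        raise FormatError(
            f"group level {level_of(sub)} is not below {parent_level}")

    def parse_group(el) -> HOG:
        level = None
        for prop in el.findall("o:property", ns):
            if prop.get("name") == "TaxRange":
                level = prop.get("value")
        if level is None:
            raise FormatError("orthologGroup without TaxRange property")
        subs: list[HOG] = []
        for child_el in el:
            tag = etree.QName(child_el).localname
            if tag == "geneRef":
                gid = child_el.get("id")
                subs.append(HOG(root_level=genome_by_int[gid],
                                gene=gene_by_int[gid]))
            elif tag == "orthologGroup":
                subs.append(parse_group(child_el))
            elif tag == "paralogGroup":
                for sub_el in child_el:
                    if etree.QName(sub_el).localname == "geneRef":
                        gid = sub_el.get("id")
                        subs.append(HOG(root_level=genome_by_int[gid],
                                        gene=gene_by_int[gid]))
                    else:
                        subs.append(parse_group(sub_el))
        if nodes[level].is_leaf and len(subs) == 1 and subs[0].gene is not None:
            # wrapped singleton family
            single = subs[0]
            single.id = el.get("id", "")
            return single
        children: dict[str, list[HOG]] = {}
        for sub in subs:
            children.setdefault(child_under(level, sub), []).append(sub)
        for lst in children.values():
            lst.sort(key=lambda h: min(h.members))
        return HOG(root_level=level, children=children,
                   hog_id=el.get("id", ""))

    hogs = []
    groups_el = doc.find("o:groups", ns)
    if groups_el is not None:
        for el in groups_el.findall("o:orthologGroup", ns):
            hogs.append(parse_group(el))
    return hogs
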