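"""Gene-neighborhood (synteny) matrices around a query gene.

The matrix has ``2w+1`` columns (the query gene at column 0, its chromosomal
neighbours by start coordinate at columns −w…+w) and one row per region: the
query region first, then a region centred on each ortholog of the query,
ordered by increasing taxonomic distance (deepest MRCA with the query genome
first).  Every non-query cell carries a colour class: the set of query-row
columns whose gene is a verified ortholog of the cell's gene.  Classes with
two or more members encode many-to-one and many-to-many relations; the empty
class renders grey.  Cells past a contig edge are empty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .types import Gene, Genome, SpeciesTree


@dataclass(frozen=True)
class SyntenyCell:
    gene_id: Optional[str]
    strand: Optional[str] = None
    color_class: frozenset[int] = frozenset()


@dataclass(frozen=True)
class SyntenyRow:
    genome_id: str
    center_gene: str
    cells: tuple[SyntenyCell, ...]


@dataclass
class SyntenyMatrix:
    window: int
    rows: list[SyntenyRow] = field(default_factory=list)

    @property
    def columns(self) -> list[int]:
        return list(range(-self.window, self.window + 1))

    def to_json(self) -> str:
        doc = {
            "window": self.window,
            "columns": self.columns,
            "rows": [{
                "genome": r.genome_id,
                "center": r.center_gene,
                "cells": [{
                    "column": c,
                    "gene": cell.gene_id,
                    "strand": cell.strand,
                    "color_class": sorted(cell.color_class),
                } for c, cell in zip(self.columns, r.cells)],
            } for r in self.rows],
        }
        return json.dumps(doc, indent=1)

    def to_tsv(self) -> str:
        lines = ["row\tgenome\tcenter\tcolumn\tgene\tstrand\tcolor_class"]
        for i, r in enumerate(self.rows):
            for c, cell in zip(self.columns, r.cells):
                cls = ",".join(map(str, sorted(cell.color_class)))
                lines.append("\t".join(map(str, [
                    i, r.genome_id, r.center_gene, c,
                    cell.gene_id or "", cell.strand or "", cls])))
        return "\n".join(lines) + "\n"


def neighborhood(gene: Gene, w: int, genome: Genome) -> list[Optional[Gene]]:
    """The 2w+1 window of genes around ``gene`` on its chromosome.

    Neighbours are ordered by start coordinate regardless of strand;
    positions past the contig edge are None.
    """
    chrom = [g for g in genome.genes if g.chromosome == gene.chromosome]
    chrom.sort(key=lambda g: (g.start, g.id))
    try:
        center = next(i for i, g in enumerate(chrom) if g.id == gene.id)
    except StopIteration:
        raise ValueError(f"gene {gene.id} is not placed on genome {genome.id}")
    out: list[Optional[Gene]] = []
    for off in range(-w, w + 1):
        i = center + off
        out.append(chrom[i] if 0 <= i < len(chrom) else None)
    return out


def build_synteny_matrix(query_gene: str, w: int, verified_pairs: Iterable,
                         species_tree: SpeciesTree,
                         genomes: list[Genome]) -> SyntenyMatrix:
    """Build the synteny matrix centred on ``query_gene``.

    Rows beyond the query row are centred on each verified ortholog of the
    query, sorted by the depth of the MRCA of the row genome and the query
    genome (deepest first, i.e. most closely related first), ties by genome
    id then gene id.
    """
    gene_by_id = {g.id: g for gm in genomes for g in gm.genes}
    genome_by_id = {gm.id: gm for gm in genomes}
    if query_gene not in gene_by_id:
        raise KeyError(query_gene)

    adj: dict[str, set[str]] = {}
    for pair in verified_pairs:
        a, b = (pair if isinstance(pair, tuple) else (pair.gene_a, pair.gene_b))
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    query = gene_by_id[query_gene]
    qgenome = genome_by_id[query.genome_id]
    window = neighborhood(query, w, qgenome)
    columns = list(range(-w, w + 1))
    col_of_gene = {g.id: c for g, c in zip(window, columns) if g is not None}

    rows = [SyntenyRow(
        genome_id=query.genome_id, center_gene=query.id,
        cells=tuple(
            SyntenyCell(gene_id=g.id if g else None,
                        strand=g.strand if g else None,
                        color_class=frozenset({c}) if g else frozenset())
            for g, c in zip(window, columns)))]

    orthologs = sorted(adj.get(query.id, set()))
    leaf = {l.name: l for l in species_tree.leaves()}

    def row_key(gene_id: str):
        g = gene_by_id[gene_id]
        mrca = species_tree.mrca(leaf[g.genome_id], leaf[query.genome_id])
        return (-species_tree.depth(mrca), g.genome_id, g.id)

    for oid in sorted(orthologs, key=row_key):
        og = gene_by_id[oid]
        ogenome = genome_by_id[og.genome_id]
        cells = []
        for g in neighborhood(og, w, ogenome):
            if g is None:
                cells.append(SyntenyCell(gene_id=None))
                continue
            cls = frozenset(col_of_gene[p] for p in adj.get(g.id, set())
                            if p in col_of_gene)
            cells.append(SyntenyCell(gene_id=g.id, strand=g.strand,
                                     color_class=cls))
        rows.append(SyntenyRow(genome_id=og.genome_id, center_gene=oid,
                               cells=tuple(cells)))
    return SyntenyMatrix(window=w, rows=rows)
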