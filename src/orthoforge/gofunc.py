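"""Gene Ontology propagation across orthologous groups, clade-restricted.

Experimental annotations (evidence codes EXP, IDA, IPI, IMP, IGI, IEP) are
propagated from each annotated member of an orthologous group to the other
members.  To keep lineage-specific terms (say, a nematode developmental stage)
from leaking into clades where they are meaningless, a propagated term must
already be used in at least one literature-based annotation within the target
gene's clade: from the source term's ancestor closure we keep only the terms
attested in the target clade's corpus, and emit the most specific of those.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .types import SpeciesTree

logger = logging.getLogger(__name__)

EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


@dataclass(frozen=True)
class Annotation:
    """A (gene, GO term) association with its evidence and provenance."""

    gene_id: str
    term_id: str
    evidence: str
    origin: str = "curated"          # curated | inferred
    source_gene: Optional[str] = None
    source_term: Optional[str] = None
    aspect: str = ""

    def __post_init__(self) -> None:
        if self.origin == "inferred" and (self.source_gene is None
                                          or self.source_term is None):
            raise ValueError("inferred annotations need propagation provenance")

    @property
    def is_experimental(self) -> bool:
        return self.evidence in EXPERIMENTAL_CODES


class GeneOntology:
    """The GO DAG: is_a and part_of edges, alt_id resolution, ancestor closure."""

    def __init__(self, terms: dict[str, dict], is_a: dict[str, set[str]],
                 part_of: dict[str, set[str]],
                 alt_ids: Optional[dict[str, str]] = None) -> None:
        self.terms = terms
        self._is_a = is_a
        self._part_of = part_of
        self._alt = alt_ids or {}
        self._cache: dict[tuple[str, bool], frozenset[str]] = {}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parents in self._is_a.items():
            g.add_edges_from((child, p) for p in parents)
        for child, parents in self._part_of.items():
            g.add_edges_from((child, p) for p in parents)
        if not nx.is_directed_acyclic_graph(g):
            member = nx.find_cycle(g)[0][0]
            raise ValueError(f"ontology graph contains a cycle through {member}")

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id (primary ids map to themselves)."""
        if term in self.terms:
            return term
        if term in self._alt:
            return self._alt[term]
        raise KeyError(f"unknown GO term {term}")

    def __contains__(self, term: str) -> bool:
        return term in self.terms or term in self._alt

    def parents(self, term: str, with_part_of: bool = False) -> set[str]:
        term = self.resolve(term)
        out = set(self._is_a.get(term, ()))
        if with_part_of:
            out |= self._part_of.get(term, set())
        return out

    def ancestors(self, term: str, with_part_of: bool = False) -> frozenset[str]:
        """Reflexive transitive closure over is_a (and part_of if requested)."""
        term = self.resolve(term)
        key = (term, with_part_of)
        if key not in self._cache:
            seen = {term}
            frontier = [term]
            while frontier:
                nxt = []
                for t in frontier:
                    for p in self.parents(t, with_part_of):
                        if p not in seen:
                            seen.add(p)
                            nxt.append(p)
                frontier = nxt
            self._cache[key] = frozenset(seen)
        return self._cache[key]

    def is_strict_ancestor(self, anc: str, term: str,
                           with_part_of: bool = False) -> bool:
        anc, term = self.resolve(anc), self.resolve(term)
        return anc != term and anc in self.ancestors(term, with_part_of)

    def minimal_terms(self, terms: Iterable[str],
                      with_part_of: bool = False) -> set[str]:
        """The most specific members of a term set (no descendant also present)."""
        ts = {self.resolve(t) for t in terms}
        return {
            t for t in ts
            if not any(o != t and t in self.ancestors(o, with_part_of) for o in ts)
        }


@dataclass
class CladeCorpus:
    """Per-clade sets of GO terms attested by literature-based annotations.

    ``corpora[name]`` holds the exact terms (not their ancestors) used in at
    least one experimental annotation on any gene of the clade.  ``clades``
    lists the configured clade nodes; a genome's clade is the most specific
    configured node whose leaf set contains it.
    """

    tree: SpeciesTree
    clades: list[str]
    corpora: dict[str, set[str]] = field(default_factory=dict)
    _leafsets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.clades:
            node = self.tree.node(name)
            self._leafsets[name] = self.tree.clade_leaf_names(node)
            self.corpora.setdefault(name, set())

    def clade_of(self, genome_id: str) -> Optional[str]:
        """Most specific configured clade containing the genome, if any."""
        best, best_size = None, None
        for name, leafset in self._leafsets.items():
            if genome_id in leafset:
                if best_size is None or len(leafset) < best_size:
                    best, best_size = name, len(leafset)
        return best

    def terms(self, clade: str) -> set[str]:
        return self.corpora[clade]


def build_clade_corpus(annotations: Iterable[Annotation], tree: SpeciesTree,
                       gene_to_genome: dict[str, str],
                       clades: Optional[list[str]] = None) -> CladeCorpus:
    """Collect, per configured clade, the terms used in experimental annotations.

    ``clades`` defaults to every named node of the species tree (leaves
    included), which makes the cumulative-containment property explicit:
    an ancestor clade's corpus contains each descendant clade's corpus.
    """
    if clades is None:
        clades = [n.name for n in tree.preorder() if n.name]
    corpus = CladeCorpus(tree=tree, clades=list(clades))
    for ann in annotations:
        if not ann.is_experimental:
            continue
        genome = gene_to_genome.get(ann.gene_id)
        if genome is None:
            logger.warning("annotation on unknown gene %s ignored", ann.gene_id)
            continue
        for name, leafset in corpus._leafsets.items():
            if genome in leafset:
                corpus.corpora[name].add(ann.term_id)
    return corpus


def propagate(oma_groups, annotations: Iterable[Annotation],
              ontology: GeneOntology, corpus: CladeCorpus,
              gene_to_genome: dict[str, str],
              with_part_of: bool = False) -> list[Annotation]:
    """Infer annotations by clade-restricted propagation within groups.

    For every experimental source annotation (gene ``g_s``, term ``t``) and
    every other group member ``g_t`` in clade ``C``: the candidate set is
    ``ancestors(t) ∩ corpus(C)`` and the minimal (most specific) candidates
    are emitted on ``g_t`` with evidence IEA and full provenance — unless the
    term is already implied by one of ``g_t``'s curated annotations.  Inferred
    annotations never act as sources, so propagation is idempotent.
    """
    ann_list = list(annotations)
    by_gene: dict[str, list[Annotation]] = {}
    for a in ann_list:
        by_gene.setdefault(a.gene_id, []).append(a)

    inferred: list[Annotation] = []
    seen: set[tuple[str, str, str, str]] = set()
    for group in oma_groups:
        members = sorted(group.members)
        sources = [
            a for g in members for a in by_gene.get(g, [])
            if a.is_experimental and a.origin == "curated"
        ]
        for src in sources:
            anc = ontology.ancestors(src.term_id, with_part_of)
            for g_t in members:
                if g_t == src.gene_id:
                    continue
                genome = gene_to_genome.get(g_t)
                clade = corpus.clade_of(genome) if genome else None
                if clade is None:
                    continue
                candidates = anc & corpus.terms(clade)
                if not candidates:
                    continue
                implied = set()
                for existing in by_gene.get(g_t, []):
                    if existing.origin == "curated":
                        implied |= ontology.ancestors(existing.term_id,
                                                      with_part_of)
                for term in sorted(ontology.minimal_terms(candidates,
                                                          with_part_of)):
                    if term in implied:
                        continue
                    key = (g_t, term, src.gene_id, src.term_id)
                    if key in seen:
                        continue
                    seen.add(key)
                    inferred.append(Annotation(
                        gene_id=g_t, term_id=term, evidence="IEA",
                        origin="inferred", source_gene=src.gene_id,
                        source_term=src.term_id, aspect=src.aspect,
                    ))
    return inferred
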