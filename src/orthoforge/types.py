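"""Core domain model: protein sequences, genes, genomes and the species tree.

Coordinates are 1-based and inclusive (GFF convention).  A :class:`Genome`
keeps its genes ordered by (chromosome, start); the ordering is re-established
after every load.  The species tree is rooted; leaf labels are genome ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import dendropy

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """An input file violates its documented dialect or a type invariant."""


_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")
# Ambiguity/rare codes folded into X on input (documented normalisation).
_FOLD_TO_X = str.maketrans({c: "X" for c in "BZJUO"})


def clean_protein(raw: str, context: str = "") -> str:
    """Canonicalise a protein sequence: uppercase, '*' removed, ambiguity → X.

    Lowercase letters and stop characters are accepted with a logged warning;
    anything else raises :class:`FormatError`.  The result is non-empty.
    """
    s = raw.strip()
    if s != s.upper() or "*" in s:
        logger.warning("normalising sequence %s: lowercase/'*' stripped", context)
    s = s.upper().replace("*", "").translate(_FOLD_TO_X)
    bad = set(s) - _VALID_RESIDUES
    if bad:
        raise FormatError(f"invalid residue(s) {sorted(bad)} in sequence {context}")
    if not s:
        raise FormatError(f"empty sequence {context}")
    return s


@dataclass
class Gene:
    """A gene model with coordinates and one or more protein splice variants."""

    id: str
    genome_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    subgenome: Optional[str] = None
    chromosome_group: Optional[int] = None
    variants: list[str] = field(default_factory=list)
    selected_variant: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.id}: bad strand {self.strand!r}")

    @property
    def sequence(self) -> str:
        """The selected splice variant (the only one, if unambiguous)."""
        if not self.variants:
            raise ValueError(f"gene {self.id} has no sequence attached")
        if self.selected_variant is not None:
            return self.variants[self.selected_variant]
        if len(self.variants) == 1:
            return self.variants[0]
        raise ValueError(f"gene {self.id}: multiple variants, none selected")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """An ordered collection of gene models for one genome (or subgenome unit)."""

    id: str
    species_name: str = ""
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort_genes()

    def sort_genes(self) -> None:
        self.genes.sort(key=lambda g: (g.chromosome, g.start, g.id))

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def gene_index(genomes: Iterable[Genome]) -> dict[str, Gene]:
    """Map gene id → Gene over a set of genomes; ids must be globally unique."""
    idx: dict[str, Gene] = {}
    for gm in genomes:
        for g in gm.genes:
            if g.id in idx:
                raise FormatError(f"duplicate gene id {g.id} across genomes")
            idx[g.id] = g
    return idx


def unit_of_map(genomes: Iterable[Genome]) -> dict[str, str]:
    """Map gene id → id of the genome *unit* it was supplied in.

    Subgenome units produced by :func:`orthoforge.homeology.split_subgenomes`
    behave as genomes here, which is what makes the homeology pipeline a plain
    re-use of the ortholog pipeline.
    """
    return {g.id: gm.id for gm in genomes for g in gm.genes}


@dataclass(frozen=True)
class DistanceEstimate:
    """Evolutionary distance in PAM units with its estimation variance (PAM^2)."""

    distance: float
    variance: float

    def __post_init__(self) -> None:
        if self.distance < 0 or self.variance <= 0:
            raise ValueError("distance must be >= 0 and variance > 0")

    @property
    def stderr(self) -> float:
        return self.variance ** 0.5


@dataclass(frozen=True)
class AlignmentHit:
    """A significant local alignment between two genes (1-based inclusive spans)."""

    gene_a: str
    gene_b: str
    score: float
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    identity: float


class TreeNode:
    """Node of the rooted species tree."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None,
                 length: Optional[float] = None) -> None:
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    def add(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.name!r})"


class SpeciesTree:
    """A rooted species tree with named leaves (genome ids).

    Internal nodes are taxonomic ranges and may be named.  Polytomies are
    preserved.  Provides the traversals and MRCA queries that HOG building,
    clade corpora and synteny row ordering need.
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        names = [l.name for l in self.leaves()]
        if len(names) != len(set(names)):
            raise FormatError("duplicate leaf labels in species tree")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
        if tree.is_rooted is False:
            raise FormatError(
                "species tree is explicitly unrooted ([&U]); supply a rooted tree"
            )

        def convert(nd: dendropy.Node) -> TreeNode:
            name = nd.taxon.label if nd.taxon else nd.label
            out = TreeNode(name=name, length=nd.edge.length)
            for ch in nd.child_nodes():
                out.add(convert(ch))
            return out

        return cls(convert(tree.seed_node))

    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            body = ""
            if n.children:
                body = "(" + ",".join(fmt(c) for c in n.children) + ")"
            label = n.name or ""
            length = f":{n.length:g}" if n.length is not None else ""
            return f"{body}{label}{length}"

        return fmt(self.root) + ";"

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return iter(reversed(out))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def node(self, name: str) -> TreeNode:
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def clade_leaf_names(self, node: TreeNode) -> frozenset[str]:
        return frozenset(n.name for n in self._subtree(node) if n.is_leaf)

    @staticmethod
    def _subtree(node: TreeNode) -> Iterator[TreeNode]:
        stack = [node]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def depth(self, node: TreeNode) -> int:
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    def ancestors(self, node: TreeNode) -> list[TreeNode]:
        """Path from ``node`` (inclusive) up to the root (inclusive)."""
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path

    def mrca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        anc_a = set(id(n) for n in self.ancestors(a))
        for n in self.ancestors(b):
            if id(n) in anc_a:
                return n
        raise ValueError("nodes are not in the same tree")

    def validate_against(self, genomes: Iterable[Genome]) -> None:
        """Warn about leaf labels with no loaded genome; error on the converse."""
        leaf_names = {l.name for l in self.leaves()}
        genome_ids = {g.id for g in genomes}
        extra = sorted(leaf_names - genome_ids)
        if extra:
            logger.warning("species-tree leaves without loaded genomes: %s", extra)
        missing = sorted(genome_ids - leaf_names)
        if missing:
            raise FormatError(f"genomes absent from species tree: {missing}")
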