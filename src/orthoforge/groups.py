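"""Phase 3: OMA groups, hierarchical orthologous groups, and branch events.

OMA groups are cliques in the verified-ortholog graph with at most one gene
per genome — extracted greedily (maximum clique being intractable) with
deterministic tie-breaking — and tagged with a fingerprint: the smallest
k-mer shared by all members and found nowhere else in the dataset.

HOGs generalise orthology to taxonomic ranges.  They are built bottom-up on
the rooted species tree: every gene starts as a singleton at its leaf; at
each internal node the child-level HOGs are joined into connected components
wherever enough verified orthologous pairs connect their members across
different children.  The construction is static, so membership at a deeper
taxonomic level is always a subset of membership at any ancestral level.
Walking the resulting forest against the species tree yields per-branch gene
gains, duplications and losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .types import Genome, SpeciesTree, TreeNode


def _pair_ids(pair) -> tuple[str, str]:
    if isinstance(pair, tuple):
        return pair[0], pair[1]
    return pair.gene_a, pair.gene_b


@dataclass
class OMAGroup:
    """A clique of verified orthologs, at most one member per genome."""

    id: int
    members: frozenset[str]
    fingerprint: str = ""


def build_oma_groups(verified_pairs: Iterable, genomes: list[Genome],
                     ) -> list[OMAGroup]:
    """Greedy clique extraction on the verified-ortholog graph.

    Seeds with the highest-degree unassigned gene; extends by the neighbour
    adjacent to all current members and from an unrepresented genome (ties:
    degree descending, then gene id ascending) until no extension is
    possible.  Each gene joins at most one group; only groups of two or more
    members are reported.  Fully deterministic.
    """
    genome_of = {g.id: gm.id for gm in genomes for g in gm.genes}
    adj: dict[str, set[str]] = {}
    for pair in verified_pairs:
        a, b = _pair_ids(pair)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    degree = {g: len(n) for g, n in adj.items()}
    order = sorted(adj, key=lambda g: (-degree[g], g))

    assigned: set[str] = set()
    groups: list[OMAGroup] = []
    for seed in order:
        if seed in assigned:
            continue
        members = [seed]
        used_genomes = {genome_of[seed]}
        pool = set(adj[seed])
        while True:
            eligible = [
                g for g in pool
                if g not in assigned and genome_of[g] not in used_genomes
            ]
            if not eligible:
                break
            nxt = min(eligible, key=lambda g: (-degree[g], g))
            members.append(nxt)
            used_genomes.add(genome_of[nxt])
            pool &= adj[nxt]
        assigned.update(members)
        if len(members) >= 2:
            groups.append(OMAGroup(id=len(groups) + 1,
                                   members=frozenset(members)))
    return groups


def compute_fingerprint(group: OMAGroup, all_sequences: dict[str, str],
                        k: int = 7) -> str:
    """Smallest k-mer shared by every member and absent from every non-member.

    Returns the empty string when no such k-mer exists.
    """
    def kmers(seq: str) -> set[str]:
        return {seq[i:i + k] for i in range(len(seq) - k + 1)}

    shared: Optional[set[str]] = None
    for gene in sorted(group.members):
        shared = kmers(all_sequences[gene]) if shared is None \
            else shared & kmers(all_sequences[gene])
        if not shared:
            return ""
    for gene, seq in all_sequences.items():
        if gene in group.members or not shared:
            continue
        shared -= kmers(seq)
    return min(shared) if shared else ""


class HOG:
    """A hierarchical orthologous group: one node of the nested group tree.

    ``root_level`` names the species-tree node the group is defined for.  A
    leaf-level HOG wraps a single gene; an internal HOG maps each species
    child to the sub-HOGs it contributes (two or more sub-HOGs under one
    child record a duplication on that branch).
    """

    __slots__ = ("id", "root_level", "gene", "children", "_members")

    def __init__(self, root_level: str, gene: Optional[str] = None,
                 children: Optional[dict[str, list["HOG"]]] = None,
                 hog_id: str = "") -> None:
        self.id = hog_id
        self.root_level = root_level
        self.gene = gene
        self.children: dict[str, list[HOG]] = children or {}
        self._members: Optional[frozenset[str]] = None

    @property
    def members(self) -> frozenset[str]:
        if self._members is None:
            if self.gene is not None:
                self._members = frozenset({self.gene})
            else:
                acc: set[str] = set()
                for subs in self.children.values():
                    for h in subs:
                        acc |= h.members
                self._members = frozenset(acc)
        return self._members

    def sub_hogs(self) -> list["HOG"]:
        """Direct sub-HOGs in deterministic (child, min-member) order."""
        out: list[HOG] = []
        for child in sorted(self.children):
            out.extend(sorted(self.children[child], key=lambda h: min(h.members)))
        return out

    def walk(self) -> Iterable["HOG"]:
        yield self
        for sub in self.sub_hogs():
            yield from sub.walk()

    def structure(self):
        """Order-insensitive normal form used for structural comparison."""
        if self.gene is not None:
            return ("gene", self.root_level, self.gene)
        return ("hog", self.root_level, tuple(sorted(
            (child, tuple(sorted(h.structure() for h in subs)))
            for child, subs in self.children.items() if subs)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"HOG({self.id or self.root_level}, {len(self.members)} genes)"


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        while self.parent.setdefault(x, x) != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_hogs(verified_pairs: Iterable, species_tree: SpeciesTree,
               genomes: list[Genome], min_edges: int = 1) -> list[HOG]:
    """Bottom-up HOG construction over the rooted species tree.

    At each internal node, child-level HOGs from *different* children are
    joined when at least ``min_edges`` verified orthologous pairs connect
    their members; connected components become the HOGs of that node.  HOGs
    spanning a single child pass through unchanged, so a family keeps the
    root level where it first spans two children — that node is its gain.
    """
    genome_of = {}
    for gm in genomes:
        leaf_names = {l.name for l in species_tree.leaves()}
        if gm.id not in leaf_names:
            raise ValueError(f"genome {gm.id} absent from species tree")
        for g in gm.genes:
            genome_of[g.id] = gm.id
    pairs = [_pair_ids(p) for p in verified_pairs]

    current: dict[str, list[HOG]] = {}
    gene_hog: dict[str, HOG] = {}
    hog_child: dict[int, TreeNode] = {}  # id(HOG) -> child of current node

    for node in species_tree.postorder():
        if node.is_leaf:
            genome = next((gm for gm in genomes if gm.id == node.name), None)
            hogs = []
            if genome is not None:
                for g in sorted(genome.genes, key=lambda g: g.id):
                    h = HOG(root_level=node.name, gene=g.id)
                    gene_hog[g.id] = h
                    hogs.append(h)
            current[node.name] = hogs
            continue

        entries: list[tuple[TreeNode, HOG]] = []
        for child in node.children:
            for h in current.get(child.name, []):
                entries.append((child, h))
                hog_child[id(h)] = child
        uf = _UnionFind()
        for _, h in entries:
            uf.find(id(h))
        edge_counts: dict[tuple[int, int], int] = {}
        under = {g for _, h in entries for g in h.members}
        for a, b in pairs:
            if a not in under or b not in under:
                continue
            ha, hb = gene_hog[a], gene_hog[b]
            if ha is hb or hog_child[id(ha)] is hog_child[id(hb)]:
                continue
            key = (id(ha), id(hb)) if id(ha) < id(hb) else (id(hb), id(ha))
            edge_counts[key] = edge_counts.get(key, 0) + 1
        for (ia, ib), n in edge_counts.items():
            if n >= min_edges:
                uf.union(ia, ib)

        comps: dict[int, list[tuple[TreeNode, HOG]]] = {}
        for child, h in entries:
            comps.setdefault(uf.find(id(h)), []).append((child, h))
        merged: list[HOG] = []
        for comp in comps.values():
            if len(comp) == 1:
                merged.append(comp[0][1])  # pass through unchanged
                continue
            children: dict[str, list[HOG]] = {}
            for child, h in comp:
                children.setdefault(child.name, []).append(h)
            for subs in children.values():
                subs.sort(key=lambda h: min(h.members))
            new = HOG(root_level=node.name, children=children)
            for g in new.members:
                gene_hog[g] = new
            merged.append(new)
        current[node.name] = merged

    top = sorted(current[species_tree.root.name], key=lambda h: min(h.members))
    for i, h in enumerate(top, start=1):
        h.id = f"HOG:{i:07d}"
        _assign_sub_ids(h)
    return top


def _assign_sub_ids(hog: HOG) -> None:
    for i, sub in enumerate(hog.sub_hogs(), start=1):
        sub.id = f"{hog.id}.{i}"
        _assign_sub_ids(sub)


@dataclass
class BranchEvents:
    """Per-node gains and per-branch duplication/loss counts."""

    gains: dict[str, int] = field(default_factory=dict)
    duplications: dict[tuple[str, str], int] = field(default_factory=dict)
    losses: dict[tuple[str, str], int] = field(default_factory=dict)

    def _bump(self, table: dict, key, n: int = 1) -> None:
        table[key] = table.get(key, 0) + n


def count_events(hogs: list[HOG], species_tree: SpeciesTree) -> BranchEvents:
    """Read gains, duplications and losses off the HOG forest.

    Gains at a node are the top-level HOGs rooted there.  For every HOG node
    and every species child: no contributing sub-HOG means the family copy
    was lost on that branch (absence of a whole sub-clade counts once, at the
    shallowest branch); k >= 2 sub-HOGs mean k-1 duplications.  A sub-HOG
    rooted deeper than the child passed through the intermediate nodes
    unmerged, which records a loss on every side branch along its path.
    """
    nodes = {n.name: n for n in species_tree.preorder()}
    events = BranchEvents()
    for h in hogs:
        events._bump(events.gains, h.root_level)

    def walk(hog: HOG) -> None:
        v = nodes[hog.root_level]
        if v.is_leaf:
            return
        for child in v.children:
            subs = hog.children.get(child.name, [])
            if not subs:
                events._bump(events.losses, (v.name, child.name))
                continue
            if len(subs) > 1:
                events._bump(events.duplications, (v.name, child.name),
                             len(subs) - 1)
            for sub in subs:
                descend(sub, child)

    def descend(hog: HOG, at_node: TreeNode) -> None:
        target = nodes[hog.root_level]
        if target is not at_node:
            path = species_tree.ancestors(target)  # target .. root
            upto = path[:path.index(at_node) + 1]  # target .. at_node
            for m, below in zip(upto[::-1][:-1], upto[::-1][1:]):
                for x in m.children:
                    if x is not below:
                        events._bump(events.losses, (m.name, x.name))
        walk(hog)

    for h in hogs:
        walk(h)
    return events
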