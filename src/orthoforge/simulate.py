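"""Gene-family evolution simulator with planted ground truth.

Families start at the root of a species tree and evolve down it: sequences
mutate under the same PAM-style substitution process the scorer uses (so
estimator calibration is testable), and gene lineages duplicate and die under
a birth--death process with per-PAM rates (Gillespie sampling along each
branch, so event times — and hence sequence divergence of duplicate copies —
are exact).  Duplicates insert adjacent to their template (tandem model);
branch-level inversions reshuffle gene order.  An optional hybridization step
merges two leaf genomes into one allopolyploid with labelled subgenomes and
inherited chromosome groups, optionally planting contaminant gene pairs at a
chosen divergence.  Every sampled event and the full gene tree of every
family are recorded, and true ortholog/paralog/homeolog relations are derived
from the gene trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .matrices import AA20, PamModel
from .types import Gene, Genome, SpeciesTree, TreeNode

logger = logging.getLogger(__name__)

_MODEL = PamModel()
_AA = np.array(list(AA20))


def random_root_sequence(length: int, rng: np.random.Generator) -> str:
    """A sequence drawn from the model's equilibrium residue frequencies."""
    return "".join(rng.choice(_AA, p=_MODEL.pi, size=length))


def mutate_sequence(seq: str, d_pam: float, rng: np.random.Generator) -> str:
    """Evolve a sequence for ``d_pam`` PAM under the substitution model.

    Exact sampling from the closed-form transition matrix: each site keeps its
    residue with probability ``exp(-beta*d)`` and otherwise redraws from the
    equilibrium frequencies (possibly redrawing the same residue, as the
    transition matrix specifies).
    """
    if d_pam < 0:
        raise ValueError("d_pam must be >= 0")
    if d_pam == 0:
        return seq
    arr = np.array(list(seq))
    redraw = rng.random(len(arr)) >= _MODEL.decay(d_pam)
    n = int(redraw.sum())
    if n:
        arr[redraw] = rng.choice(_AA, p=_MODEL.pi, size=n)
    return "".join(arr)


@dataclass(frozen=True)
class HybridizationSpec:
    """Merge two leaf lineages into one allopolyploid genome."""

    progenitor_a: str
    progenitor_b: str
    name: str = "polyploid"
    labels: tuple[str, str] = ("A", "B")
    contaminant_pairs: int = 0
    contaminant_distance: float = 200.0

    def __post_init__(self) -> None:
        if self.progenitor_a == self.progenitor_b:
            raise ValueError("hybridization lineages must be distinct")


@dataclass
class SimulationParams:
    """Study conditions for one simulated dataset."""

    newick: str
    n_families: int = 100
    dup_rate: float = 0.0      # duplications per gene per PAM
    loss_rate: float = 0.0     # losses per gene per PAM
    seq_length: int = 200      # residues
    inversion_rate: float = 0.0  # gene-order inversions per genome per branch
    n_chromosomes: int = 1
    hybridization: Optional[HybridizationSpec] = None
    one_event_per_family: bool = False
    event_probability: float = 0.5  # only in one-event mode
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dup_rate, self.loss_rate, self.inversion_rate) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth: pair relations, per-branch events, per-family gene trees."""

    relations: dict[tuple[str, str], str] = field(default_factory=dict)
    gains: dict[str, int] = field(default_factory=dict)
    duplications: dict[tuple[str, str], int] = field(default_factory=dict)
    losses: dict[tuple[str, str], int] = field(default_factory=dict)
    gene_trees: dict[int, dict] = field(default_factory=dict)
    homeologs: set[tuple[str, str]] = field(default_factory=set)
    contaminants: set[tuple[str, str]] = field(default_factory=set)

    def relation(self, a: str, b: str) -> Optional[str]:
        return self.relations.get((a, b) if a <= b else (b, a))

    def ortholog_pairs(self) -> set[tuple[str, str]]:
        return {p for p, r in self.relations.items() if r == "ortholog"}

    def orthologs_between(self, genes_a: set[str],
                          genes_b: set[str]) -> set[tuple[str, str]]:
        out = set()
        for (x, y), r in self.relations.items():
            if r != "ortholog":
                continue
            if (x in genes_a and y in genes_b) or (x in genes_b and y in genes_a):
                out.add((x, y))
        return out


class _Instance:
    """A gene lineage currently alive at some point of the species tree."""

    __slots__ = ("family", "seq", "node")

    def __init__(self, family: int, seq: str, node: dict) -> None:
        self.family = family
        self.seq = seq
        self.node = node        # its (open) gene-tree node


def _new_node(species: str) -> dict:
    return {"event": None, "species": species, "children": [], "gene_id": None}


class _Simulator:
    def __init__(self, params: SimulationParams) -> None:
        self.p = params
        self.rng = np.random.default_rng(params.seed)
        self.tree = SpeciesTree.from_newick(params.newick)
        counter = 0
        seen = {n.name for n in self.tree.preorder() if n.name}
        for node in self.tree.preorder():
            if node is not self.tree.root and (node.length is None
                                               or node.length < 0):
                raise ValueError("species tree needs non-negative branch lengths")
            if not node.name:  # events are keyed by node name
                counter += 1
                while f"n{counter}" in seen:
                    counter += 1
                node.name = f"n{counter}"
        self.truth = GroundTruth()
        self._leaf_serial: dict[tuple[str, int], int] = {}
        self._planted: dict[int, tuple[str, str, str]] = {}  # fam -> (type, v, c)

    # -- event planting (one-event mode) -----------------------------------
    def _plant_events(self) -> None:
        branches = []
        for node in self.tree.preorder():
            for child in node.children:
                branches.append((node, child))
        loss_ok = [b for b in branches if b[0] is not self.tree.root]
        for fam in range(self.p.n_families):
            if self.rng.random() >= self.p.event_probability:
                continue
            total = self.p.dup_rate + self.p.loss_rate
            p_dup = self.p.dup_rate / total if total > 0 else 0.5
            if self.rng.random() < p_dup:
                v, c = branches[self.rng.integers(len(branches))]
                self._planted[fam] = ("dup", v.name, c.name)
            elif loss_ok:
                # losses on root-adjacent branches leave no outgroup evidence
                # and are unidentifiable; they are not planted
                v, c = loss_ok[self.rng.integers(len(loss_ok))]
                self._planted[fam] = ("loss", v.name, c.name)

    # -- branch evolution ---------------------------------------------------
    def _evolve_branch(self, inst: _Instance, parent: TreeNode,
                       child: TreeNode) -> list[_Instance]:
        """Evolve one lineage along a branch; returns surviving instances."""
        length = child.length or 0.0
        key = (parent.name, child.name)
        if self.p.one_event_per_family:
            planted = self._planted.get(inst.family)
            if planted and planted[1] == parent.name and planted[2] == child.name:
                etype = planted[0]
                if etype == "loss":
                    self.truth.losses[key] = self.truth.losses.get(key, 0) + 1
                    return []
                self.truth.duplications[key] = \
                    self.truth.duplications.get(key, 0) + 1
                mid = mutate_sequence(inst.seq, length / 2, self.rng)
                dup = {"event": "dup", "species": child.name, "children": [],
                       "gene_id": None}
                inst.node["children"].append(dup)
                out = []
                for _ in range(2):
                    tip = _new_node(child.name)
                    dup["children"].append(tip)
                    out.append(_Instance(
                        inst.family,
                        mutate_sequence(mid, length / 2, self.rng), tip))
                return out
            tip = _new_node(child.name)
            inst.node["children"].append(tip)
            return [_Instance(inst.family,
                              mutate_sequence(inst.seq, length, self.rng), tip)]

        # Gillespie birth-death along the branch
        out: list[_Instance] = []
        stack = [(inst.seq, length, inst.node)]
        while stack:
            seq, remaining, parent_node = stack.pop()
            total = self.p.dup_rate + self.p.loss_rate
            while True:
                wait = (self.rng.exponential(1.0 / total)
                        if total > 0 else np.inf)
                if wait >= remaining:
                    tip = _new_node(child.name)
                    parent_node["children"].append(tip)
                    out.append(_Instance(
                        inst.family,
                        mutate_sequence(seq, remaining, self.rng), tip))
                    break
                seq = mutate_sequence(seq, wait, self.rng)
                remaining -= wait
                if self.rng.random() < self.p.loss_rate / total:
                    self.truth.losses[key] = self.truth.losses.get(key, 0) + 1
                    break
                self.truth.duplications[key] = \
                    self.truth.duplications.get(key, 0) + 1
                dup = {"event": "dup", "species": child.name, "children": [],
                       "gene_id": None}
                parent_node["children"].append(dup)
                stack.append((seq, remaining, dup))
                parent_node = dup
                # current lineage continues in the while loop under dup node
        return out

    # -- tree descent -------------------------------------------------------
    def _descend(self, node: TreeNode,
                 state: dict[str, list[_Instance]],
                 genomes: dict[str, Genome]) -> None:
        if node.is_leaf:
            genomes[node.name] = self._materialize(node.name, state)
            return
        for child in node.children:
            child_state: dict[str, list[_Instance]] = {}
            for chrom, instances in state.items():
                row: list[_Instance] = []
                for inst in instances:
                    if inst.node["event"] is None:
                        inst.node["event"] = "spec"
                    row.extend(self._evolve_branch(inst, node, child))
                child_state[chrom] = row
            self._apply_inversions(child_state)
            self._descend(child, child_state, genomes)

    def _apply_inversions(self, state: dict[str, list[_Instance]]) -> None:
        if self.p.inversion_rate <= 0:
            return
        n_inv = self.rng.poisson(self.p.inversion_rate)
        chroms = sorted(state)
        for _ in range(n_inv):
            chrom = chroms[self.rng.integers(len(chroms))]
            row = state[chrom]
            if len(row) < 2:
                continue
            i = int(self.rng.integers(len(row)))
            j = int(self.rng.integers(len(row)))
            i, j = min(i, j), max(i, j)
            row[i:j + 1] = row[i:j + 1][::-1]

    def _materialize(self, leaf: str,
                     state: dict[str, list[_Instance]]) -> Genome:
        genes = []
        for ci, chrom in enumerate(sorted(state)):
            for pos, inst in enumerate(state[chrom]):
                serial = self._leaf_serial.get((leaf, inst.family), 0)
                self._leaf_serial[(leaf, inst.family)] = serial + 1
                gid = f"{leaf}_f{inst.family:04d}" + \
                      (f"_c{serial}" if serial else "")
                inst.node["event"] = "leaf"
                inst.node["gene_id"] = gid
                start = pos * 1000 + 1
                genes.append(Gene(
                    id=gid, genome_id=leaf, chromosome=chrom,
                    start=start, end=start + 3 * len(inst.seq) - 1,
                    strand="+" if self.rng.random() < 0.5 else "-",
                    chromosome_group=ci + 1,
                    variants=[inst.seq], selected_variant=0))
        return Genome(id=leaf, species_name=leaf, genes=genes)

    # -- relations ----------------------------------------------------------
    def _collect_relations(self, node: dict) -> set[str]:
        if node["event"] == "leaf":
            return {node["gene_id"]}
        child_sets = [self._collect_relations(c) for c in node["children"]]
        label = "ortholog" if node["event"] == "spec" else "paralog"
        for i in range(len(child_sets)):
            for j in range(i + 1, len(child_sets)):
                for a in child_sets[i]:
                    for b in child_sets[j]:
                        key = (a, b) if a <= b else (b, a)
                        self.truth.relations[key] = label
        return set().union(*child_sets) if child_sets else set()

    # -- hybridization ------------------------------------------------------
    def _hybridize(self, genomes: dict[str, Genome]) -> None:
        spec = self.p.hybridization
        assert spec is not None
        for prog in (spec.progenitor_a, spec.progenitor_b):
            if prog not in genomes:
                raise ValueError(f"hybridization lineage {prog} is not a leaf")
        merged: list[Gene] = []
        members: dict[str, set[str]] = {}
        for prog, label in zip((spec.progenitor_a, spec.progenitor_b),
                               spec.labels):
            src = genomes.pop(prog)
            members[label] = {g.id for g in src.genes}
            for g in src.genes:
                merged.append(Gene(
                    id=g.id, genome_id=spec.name,
                    chromosome=f"{label}_{g.chromosome}",
                    start=g.start, end=g.end, strand=g.strand,
                    subgenome=label, chromosome_group=g.chromosome_group,
                    variants=list(g.variants),
                    selected_variant=g.selected_variant))
        self.truth.homeologs = {
            p for p in self.truth.orthologs_between(members[spec.labels[0]],
                                                    members[spec.labels[1]])}
        # contaminant pairs: private two-gene families at a planted divergence,
        # placed on mismatched chromosome groups
        n_groups = self.p.n_chromosomes
        for k in range(spec.contaminant_pairs):
            anc = random_root_sequence(self.p.seq_length, self.rng)
            half = spec.contaminant_distance / 2
            ga = f"{spec.name}_contam{k:03d}_a"
            gb = f"{spec.name}_contam{k:03d}_b"
            for gid, label in ((ga, spec.labels[0]), (gb, spec.labels[1])):
                chrom_i = (k + (0 if label == spec.labels[0] else 1)) % n_groups
                start = (self.p.n_families + k) * 1000 + 1
                merged.append(Gene(
                    id=gid, genome_id=spec.name,
                    chromosome=f"{label}_chr{chrom_i + 1}",
                    start=start, end=start + 3 * self.p.seq_length - 1,
                    strand="+", subgenome=label,
                    chromosome_group=chrom_i + 1,
                    variants=[mutate_sequence(anc, half, self.rng)],
                    selected_variant=0))
            self.truth.contaminants.add((ga, gb) if ga <= gb else (gb, ga))
        genomes[spec.name] = Genome(id=spec.name, species_name=spec.name,
                                    genes=merged)

    # -- driver -------------------------------------------------------------
    def run(self) -> tuple[list[Genome], SpeciesTree, GroundTruth]:
        p = self.p
        if p.one_event_per_family:
            self._plant_events()
        root_name = self.tree.root.name or "root"
        self.truth.gains[root_name] = p.n_families
        state: dict[str, list[_Instance]] = {
            f"chr{c + 1}": [] for c in range(p.n_chromosomes)}
        roots = []
        for fam in range(p.n_families):
            seq = random_root_sequence(p.seq_length, self.rng)
            node = _new_node(root_name)
            roots.append(node)
            chrom = f"chr{fam % p.n_chromosomes + 1}"
            state[chrom].append(_Instance(fam, seq, node))
        genomes: dict[str, Genome] = {}
        self._descend(self.tree.root, state, genomes)
        for leaf in self.tree.leaves():
            if not genomes.get(leaf.name) or len(genomes[leaf.name]) == 0:
                logger.warning("lineage %s lost all genes", leaf.name)
                genomes.setdefault(leaf.name,
                                   Genome(id=leaf.name, species_name=leaf.name))
        for fam, node in enumerate(roots):
            self.truth.gene_trees[fam] = node
            self._collect_relations(node)
        if p.hybridization is not None:
            self._hybridize(genomes)
        ordered = [genomes[k] for k in sorted(genomes)]
        return ordered, self.tree, self.truth


def simulate_dataset(params: SimulationParams
                     ) -> tuple[list[Genome], SpeciesTree, GroundTruth]:
    """Generate genomes with planted ground truth; reproducible from the seed."""
    return _Simulator(params).run()


def write_dataset(dirpath, genomes: list[Genome], tree: SpeciesTree,
                  truth: GroundTruth) -> None:
    """Write standard inputs (FASTA, gene table, Newick) plus truth TSVs."""
    from . import io as _io

    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for gm in genomes:
        _io.write_fasta(d / f"{gm.id}.fa", gm)
    _io.write_gene_table(d / "genes.tsv", genomes)
    (d / "species.nwk").write_text(tree.to_newick() + "\n")
    with open(d / "truth_pairs.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\trelation\n")
        for (a, b), rel in sorted(truth.relations.items()):
            fh.write(f"{a}\t{b}\t{rel}\n")
    with open(d / "truth_events.tsv", "w") as fh:
        fh.write("kind\tparent\tchild\tcount\n")
        for node, n in sorted(truth.gains.items()):
            fh.write(f"gain\t\t{node}\t{n}\n")
        for (v, c), n in sorted(truth.duplications.items()):
            fh.write(f"duplication\t{v}\t{c}\t{n}\n")
        for (v, c), n in sorted(truth.losses.items()):
            fh.write(f"loss\t{v}\t{c}\t{n}\n")
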