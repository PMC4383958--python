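"""OMA groups (cliques, fingerprints), HOGs and branch-event counting."""

import itertools

import numpy as np
import pytest

from conftest import make_genome

from orthoforge.groups import (HOG, build_hogs, build_oma_groups,
                               compute_fingerprint, count_events)
from orthoforge.types import SpeciesTree


def _genomes_for(genes: dict[str, str]):
    """genes: gene id -> genome id; sequences are placeholders."""
    by_genome: dict[str, dict[str, str]] = {}
    for gid, gm in genes.items():
        by_genome.setdefault(gm, {})[gid] = "MKVLW"
    return [make_genome(gm, seqs) for gm, seqs in sorted(by_genome.items())]


# -- OMA groups -------------------------------------------------------------

def test_triangle_across_three_genomes_is_one_group():
    genomes = _genomes_for({"a": "A", "b": "B", "c": "C"})
    groups = build_oma_groups([("a", "b"), ("b", "c"), ("a", "c")], genomes)
    assert len(groups) == 1
    assert groups[0].members == {"a", "b", "c"}


def test_path_never_yields_a_non_clique_group():
    genomes = _genomes_for({"a": "A", "b": "B", "c": "C"})
    groups = build_oma_groups([("a", "b"), ("b", "c")], genomes)
    assert len(groups) == 1
    assert groups[0].members in ({"a", "b"}, {"b", "c"})


def _max_constrained_clique(edges, genome_of):
    """Exhaustive oracle: largest clique with at most one gene per genome."""
    vertices = sorted({v for e in edges for v in e})
    adj = {v: set() for v in vertices}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    best = 0
    for r in range(len(vertices), 0, -1):
        if r <= best:
            break
        for combo in itertools.combinations(vertices, r):
            genomes = [genome_of[v] for v in combo]
            if len(set(genomes)) != len(genomes):
                continue
            if all(b in adj[a] for a, b in itertools.combinations(combo, 2)):
                best = r
                break
    return best


def test_greedy_groups_are_valid_and_near_optimal_on_random_graphs():
    rng = np.random.default_rng(21)
    for trial in range(30):
        n = int(rng.integers(4, 13))
        genome_of = {f"g{i}": f"G{i % 4}" for i in range(n)}
        edges = []
        for a, b in itertools.combinations(range(n), 2):
            if rng.random() < 0.45:
                edges.append((f"g{a}", f"g{b}"))
        if not edges:
            continue
        genomes = _genomes_for(genome_of)
        groups = build_oma_groups(edges, genomes)
        adj = {}
        for a, b in edges:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        seen = set()
        for grp in groups:
            # clique property and one gene per genome
            for a, b in itertools.combinations(sorted(grp.members), 2):
                assert b in adj[a]
            gms = [genome_of[m] for m in grp.members]
            assert len(set(gms)) == len(gms)
            assert not (grp.members & seen)  # each gene in at most one group
            seen |= grp.members
        best = _max_constrained_clique(edges, genome_of)
        if groups:
            largest = max(len(g.members) for g in groups)
            assert largest >= best - 2


def test_group_extraction_is_deterministic():
    genomes = _genomes_for({"a": "A", "b": "B", "c": "C", "d": "D"})
    edges = [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")]
    runs = [build_oma_groups(list(edges), genomes) for _ in range(3)]
    assert all([g.members for g in r] == [g.members for g in runs[0]]
               for r in runs)


# -- fingerprints -----------------------------------------------------------

def _brute_force_fingerprint(members, seqs, k=7):
    def kmers(s):
        return {s[i:i + k] for i in range(len(s) - k + 1)}
    shared = set.intersection(*[kmers(seqs[m]) for m in members])
    outside = set().union(*[kmers(s) for g, s in seqs.items()
                            if g not in members]) if len(seqs) > len(members) \
        else set()
    unique = shared - outside
    return min(unique) if unique else ""

FINGERPRINT = "VWQCDTP"


def test_shared_unique_seven_mer_is_the_fingerprint():
    seqs = {"a": "MK" + FINGERPRINT + "LLA", "b": "AA" + FINGERPRINT + "KW",
            "c": FINGERPRINT + "HHHH", "z": "MKLLAAKWHHHH"}
    from orthoforge.groups import OMAGroup
    grp = OMAGroup(id=1, members=frozenset({"a", "b", "c"}))
    assert compute_fingerprint(grp, seqs) == FINGERPRINT
    assert compute_fingerprint(grp, seqs) == \
        _brute_force_fingerprint(grp.members, seqs)


def test_no_common_kmer_gives_empty_fingerprint():
    from orthoforge.groups import OMAGroup
    seqs = {"a": "MKVLWAAHHYY", "b": "CDEFGCDEFGC"}
    grp = OMAGroup(id=1, members=frozenset({"a", "b"}))
    assert compute_fingerprint(grp, seqs) == ""


def test_kmer_shared_with_non_member_is_excluded():
    from orthoforge.groups import OMAGroup
    shared = "VWQCDTP"
    unique = "CCHHKKW"
    seqs = {"a": shared + unique, "b": unique + shared,
            "z": shared + "AAAAAAA"}  # non-member also carries `shared`
    grp = OMAGroup(id=1, members=frozenset({"a", "b"}))
    got = compute_fingerprint(grp, seqs)
    assert got == _brute_force_fingerprint(grp.members, seqs)
    assert shared not in (got,)


# -- HOGs -------------------------------------------------------------------

TREE_AB_C = "((A,B)ab,C)root;"


def test_one_to_one_family_nests_by_clade():
    tree = SpeciesTree.from_newick(TREE_AB_C)
    genomes = _genomes_for({"a": "A", "b": "B", "c": "C"})
    hogs = build_hogs([("a", "b"), ("a", "c"), ("b", "c")], tree, genomes)
    assert len(hogs) == 1
    root_hog = hogs[0]
    assert root_hog.root_level == "root"
    assert root_hog.members == {"a", "b", "c"}
    (ab_sub,) = root_hog.children["ab"]
    assert ab_sub.root_level == "ab"
    assert ab_sub.members == {"a", "b"}


def test_duplication_splits_subtree_level_hogs():
    tree = SpeciesTree.from_newick(TREE_AB_C)
    genomes = _genomes_for({"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                            "c": "C"})
    pairs = [("a1", "b1"), ("a2", "b2"),
             ("a1", "c"), ("a2", "c"), ("b1", "c"), ("b2", "c")]
    hogs = build_hogs(pairs, tree, genomes)
    assert len(hogs) == 1
    root_hog = hogs[0]
    subs = root_hog.children["ab"]
    assert len(subs) == 2   # the two paralogous copies at the (A,B) level
    assert {frozenset(h.members) for h in subs} == \
        {frozenset({"a1", "b1"}), frozenset({"a2", "b2"})}


def test_gene_without_orthologs_stays_a_leaf_singleton():
    tree = SpeciesTree.from_newick(TREE_AB_C)
    genomes = _genomes_for({"a": "A", "b": "B", "lonely": "C"})
    hogs = build_hogs([("a", "b")], tree, genomes)
    singles = [h for h in hogs if h.members == {"lonely"}]
    assert len(singles) == 1
    assert singles[0].root_level == "C"


def test_genome_absent_from_tree_is_an_error():
    tree = SpeciesTree.from_newick(TREE_AB_C)
    genomes = _genomes_for({"q": "Q"})
    with pytest.raises(ValueError, match="Q"):
        build_hogs([], tree, genomes)


def test_hog_ids_follow_the_numbering_scheme(small_world):
    hogs = build_hogs(small_world["orthologs"], small_world["tree"],
                      small_world["genomes"])
    assert all(h.id.startswith("HOG:") and len(h.id) == 11 for h in hogs)
    for h in hogs:
        for i, sub in enumerate(h.sub_hogs(), start=1):
            assert sub.id == f"{h.id}.{i}"


def test_hog_membership_nests_upward(small_world):
    hogs = build_hogs(small_world["orthologs"], small_world["tree"],
                      small_world["genomes"])
    seen = set()
    for top in hogs:
        for sub in top.walk():
            assert sub.members <= top.members
        assert not (top.members & seen)  # one top-level HOG per gene
        seen |= top.members


# -- branch events ----------------------------------------------------------

def test_perfect_one_to_one_families_are_gains_only():
    tree = SpeciesTree.from_newick(TREE_AB_C)
    genomes = _genomes_for({"a": "A", "b": "B", "c": "C"})
    hogs = build_hogs([("a", "b"), ("a", "c"), ("b", "c")], tree, genomes)
    ev = count_events(hogs, tree)
    assert ev.gains == {"root": 1}
    assert ev.duplications == {} and ev.losses == {}


def test_duplication_fixture_counts_one_duplication():
    tree = SpeciesTree.from_newick(TREE_AB_C)
    genomes = _genomes_for({"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                            "c": "C"})
    pairs = [("a1", "b1"), ("a2", "b2"),
             ("a1", "c"), ("a2", "c"), ("b1", "c"), ("b2", "c")]
    ev = count_events(build_hogs(pairs, tree, genomes), tree)
    assert ev.duplications == {("root", "ab"): 1}
    assert ev.losses == {}


def test_absence_in_one_leaf_counts_one_loss_on_its_branch():
    tree = SpeciesTree.from_newick(TREE_AB_C)
    genomes = _genomes_for({"a": "A", "c": "C"})
    ev = count_events(build_hogs([("a", "c")], tree, genomes), tree)
    assert ev.losses == {("ab", "B"): 1}
    assert ev.gains == {"root": 1}


def test_truth_relations_reproduce_planted_events_exactly():
    from orthoforge.simulate import SimulationParams, simulate_dataset

    nwk = "(((A:15,B:15)ab:20,C:30)abc:15,(D:25,E:25)de:20)root;"
    for seed in range(5):
        params = SimulationParams(newick=nwk, n_families=15, dup_rate=0.002,
                                  loss_rate=0.002, seq_length=60, seed=seed,
                                  one_event_per_family=True)
        genomes, tree, truth = simulate_dataset(params)
        hogs = build_hogs(sorted(truth.ortholog_pairs()), tree, genomes)
        ev = count_events(hogs, tree)
        assert dict(ev.duplications) == dict(truth.duplications)
        assert dict(ev.losses) == dict(truth.losses)
        assert ev.gains.get("root", 0) == params.n_families


def test_every_multi_species_family_is_gained_somewhere(small_world):
    hogs = build_hogs(small_world["orthologs"], small_world["tree"],
                      small_world["genomes"])
    ev = count_events(hogs, small_world["tree"])
    tree = small_world["tree"]
    leaves = {l.name for l in tree.leaves()}
    genome_of = {g.id: gm.id for gm in small_world["genomes"]
                 for g in gm.genes}
    multi = sum(1 for h in hogs
                if len({genome_of[m] for m in h.members} & leaves) >= 2)
    assert sum(ev.gains.values()) >= multi
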