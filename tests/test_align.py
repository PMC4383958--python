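"""Alignment, distance estimation, splice variants and the cache."""

import numpy as np
import pytest

from conftest import make_genome, random_protein

from orthoforge.align import (NoHomologyError, StaleCacheError,
                              all_against_all, estimate_distance,
                              export_cache, import_cache, smith_waterman)
from orthoforge.matrices import AA_INDEX
from orthoforge.types import Gene, Genome


# -- independent quadratic Gotoh DP oracle ----------------------------------

def gotoh_local_score(a: str, b: str, matrix: np.ndarray, gap_open: int,
                      gap_extend: int) -> float:
    """Affine-gap local alignment score by the textbook O(nm) recursion.

    A gap of length l costs gap_open + (l-1) * gap_extend.
    """
    n, m = len(a), len(b)
    NEG = -10 ** 9
    M = [[0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[AA_INDEX[a[i - 1]], AA_INDEX[b[j - 1]]]
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0, diag + s)
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return float(best)


def test_smith_waterman_agrees_with_dp_oracle(family):
    rng = np.random.default_rng(42)
    ref = family.reference_matrix
    for _ in range(40):
        la, lb = rng.integers(5, 41, size=2)
        a = random_protein(rng, int(la))
        b = random_protein(rng, int(lb))
        oracle = gotoh_local_score(a, b, ref, family.gap_open,
                                   family.gap_extend)
        hit = smith_waterman(a, b, family)
        assert (hit.score if hit else 0.0) == oracle


def test_self_alignment_scores_full_diagonal(family):
    rng = np.random.default_rng(0)
    seq = random_protein(rng, 120)
    hit = smith_waterman(seq, seq, family)
    expected = sum(family.reference_matrix[AA_INDEX[c], AA_INDEX[c]]
                   for c in seq)
    assert hit.score == expected
    assert hit.span_a == (1, 120) and hit.span_b == (1, 120)
    assert hit.identity == 1.0


def test_all_negative_scores_yield_no_hit(family):
    # at the shallowest matrix every mismatch is strongly negative
    assert smith_waterman("AAAA", "WWWW", family, matrix_index=0) is None


# -- distance estimation ----------------------------------------------------

def test_identical_sequences_sit_at_the_grid_floor(family):
    rng = np.random.default_rng(1)
    seq = random_protein(rng, 200, pi=family.model.pi)
    dist, hit = estimate_distance(seq, seq, family)
    assert dist.distance == family.grid[0]
    assert dist.variance >= 0.25


def test_unrelated_sequences_raise_no_homology(family):
    assert pytest.raises(NoHomologyError, estimate_distance, "AAAA", "WWWW",
                         family)


def test_distance_estimates_increase_with_truth(family, model):
    from orthoforge.simulate import mutate_sequence, random_root_sequence

    rng = np.random.default_rng(3)
    means = []
    for true_d in (20, 60, 120, 180):
        ests = []
        for _ in range(5):
            s = random_root_sequence(2000, rng)
            dist, _ = estimate_distance(s, mutate_sequence(s, true_d, rng),
                                        family)
            ests.append(dist.distance)
        means.append(np.mean(ests))
    assert all(a < b for a, b in zip(means, means[1:]))


def test_likelihood_profile_is_unimodal_for_simulated_pairs(family, model):
    from orthoforge.align import _align
    from orthoforge.simulate import mutate_sequence, random_root_sequence

    rng = np.random.default_rng(4)
    for true_d in (40, 150):
        s = random_root_sequence(3000, rng)
        t = mutate_sequence(s, true_d, rng)
        _, counts, mism = _align(s, t, family, None, None, "a", "b",
                                 local=False)
        ll = [model.pair_log_likelihood(counts, mism, d)
              for d in family.grid]
        k = int(np.argmax(ll))
        assert all(ll[i] < ll[i + 1] for i in range(k))
        assert all(ll[i] > ll[i + 1] for i in range(k, len(ll) - 1))


def test_random_pairs_are_almost_never_significant(family):
    # uniform-composition 100-mers under the default score threshold
    rng = np.random.default_rng(5)
    significant_trials = 0
    for _ in range(100):
        a = random_protein(rng, 100)
        b = random_protein(rng, 100)
        hit = smith_waterman(a, b, family)
        if hit is not None and hit.score >= 130:
            significant_trials += 1
    assert significant_trials <= 1


# -- splice-variant selection ------------------------------------------------

def _two_genome_variant_world(rng):
    anchor = random_protein(rng, 110)
    decoy = random_protein(rng, 160)   # longer but unrelated
    a_gene = Gene(id="a1", genome_id="A", chromosome="chr1", start=1, end=330,
                  strand="+", variants=[decoy, anchor])
    b_gene = Gene(id="b1", genome_id="B", chromosome="chr1", start=1, end=330,
                  strand="+", variants=[anchor], selected_variant=0)
    return [Genome(id="A", genes=[a_gene]), Genome(id="B", genes=[b_gene])]


def test_variant_with_cross_genome_support_wins_over_longest(family):
    from orthoforge.align import select_splice_variants

    genomes = _two_genome_variant_world(np.random.default_rng(6))
    select_splice_variants(genomes, family)
    a_gene = genomes[0].genes[0]
    assert a_gene.selected_variant == 1        # the matching, shorter variant
    assert len(a_gene.variants[1]) < len(a_gene.variants[0])


def test_scoreless_variants_fall_back_to_longest(family):
    from orthoforge.align import select_splice_variants

    rng = np.random.default_rng(7)
    gene = Gene(id="a1", genome_id="A", chromosome="chr1", start=1, end=90,
                strand="+", variants=[random_protein(rng, 50),
                                      random_protein(rng, 80)])
    other = make_genome("B", {"b1": random_protein(rng, 60)})
    select_splice_variants([Genome(id="A", genes=[gene]), other], family)
    assert gene.selected_variant == 1          # longest wins the tie


def test_single_variant_gene_keeps_its_variant(family):
    from orthoforge.align import select_splice_variants

    genomes = [make_genome("A", {"a1": "MKVLWAAHH" * 5}),
               make_genome("B", {"b1": "MKVLWAAHH" * 5})]
    select_splice_variants(genomes, family)
    assert genomes[0].genes[0].selected_variant == 0


# -- all-against-all --------------------------------------------------------

def test_all_against_all_is_symmetric_and_self_pair_free(small_world):
    avr = small_world["avr"]
    for a, b in avr.pairs():
        assert a != b
        assert avr.unit_of(a) != avr.unit_of(b)
        assert avr.distance(a, b) == avr.distance(b, a)
        assert avr.hit(a, b).score == avr.hit(b, a).score


def test_identical_genes_across_genomes_are_retained(family):
    rng = np.random.default_rng(8)
    seq = random_protein(rng, 120, pi=family.model.pi)
    avr = all_against_all([make_genome("A", {"a1": seq}),
                           make_genome("B", {"b1": seq})], family)
    assert list(avr.pairs()) == [("a1", "b1")]


# -- cache export / import ---------------------------------------------------

def test_cache_round_trip_and_incremental_recompute(family, tmp_path):
    rng = np.random.default_rng(9)
    base = random_protein(rng, 120, pi=family.model.pi)
    genomes = [make_genome(gid, {f"{gid.lower()}{i}": base
                                 for i in range(2)})
               for gid in ("A", "B")]
    avr = all_against_all(genomes, family)
    export_cache(avr, genomes, tmp_path / "cache")
    back = import_cache(tmp_path / "cache")
    assert back == avr

    new = make_genome("C", {"c0": base})
    avr2 = all_against_all(genomes + [new], family, cache=back)
    # only A-C and B-C inter-genome pairs plus C's intra pairs are recomputed
    assert avr2.stats["alignments_computed"] == 2 * 2  # |A|*|C| + |B|*|C|
    for a, b in avr.pairs():
        assert avr2.distance(a, b) == avr.distance(a, b)


def test_stale_cache_is_refused(family, tmp_path):
    rng = np.random.default_rng(10)
    seq = random_protein(rng, 120, pi=family.model.pi)
    genomes = [make_genome("A", {"a1": seq}), make_genome("B", {"b1": seq})]
    avr = all_against_all(genomes, family)
    export_cache(avr, genomes, tmp_path / "cache")
    back = import_cache(tmp_path / "cache")
    mutated = make_genome("A", {"a1": seq[:-1] + ("W" if seq[-1] != "W"
                                                  else "Y")})
    with pytest.raises(StaleCacheError):
        all_against_all([mutated, genomes[1]], family, cache=back)


def test_export_refuses_more_than_the_genome_limit(family, tmp_path):
    genomes = [make_genome(f"G{i:02d}", {f"g{i:02d}": "MKVLW" * 10})
               for i in range(51)]
    avr = all_against_all(genomes[:2], family)
    with pytest.raises(ValueError, match="50"):
        export_cache(avr, genomes, tmp_path / "cache")
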