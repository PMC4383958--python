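"""Shared fixtures: scoring family, tiny genome builders, a simulated world."""

from __future__ import annotations

import numpy as np
import pytest

from orthoforge.align import AllVsAllResult, all_against_all
from orthoforge.matrices import AA20, PamModel, build_matrix_family
from orthoforge.pairs import infer_pairs
from orthoforge.simulate import SimulationParams, simulate_dataset
from orthoforge.types import AlignmentHit, DistanceEstimate, Gene, Genome

FIVE_LEAF_NEWICK = "(((A:15,B:15)ab:20,C:30)abc:15,(D:25,E:25)de:20)root;"


@pytest.fixture(scope="session")
def family():
    return build_matrix_family()


@pytest.fixture(scope="session")
def model():
    return PamModel()


def random_protein(rng: np.random.Generator, n: int,
                   pi: np.ndarray | None = None) -> str:
    if pi is None:
        return "".join(rng.choice(list(AA20), size=n))
    return "".join(rng.choice(list(AA20), p=pi, size=n))


def make_genome(genome_id: str, seqs: dict[str, str],
                chromosome: str = "chr1") -> Genome:
    genes = []
    for i, (gid, seq) in enumerate(sorted(seqs.items())):
        start = i * 1000 + 1
        genes.append(Gene(id=gid, genome_id=genome_id, chromosome=chromosome,
                          start=start, end=start + 3 * len(seq) - 1,
                          strand="+", variants=[seq], selected_variant=0))
    return Genome(id=genome_id, species_name=genome_id, genes=genes)


def mkhit(a: str, b: str, score: float = 300.0) -> AlignmentHit:
    return AlignmentHit(gene_a=a, gene_b=b, score=score, span_a=(1, 100),
                        span_b=(1, 100), identity=0.9)


def build_avr(units: dict[str, list[str]],
              distances: dict[tuple[str, str], float],
              variance: float = 1.0,
              intra: dict[tuple[str, str], float] | None = None,
              ) -> AllVsAllResult:
    """Hand-build an all-against-all result from unit membership + distances."""
    avr = AllVsAllResult()
    for unit, genes in units.items():
        avr.register_unit(unit, genes)
    for (a, b), d in distances.items():
        avr.add(mkhit(a, b), DistanceEstimate(distance=d, variance=variance))
    for (a, b), d in (intra or {}).items():
        avr.add_intra(a, b, DistanceEstimate(distance=d, variance=variance))
    return avr


@pytest.fixture(scope="session")
def small_world(family):
    """A simulated 5-genome world with its all-against-all and pairs."""
    params = SimulationParams(newick=FIVE_LEAF_NEWICK, n_families=24,
                              dup_rate=0.002, loss_rate=0.002,
                              seq_length=150, seed=7)
    genomes, tree, truth = simulate_dataset(params)
    avr = all_against_all(genomes, family)
    orthologs, reports = infer_pairs(avr)
    return {"genomes": genomes, "tree": tree, "truth": truth, "avr": avr,
            "orthologs": orthologs, "reports": reports, "params": params}
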