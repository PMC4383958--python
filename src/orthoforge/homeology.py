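"""Homeolog inference in allopolyploids.

Homeologs are pairs of genes that started diverging through the speciation of
the progenitor genomes and were reunited in one nucleus by hybridization —
orthologs between subgenomes.  The polyploid is therefore partitioned into
subgenome units which run through the ordinary ortholog pipeline (including
the witness-of-non-orthology filter, with witnesses drawn from related
diploid genomes and the remaining subgenomes).  Two filters then clean the
candidate set, strictly in order: the witness filter first, then a
distance-outlier filter computed on the witness survivors (pairs more than
``sd_multiplier`` standard deviations above the mean distance are dropped).
Retained pairs are labelled high confidence when both genes sit on the same
chromosome group, low confidence otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

from .align import AllVsAllResult, all_against_all
from .matrices import ScoringMatrixFamily, build_matrix_family
from .pairs import find_candidate_pairs, verify_non_orthology
from .types import DistanceEstimate, Gene, Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HomeologyParams:
    sd_multiplier: float = 2.5
    population_sd: bool = True      # divisor n; False = sample SD (n-1)
    k_tolerance: float = 1.96
    witness_tol: float = 0.0
    witness_use_stderr: bool = True
    witness_se_multiplier: float = 1.96
    min_score: float = 130.0
    min_aln_fraction: float = 0.6


@dataclass(frozen=True)
class HomeologPair:
    """An evaluated inter-subgenome pair with its filtering outcome."""

    gene_a: str
    gene_b: str
    distance: DistanceEstimate
    identity: float
    status: str                       # retained | discarded_witness | discarded_outlier
    confidence: Optional[str] = None  # high | low (retained pairs only)
    chromosome_group_a: Optional[int] = None
    chromosome_group_b: Optional[int] = None
    witness_genome: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status == "retained" and self.confidence not in (None, "high",
                                                                 "low"):
            raise ValueError("bad confidence label")
        if self.status != "retained" and self.confidence is not None:
            raise ValueError("only retained pairs carry a confidence label")


def split_subgenomes(genome: Genome,
                     partition: dict[str, str]) -> list[Genome]:
    """Split a polyploid genome into per-subgenome pseudo-genome units.

    ``partition`` maps gene id → subgenome label (genes with a ``subgenome``
    attribute set are partitioned implicitly when absent from the map).
    Units are named ``<genome>:<label>`` and behave as genomes in the
    alignment and pairing stages.  Unpartitioned genes are excluded with a
    logged count; fewer than two labels is an error.
    """
    by_label: dict[str, list[Gene]] = {}
    skipped = 0
    for g in genome.genes:
        label = partition.get(g.id, g.subgenome)
        if label is None:
            skipped += 1
            continue
        by_label.setdefault(label, []).append(replace(g))
    if skipped:
        logger.warning("%d genes of %s have no subgenome label and were "
                       "excluded", skipped, genome.id)
    if len(by_label) < 2:
        raise ValueError(
            f"subgenome partition of {genome.id} needs >= 2 labels, "
            f"got {sorted(by_label)}")
    return [Genome(id=f"{genome.id}:{label}", species_name=genome.species_name,
                   genes=genes)
            for label, genes in sorted(by_label.items())]


def infer_homeologs(units: list[Genome], other_genomes: list[Genome],
                    params: HomeologyParams = HomeologyParams(),
                    family: Optional[ScoringMatrixFamily] = None,
                    avresult: Optional[AllVsAllResult] = None,
                    ) -> list[HomeologPair]:
    """Candidate homeologs via the standard ortholog pipeline between units.

    Returns every evaluated inter-unit candidate with status ``retained`` or
    ``discarded_witness``; witnesses are drawn from the other genomes and
    from the remaining subgenome units.  Outlier filtering and confidence
    labelling are separate, subsequent steps.
    """
    if family is None:
        family = build_matrix_family()
    if avresult is None:
        avresult = all_against_all(list(units) + list(other_genomes), family,
                                   min_score=params.min_score,
                                   min_aln_fraction=params.min_aln_fraction)
    unit_ids = {u.id for u in units}
    gene_lookup = {g.id: g for gm in list(units) + list(other_genomes)
                   for g in gm.genes}

    candidates = find_candidate_pairs(avresult, k_tolerance=params.k_tolerance)
    verified, reports = verify_non_orthology(
        candidates, avresult, tol=params.witness_tol,
        use_stderr=params.witness_use_stderr,
        se_multiplier=params.witness_se_multiplier)
    witness_by_pair = {(r.gene_a, r.gene_b): r for r in reports}

    def is_inter_unit(a: str, b: str) -> bool:
        ua, ub = avresult.unit_of(a), avresult.unit_of(b)
        return ua in unit_ids and ub in unit_ids and ua != ub

    out = []
    for cand in candidates:
        if not is_inter_unit(cand.gene_a, cand.gene_b):
            continue
        report = witness_by_pair.get((cand.gene_a, cand.gene_b))
        hit = avresult.hit(cand.gene_a, cand.gene_b)
        ga = gene_lookup[cand.gene_a]
        gb = gene_lookup[cand.gene_b]
        out.append(HomeologPair(
            gene_a=cand.gene_a, gene_b=cand.gene_b, distance=cand.distance,
            identity=hit.identity,
            status="discarded_witness" if report else "retained",
            chromosome_group_a=ga.chromosome_group,
            chromosome_group_b=gb.chromosome_group,
            witness_genome=report.witness_genome if report else None))
    out.sort(key=lambda p: (p.gene_a, p.gene_b))
    return out


def filter_outliers(pairs: list[HomeologPair],
                    params: HomeologyParams = HomeologyParams(),
                    ) -> list[HomeologPair]:
    """Single-pass distance-outlier removal on the witness survivors.

    Mean and standard deviation are computed over the retained candidates
    only; pairs with distance above ``mean + sd_multiplier * sd`` become
    ``discarded_outlier``.  The threshold is not re-estimated after removal.
    With fewer than two retained pairs this is a no-op.
    """
    retained = [p for p in pairs if p.status == "retained"]
    if len(retained) < 2 or math.isinf(params.sd_multiplier):
        return list(pairs)
    dists = [p.distance.distance for p in retained]
    mu = sum(dists) / len(dists)
    ss = sum((d - mu) ** 2 for d in dists)
    denom = len(dists) if params.population_sd else len(dists) - 1
    sigma = math.sqrt(ss / denom)
    threshold = mu + params.sd_multiplier * sigma
    out = []
    for p in pairs:
        if p.status == "retained" and p.distance.distance > threshold:
            out.append(replace(p, status="discarded_outlier", confidence=None))
        else:
            out.append(p)
    return out


def label_confidence(pairs: list[HomeologPair]) -> list[HomeologPair]:
    """High confidence iff both genes carry the same chromosome group.

    Pairs with a missing group on either side are conservatively low
    confidence; discarded pairs are left unlabelled.
    """
    out = []
    for p in pairs:
        if p.status != "retained":
            out.append(p)
            continue
        high = (p.chromosome_group_a is not None
                and p.chromosome_group_a == p.chromosome_group_b)
        out.append(replace(p, confidence="high" if high else "low"))
    return out


def summarize(pairs: list[HomeologPair]) -> dict:
    """The homeology report: status counts, group consistency, distances.

    Mean/SD of retained distances are reported both over all witness
    survivors (pre-outlier) and over the final retained set, plus mean
    percent identity per confidence class.
    """
    def stats(values: list[float]) -> tuple[float, float]:
        if not values:
            return float("nan"), float("nan")
        mu = sum(values) / len(values)
        sd = math.sqrt(sum((v - mu) ** 2 for v in values) / len(values))
        return mu, sd

    by_status: dict[str, list[HomeologPair]] = {}
    for p in pairs:
        by_status.setdefault(p.status, []).append(p)

    def frac_same_group(ps: list[HomeologPair]) -> float:
        if not ps:
            return float("nan")
        same = sum(1 for p in ps
                   if p.chromosome_group_a is not None
                   and p.chromosome_group_a == p.chromosome_group_b)
        return same / len(ps)

    survivors = [p for p in pairs if p.status in ("retained",
                                                  "discarded_outlier")]
    retained = by_status.get("retained", [])
    pre_mu, pre_sd = stats([p.distance.distance for p in survivors])
    post_mu, post_sd = stats([p.distance.distance for p in retained])
    report = {
        "counts": {s: len(v) for s, v in sorted(by_status.items())},
        "frac_same_group": {s: frac_same_group(v)
                            for s, v in sorted(by_status.items())},
        "distance_mean_pre_outlier": pre_mu,
        "distance_sd_pre_outlier": pre_sd,
        "distance_mean_retained": post_mu,
        "distance_sd_retained": post_sd,
    }
    for label in ("high", "low"):
        ps = [p for p in retained if p.confidence == label]
        report[f"mean_identity_{label}"] = (
            sum(p.identity for p in ps) / len(ps) if ps else float("nan"))
        report[f"n_{label}"] = len(ps)
    return report
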