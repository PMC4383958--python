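"""Phase 2: verified orthologous pairs.

Candidates are mutually closest homologs under the evolutionary-distance
metric, with a tolerance that accounts for the estimation uncertainty of both
distances.  Candidates are then screened for hidden paralogy: a third genome
carrying two distinct genes that are each much closer to one side of the pair
than the pair is to itself — while being distant from each other — witnesses a
differential gene loss, and the pair is discarded as pseudo-orthologous.
Survivors are tagged with their cardinality (1:1, 1:m, m:1, m:m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .align import AllVsAllResult
from .types import DistanceEstimate


@dataclass(frozen=True)
class CandidatePair:
    """A mutually-closest homolog pair, with the slack by which each side won."""

    gene_a: str
    gene_b: str
    distance: DistanceEstimate
    slack_a: float
    slack_b: float


@dataclass(frozen=True)
class WitnessReport:
    """Why a candidate was discarded: the third-genome witness pair."""

    gene_a: str
    gene_b: str
    witness_genome: str
    witness_gene_1: str
    witness_gene_2: str
    verdict: str = "discarded"


@dataclass(frozen=True)
class OrthologousPair:
    """A verified ortholog with its cardinality tag."""

    gene_a: str
    gene_b: str
    distance: DistanceEstimate
    cardinality: str  # 1:1 | 1:m | m:1 | m:m


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def find_candidate_pairs(avresult: AllVsAllResult,
                         k_tolerance: float = 1.96) -> list[CandidatePair]:
    """Mutually closest homologs with uncertainty tolerance.

    (x, y) is a candidate iff for every y' in y's unit:
    ``d(x,y) <= d(x,y') + k * sqrt(var(x,y) + var(x,y'))`` and symmetrically
    on x's side.  The slack recorded per side is the smallest margin by which
    the inequalities held (``inf`` when the partner was unique in its unit).
    """

    def side_ok(x: str, y: str) -> tuple[bool, float]:
        d_xy = avresult.distance(x, y)
        slack = math.inf
        for y2, dist2 in avresult.partners_in(x, avresult.unit_of(y)).items():
            if y2 == y:
                continue
            margin = (dist2.distance
                      + k_tolerance * math.sqrt(d_xy.variance + dist2.variance)
                      - d_xy.distance)
            if margin < 0:
                return False, 0.0
            slack = min(slack, margin)
        return True, slack

    out = []
    for x, y in avresult.pairs():
        ok_x, slack_x = side_ok(x, y)
        if not ok_x:
            continue
        ok_y, slack_y = side_ok(y, x)
        if not ok_y:
            continue
        out.append(CandidatePair(gene_a=x, gene_b=y,
                                 distance=avresult.distance(x, y),
                                 slack_a=slack_x, slack_b=slack_y))
    out.sort(key=lambda c: (c.gene_a, c.gene_b))
    return out


def verify_non_orthology(candidates: list[CandidatePair],
                         avresult: AllVsAllResult,
                         tol: float = 0.0,
                         use_stderr: bool = True,
                         se_multiplier: float = 1.96,
                         ) -> tuple[list[CandidatePair], list[WitnessReport]]:
    """Discard candidates for which a third unit witnesses non-orthology.

    Candidate (x, z) is discarded iff some unit Y (distinct from both sides)
    contains y1 != y2 with

        d(x, y1) < d(x, z) - tol_1
        d(z, y2) < d(x, z) - tol_2
        d(y1, y2) > max(d(x, y1), d(z, y2)) + tol_3

    where y1 is itself a candidate partner of x and y2 of z, and each tol_i is
    ``tol`` plus (if ``use_stderr``) ``se_multiplier`` times the combined
    standard error of the two distances compared — the same 95% normal band
    the candidate search uses, so that estimate noise alone rarely fabricates
    a witness.  A missing d(y1, y2) — the hit was not retained — is treated
    as infinite divergence, satisfying the third condition.
    """
    partner_sets: dict[str, set[str]] = {}
    for c in candidates:
        partner_sets.setdefault(c.gene_a, set()).add(c.gene_b)
        partner_sets.setdefault(c.gene_b, set()).add(c.gene_a)

    def tol_for(v1: float, v2: Optional[float]) -> float:
        if not use_stderr:
            return tol
        return tol + se_multiplier * math.sqrt(
            v1 + (v2 if v2 is not None else 0.0))

    all_units = sorted(avresult.units())
    verified: list[CandidatePair] = []
    reports: list[WitnessReport] = []

    for cand in candidates:
        x, z = cand.gene_a, cand.gene_b
        d_xz = cand.distance
        witness = None
        excluded = {avresult.unit_of(x), avresult.unit_of(z)}
        for unit in all_units:
            if unit in excluded:
                continue
            near_x = {}
            for y1 in sorted(partner_sets.get(x, ()) & avresult.genes_of(unit)):
                d1 = avresult.distance(x, y1)
                if d1.distance < d_xz.distance - tol_for(d1.variance,
                                                         d_xz.variance):
                    near_x[y1] = d1
            if not near_x:
                continue
            near_z = {}
            for y2 in sorted(partner_sets.get(z, ()) & avresult.genes_of(unit)):
                d2 = avresult.distance(z, y2)
                if d2.distance < d_xz.distance - tol_for(d2.variance,
                                                         d_xz.variance):
                    near_z[y2] = d2
            for y1, d1 in sorted(near_x.items()):
                for y2, d2 in sorted(near_z.items()):
                    if y1 == y2:
                        continue
                    d12 = avresult.distance_or_none(y1, y2)
                    floor = max(d1.distance, d2.distance)
                    if d12 is None:
                        deep = True
                    else:
                        deep = d12.distance > floor + tol_for(d12.variance,
                                                              max(d1.variance,
                                                                  d2.variance))
                    if deep:
                        witness = WitnessReport(
                            gene_a=x, gene_b=z, witness_genome=unit,
                            witness_gene_1=y1, witness_gene_2=y2)
                        break
                if witness:
                    break
            if witness:
                break
        if witness:
            reports.append(witness)
        else:
            verified.append(cand)
    return verified, reports


def classify_cardinality(verified: list[CandidatePair],
                         avresult: AllVsAllResult) -> list[OrthologousPair]:
    """Tag each verified pair 1:1 / 1:m / m:1 / m:m from partner counts."""
    counts: dict[tuple[str, str], int] = {}
    for c in verified:
        ua = avresult.unit_of(c.gene_a)
        ub = avresult.unit_of(c.gene_b)
        counts[(c.gene_a, ub)] = counts.get((c.gene_a, ub), 0) + 1
        counts[(c.gene_b, ua)] = counts.get((c.gene_b, ua), 0) + 1

    out = []
    for c in verified:
        ua = avresult.unit_of(c.gene_a)
        ub = avresult.unit_of(c.gene_b)
        many_a = counts[(c.gene_b, ua)] >= 2   # b has >= 2 partners in a's unit
        many_b = counts[(c.gene_a, ub)] >= 2   # a has >= 2 partners in b's unit
        card = f"{'m' if many_a else '1'}:{'m' if many_b else '1'}"
        out.append(OrthologousPair(gene_a=c.gene_a, gene_b=c.gene_b,
                                   distance=c.distance, cardinality=card))
    out.sort(key=lambda p: (p.gene_a, p.gene_b))
    return out


def infer_pairs(avresult: AllVsAllResult, k_tolerance: float = 1.96,
                witness_tol: float = 0.0, use_stderr: bool = True,
                witness_se_multiplier: float = 1.96,
                ) -> tuple[list[OrthologousPair], list[WitnessReport]]:
    """Candidate search, witness filtering and cardinality tagging in one call."""
    cands = find_candidate_pairs(avresult, k_tolerance=k_tolerance)
    verified, reports = verify_non_orthology(cands, avresult, tol=witness_tol,
                                             use_stderr=use_stderr,
                                             se_multiplier=witness_se_multiplier)
    return classify_cardinality(verified, avresult), reports
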