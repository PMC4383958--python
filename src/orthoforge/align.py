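"""Phase 1: all-against-all local alignment and ML evolutionary distances.

Every inter-genome protein pair is aligned with Smith–Waterman under affine
gaps (biotite's C kernel), scored with the log-odds matrix of the package's
PAM-style model at a reference distance.  Significant hits are re-scored on
the fixed alignment across the whole distance grid; the maximum-likelihood
distance is located by quadratic interpolation and its variance taken from
the local curvature of the log-likelihood.  Splice-variant selection and an
export/import cache for the all-against-all results live here too.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign

from .matrices import AA20, ScoringMatrixFamily, build_matrix_family
from .types import AlignmentHit, DistanceEstimate, Genome

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 130.0
DEFAULT_MIN_ALN_FRACTION = 0.6
VARIANCE_FLOOR = 0.25  # PAM^2
MAX_EXPORT_GENOMES = 50
# Gap penalties (open, extend) for the distance-estimation alignment; stiff
# so that only strongly supported indels interrupt the ungapped frame.
ESTIMATION_GAP_PENALTY = (-40, -5)

_BIOTITE_ALPHABET = bseq.ProteinSequence.alphabet
_AA20_CODES = np.array([_BIOTITE_ALPHABET.encode(a) for a in AA20])
# biotite symbol code -> AA20 index (-1 for X and other non-standard codes)
_CODE_MAP = np.full(len(_BIOTITE_ALPHABET), -1, dtype=np.int64)
for _i, _c in enumerate(_AA20_CODES):
    _CODE_MAP[_c] = _i


class NoHomologyError(ValueError):
    """No grid matrix yields a positive alignment score for the pair."""


class StaleCacheError(RuntimeError):
    """An imported all-against-all cache does not match the supplied genomes."""


@lru_cache(maxsize=64)
def _biotite_matrix(family: ScoringMatrixFamily, index: int):
    n = len(_BIOTITE_ALPHABET)
    full = np.zeros((n, n), dtype=np.int32)
    mat = family.matrices[index]
    full[np.ix_(_AA20_CODES, _AA20_CODES)] = mat
    return balign.SubstitutionMatrix(_BIOTITE_ALPHABET, _BIOTITE_ALPHABET, full)


def _as_protein(seq) -> bseq.ProteinSequence:
    return seq if isinstance(seq, bseq.ProteinSequence) else bseq.ProteinSequence(seq)


def _auto_band(la: int, lb: int) -> Optional[tuple[int, int]]:
    """Band for long near-colinear pairs; full DP below the size threshold."""
    if min(la, lb) < 3000:
        return None
    b = max(200, int(0.05 * min(la, lb)))
    return (-b - max(0, la - lb), b + max(0, lb - la))


def smith_waterman(a, b, family: ScoringMatrixFamily,
                   matrix_index: Optional[int] = None,
                   band="auto", gene_a: str = "a", gene_b: str = "b",
                   ) -> Optional[AlignmentHit]:
    """Optimal local alignment under affine gaps; None if best score <= 0."""
    hit, _, _ = _align(a, b, family, matrix_index, band, gene_a, gene_b)
    return hit


def _align(a, b, family: ScoringMatrixFamily, matrix_index, band,
           gene_a: str, gene_b: str, local: bool = True,
           gap_override: Optional[tuple[int, int]] = None):
    """Align and return (hit, per-residue match counts, mismatch count)."""
    if matrix_index is None:
        matrix_index = family.reference_index
    sa, sb = _as_protein(a), _as_protein(b)
    matrix = _biotite_matrix(family, matrix_index)
    gap = gap_override or (-family.gap_open, -family.gap_extend)
    if band == "auto":
        band = _auto_band(len(sa), len(sb))
    if band is None:
        alns = balign.align_optimal(sa, sb, matrix, gap_penalty=gap,
                                    local=local, max_number=1)
    else:
        alns = balign.align_banded(sa, sb, matrix, band=band, gap_penalty=gap,
                                   local=local, max_number=1)
    if not alns or (local and alns[0].score <= 0):
        return None, None, 0
    aln = alns[0]
    trace = aln.trace
    both = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    cols_a = trace[both, 0]
    cols_b = trace[both, 1]
    code_a = np.asarray(sa.code)[cols_a]
    code_b = np.asarray(sb.code)[cols_b]
    same_all = code_a == code_b
    # likelihood profile over standard residues only (columns with X ignored)
    ia = _CODE_MAP[code_a]
    ib = _CODE_MAP[code_b]
    std = (ia >= 0) & (ib >= 0)
    same_std = std & same_all
    counts = np.bincount(ia[same_std], minlength=20).astype(np.int64)
    n_mismatch = int((std & ~same_all).sum())
    span_a = (int(trace[trace[:, 0] >= 0, 0].min()) + 1,
              int(trace[trace[:, 0] >= 0, 0].max()) + 1)
    span_b = (int(trace[trace[:, 1] >= 0, 1].min()) + 1,
              int(trace[trace[:, 1] >= 0, 1].max()) + 1)
    identity = float(same_all.sum() / max(1, both.sum()))
    hit = AlignmentHit(gene_a=gene_a, gene_b=gene_b, score=float(aln.score),
                       span_a=span_a, span_b=span_b, identity=identity)
    return hit, counts, n_mismatch


def _parabola_vertex(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Vertex location and second derivative of the parabola through 3 points."""
    c2, c1, _ = np.polyfit(x, y, 2)
    if c2 >= 0:
        return float(x[int(np.argmax(y))]), 0.0
    return float(-c1 / (2 * c2)), float(2 * c2)


def estimate_distance(a, b, family: ScoringMatrixFamily, band="auto",
                      gene_a: str = "a", gene_b: str = "b",
                      ) -> tuple[DistanceEstimate, AlignmentHit]:
    """ML distance (PAM) with variance from the log-likelihood curvature.

    The alignment is computed once at the reference matrix and held fixed;
    its column profile is re-scored in closed form across the grid.  The best
    grid point is refined by quadratic interpolation (coarse grid parabola,
    then a fine unit-spaced parabola); variance is the inverse negative
    curvature of the natural-log likelihood, floored at 0.25 PAM^2.  At a grid
    edge the grid point itself is returned.

    Raises :class:`NoHomologyError` when no positive-scoring alignment exists.
    """
    hit, _, _ = _align(a, b, family, None, band, gene_a, gene_b, local=True)
    if hit is None:
        raise NoHomologyError(
            f"no significant homology between {gene_a} and {gene_b}")
    dist = _ml_distance(a, b, family, band, gene_a, gene_b)
    return dist, hit


def _ml_distance(a, b, family: ScoringMatrixFamily, band, gene_a: str,
                 gene_b: str) -> DistanceEstimate:
    model = family.model
    grid = np.asarray(family.grid)
    # The likelihood profile comes from a *global* alignment under stiff gap
    # penalties: a local alignment trims mismatch-rich ends by construction,
    # and cheap gaps let the aligner shift frames through mismatch runs to
    # harvest chance matches — both inflate identity and bias the distance
    # down, increasingly so with divergence.
    _, counts, n_mismatch = _align(a, b, family, None, band, gene_a, gene_b,
                                   local=False,
                                   gap_override=ESTIMATION_GAP_PENALTY)
    ll = np.array([model.pair_log_likelihood(counts, n_mismatch, d)
                   for d in grid])
    k = int(np.argmax(ll))
    if k == 0 or k == len(grid) - 1:
        d_hat = float(grid[k])
        lo = max(grid[0], d_hat - 1.0) if k else d_hat
        xs = np.array([lo, d_hat + 1.0, d_hat + 2.0]) if k == 0 else \
            np.array([d_hat - 2.0, d_hat - 1.0, d_hat])
        ys = np.array([model.pair_log_likelihood(counts, n_mismatch, x) for x in xs])
        _, curv = _parabola_vertex(xs, ys)
    else:
        d1, _ = _parabola_vertex(grid[k - 1:k + 2], ll[k - 1:k + 2])
        d1 = float(np.clip(d1, grid[0], grid[-1]))
        xs = np.array([d1 - 1.0, d1, d1 + 1.0])
        ys = np.array([model.pair_log_likelihood(counts, n_mismatch, x) for x in xs])
        d_hat, curv = _parabola_vertex(xs, ys)
        d_hat = float(np.clip(d_hat, grid[0], grid[-1]))
    variance = VARIANCE_FLOOR if curv >= 0 else max(VARIANCE_FLOOR, -1.0 / curv)
    return DistanceEstimate(distance=d_hat, variance=variance)


def _span_fraction(hit: AlignmentHit, la: int, lb: int) -> float:
    if la <= lb:
        lo, hi = hit.span_a
        return (hi - lo + 1) / la
    lo, hi = hit.span_b
    return (hi - lo + 1) / lb


def select_splice_variants(genomes: list[Genome], family: ScoringMatrixFamily,
                           min_score: float = DEFAULT_MIN_SCORE,
                           min_aln_fraction: float = DEFAULT_MIN_ALN_FRACTION,
                           ) -> None:
    """Pick, per gene, the splice variant best supported by cross-genome matches.

    The chosen variant maximises the summed scores of its significant
    alignments against the representative sequences of all genes in all other
    genomes — not necessarily the longest variant.  Ties go to the longer
    sequence, then to the smaller variant index.  Selection is written into
    ``gene.selected_variant``.
    """
    reps: list[tuple[str, bseq.ProteinSequence]] = []
    for gm in genomes:
        for g in gm.genes:
            rep = g.variants[g.selected_variant or 0]
            reps.append((gm.id, _as_protein(rep)))

    for gm in genomes:
        for g in gm.genes:
            if len(g.variants) == 1:
                g.selected_variant = 0
                continue
            scored = []
            for vi, variant in enumerate(g.variants):
                sv = _as_protein(variant)
                total = 0.0
                for other_gm, other_seq in reps:
                    if other_gm == gm.id:
                        continue
                    hit = smith_waterman(sv, other_seq, family)
                    if hit and hit.score >= min_score and \
                            _span_fraction(hit, len(sv), len(other_seq)) >= min_aln_fraction:
                        total += hit.score
                scored.append((total, len(variant), -vi, vi))
            scored.sort(reverse=True)
            g.selected_variant = scored[0][3]


@dataclass
class AllVsAllResult:
    """Symmetric map (inter-unit gene pair) → (AlignmentHit, DistanceEstimate)."""

    _adj: dict[str, dict[str, tuple[AlignmentHit, DistanceEstimate]]] = \
        field(default_factory=dict)
    _intra: dict[tuple[str, str], DistanceEstimate] = field(default_factory=dict)
    _unit_of: dict[str, str] = field(default_factory=dict)
    _unit_genes: dict[str, set[str]] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    stats: dict[str, int] = field(default_factory=dict)

    def register_unit(self, unit_id: str, gene_ids: Iterable[str],
                      checksum: str = "") -> None:
        genes = set(gene_ids)
        self._unit_genes[unit_id] = genes
        for g in genes:
            self._unit_of[g] = unit_id
        if checksum:
            self.checksums[unit_id] = checksum

    def add(self, hit: AlignmentHit, dist: DistanceEstimate) -> None:
        a, b = hit.gene_a, hit.gene_b
        if a == b:
            raise ValueError("self pairs are not stored")
        if self._unit_of.get(a) == self._unit_of.get(b):
            raise ValueError(f"{a} and {b} are in the same unit")
        self._adj.setdefault(a, {})[b] = (hit, dist)
        self._adj.setdefault(b, {})[a] = (hit, dist)

    # -- queries -----------------------------------------------------------
    def units(self) -> set[str]:
        return set(self._unit_genes)

    def genes_of(self, unit: str) -> set[str]:
        return self._unit_genes[unit]

    def unit_of(self, gene: str) -> str:
        return self._unit_of[gene]

    def pairs(self) -> Iterator[tuple[str, str]]:
        """Each retained pair once, in canonical sorted order."""
        for a in sorted(self._adj):
            for b in sorted(self._adj[a]):
                if a < b:
                    yield a, b

    def hit(self, a: str, b: str) -> AlignmentHit:
        return self._adj[a][b][0]

    def distance(self, a: str, b: str) -> DistanceEstimate:
        return self._adj[a][b][1]

    def add_intra(self, a: str, b: str, dist: DistanceEstimate) -> None:
        """Record a within-unit (paralog) distance, used by the witness rule."""
        if a == b:
            raise ValueError("self pairs are not stored")
        self._intra[(a, b) if a <= b else (b, a)] = dist

    def distance_or_none(self, a: str, b: str) -> Optional[DistanceEstimate]:
        entry = self._adj.get(a, {}).get(b)
        if entry:
            return entry[1]
        return self._intra.get((a, b) if a <= b else (b, a))

    def partners(self, gene: str) -> dict[str, DistanceEstimate]:
        return {p: hd[1] for p, hd in self._adj.get(gene, {}).items()}

    def partners_in(self, gene: str, unit: str) -> dict[str, DistanceEstimate]:
        members = self._unit_genes.get(unit, set())
        return {p: hd[1] for p, hd in self._adj.get(gene, {}).items()
                if p in members}

    def __len__(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    def __eq__(self, other) -> bool:
        if not isinstance(other, AllVsAllResult):
            return NotImplemented
        return (self._adj == other._adj and self._intra == other._intra
                and self._unit_genes == other._unit_genes)


def genome_checksum(genome: Genome) -> str:
    h = hashlib.sha256()
    for g in sorted(genome.genes, key=lambda g: g.id):
        h.update(g.id.encode())
        h.update(g.sequence.encode())
    return h.hexdigest()


def all_against_all(genomes: list[Genome], family: ScoringMatrixFamily = None,
                    min_score: float = DEFAULT_MIN_SCORE,
                    min_aln_fraction: float = DEFAULT_MIN_ALN_FRACTION,
                    cache: Optional[AllVsAllResult] = None,
                    band="auto", compute_intra: bool = True) -> AllVsAllResult:
    """Align every inter-genome gene pair and retain significant matches.

    A hit is retained iff its reference-matrix score is >= ``min_score`` and
    its alignment span covers >= ``min_aln_fraction`` of the shorter sequence;
    each retained hit carries an ML distance estimate.  When ``cache`` (an
    imported previous result) covers a genome pair and its per-genome
    checksums match, that pair is copied instead of recomputed; a checksum
    mismatch on a covered genome raises :class:`StaleCacheError`.
    """
    if family is None:
        family = build_matrix_family()
    needs_selection = any(
        g.selected_variant is None and len(g.variants) > 1
        for gm in genomes for g in gm.genes)
    if needs_selection:
        select_splice_variants(genomes, family, min_score, min_aln_fraction)
    for gm in genomes:
        for g in gm.genes:
            if g.selected_variant is None:
                g.selected_variant = 0

    result = AllVsAllResult()
    result.stats["alignments_computed"] = 0
    sums = {}
    for gm in genomes:
        cs = genome_checksum(gm)
        sums[gm.id] = cs
        result.register_unit(gm.id, (g.id for g in gm.genes), cs)

    if cache is not None:
        for unit in cache.units() & set(sums):
            if cache.checksums.get(unit) and cache.checksums[unit] != sums[unit]:
                raise StaleCacheError(
                    f"cached genome {unit} differs from the supplied one")

    seqs = {g.id: _as_protein(g.sequence) for gm in genomes for g in gm.genes}
    ordered = sorted(genomes, key=lambda g: g.id)
    for i, ga in enumerate(ordered):
        for gb in ordered[i + 1:]:
            if cache is not None and ga.id in cache.units() \
                    and gb.id in cache.units():
                genes_b = cache.genes_of(gb.id)
                for x in sorted(cache.genes_of(ga.id)):
                    for y, (hit, dist) in sorted(cache._adj.get(x, {}).items()):
                        if y in genes_b:
                            result.add(hit, dist)
                continue
            for x in ga.genes:
                sx = seqs[x.id]
                for y in gb.genes:
                    sy = seqs[y.id]
                    result.stats["alignments_computed"] += 1
                    hit, _, _ = _align(sx, sy, family, None, band,
                                       x.id, y.id, local=True)
                    if hit is None or hit.score < min_score:
                        continue
                    if _span_fraction(hit, len(sx), len(sy)) < min_aln_fraction:
                        continue
                    dist = _ml_distance(sx, sy, family, band, x.id, y.id)
                    result.add(hit, dist)
    if compute_intra:
        for gm in ordered:
            if cache is not None and gm.id in cache.units():
                mine = cache.genes_of(gm.id)
                for (a, b), dist in cache._intra.items():
                    if a in mine:
                        result.add_intra(a, b, dist)
                continue
            genes = sorted(gm.genes, key=lambda g: g.id)
            for i, x in enumerate(genes):
                for y in genes[i + 1:]:
                    sx, sy = seqs[x.id], seqs[y.id]
                    result.stats["alignments_computed"] += 1
                    hit, _, _ = _align(sx, sy, family, None, band,
                                       x.id, y.id, local=True)
                    if hit is None or hit.score < min_score:
                        continue
                    if _span_fraction(hit, len(sx), len(sy)) < min_aln_fraction:
                        continue
                    result.add_intra(x.id, y.id,
                                     _ml_distance(sx, sy, family, band,
                                                  x.id, y.id))
    return result


# -- export / import of the all-against-all cache ---------------------------

_CACHE_COLUMNS = ["gene_a", "gene_b", "score", "span_a_start", "span_a_end",
                  "span_b_start", "span_b_end", "identity", "distance",
                  "variance"]


def export_cache(result: AllVsAllResult, genomes: list[Genome], dirpath,
                 max_genomes: int = MAX_EXPORT_GENOMES) -> None:
    """Write per-genome FASTA plus a TSV of hits and distances.

    Refuses more than ``max_genomes`` genomes, mirroring the bounded genome
    export of the reference service.
    """
    if len(genomes) > max_genomes:
        raise ValueError(
            f"at most {max_genomes} genomes may be exported, got {len(genomes)}")
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    meta = {"units": {}, "columns": _CACHE_COLUMNS}
    for gm in sorted(genomes, key=lambda g: g.id):
        lines = []
        for g in sorted(gm.genes, key=lambda g: g.id):
            lines.append(f">{g.id}\n{g.sequence}\n")
        (d / f"{gm.id}.fa").write_text("".join(lines))
        meta["units"][gm.id] = {
            "checksum": genome_checksum(gm),
            "genes": sorted(g.id for g in gm.genes),
        }
    with open(d / "pairs.tsv", "w") as fh:
        fh.write("\t".join(_CACHE_COLUMNS) + "\n")
        for a, b in result.pairs():
            hit = result.hit(a, b)
            dist = result.distance(a, b)
            if hit.gene_a != a:  # emit in canonical orientation
                hit = AlignmentHit(gene_a=a, gene_b=b, score=hit.score,
                                   span_a=hit.span_b, span_b=hit.span_a,
                                   identity=hit.identity)
            fh.write("\t".join(map(str, [
                a, b, repr(hit.score),
                hit.span_a[0], hit.span_a[1], hit.span_b[0], hit.span_b[1],
                repr(hit.identity), repr(dist.distance), repr(dist.variance),
            ])) + "\n")
    with open(d / "intra.tsv", "w") as fh:
        fh.write("gene_a\tgene_b\tdistance\tvariance\n")
        for (a, b), dist in sorted(result._intra.items()):
            fh.write(f"{a}\t{b}\t{dist.distance!r}\t{dist.variance!r}\n")
    (d / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def import_cache(dirpath) -> AllVsAllResult:
    """Read a cache directory back into an :class:`AllVsAllResult`."""
    d = Path(dirpath)
    meta = json.loads((d / "meta.json").read_text())
    result = AllVsAllResult()
    for unit, info in meta["units"].items():
        result.register_unit(unit, info["genes"], info["checksum"])
    with open(d / "pairs.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CACHE_COLUMNS:
            raise StaleCacheError("unrecognised cache TSV columns")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hit = AlignmentHit(
                gene_a=f[0], gene_b=f[1], score=float(f[2]),
                span_a=(int(f[3]), int(f[4])), span_b=(int(f[5]), int(f[6])),
                identity=float(f[7]))
            dist = DistanceEstimate(distance=float(f[8]), variance=float(f[9]))
            result.add(hit, dist)
    intra = d / "intra.tsv"
    if intra.exists():
        with open(intra) as fh:
            fh.readline()
            for line in fh:
                a, b, dd, vv = line.rstrip("\n").split("\t")
                result.add_intra(a, b, DistanceEstimate(distance=float(dd),
                                                        variance=float(vv)))
    return result
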