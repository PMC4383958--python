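# Methods

orthoforge is a desk-scale orthology-inference pipeline with a built-in
gene-family evolution simulator that plants ground truth for every inference
stage. This note records the models, the defaults and why they are what they
are, the numerical choices, and what the validation suite does and does not
demonstrate.

## Substitution model and scoring matrices

All sequence comparison rests on a single 20-state Markov substitution
process of the Felsenstein-81 type with Dayhoff equilibrium frequencies
π: a substituting site draws its new residue from π regardless of the old
one, so the transition matrix has the closed form

    P(d) = e^{-βd} I + (1 − e^{-βd}) 1πᵀ ,

with β calibrated so that one PAM unit corresponds to an expected 1% of
sites accepting a substitution (`Σᵢ πᵢ Pᵢᵢ(1) = 0.99`; 1 PAM = 0.01
expected substitutions per site). The closed form gives exact expected
identities, exact per-column log-likelihoods and an exact simulation recipe,
so estimator calibration is a testable property rather than an article of
faith. The model deliberately has no exchangeability structure beyond the
equilibrium frequencies; distance information therefore comes from the
identity profile, which is the quantity the F81 family identifies. A
mismatched-model robustness mode is a known omission (see Limitations).

Scoring matrices are Dayhoff-convention log-odds, `s_ij(d) = 10·log10(P_ij(d)
/ π_j)`, rounded to integers for alignment. Reversibility makes them
symmetric. The default grid spans PAM 10–300 in steps of 10; affine gap
penalties are open 12, extend 2 in matrix units, with a gap of length l
costing `open + (l−1)·extend`. The alignment kernel is biotite's C
implementation of Smith–Waterman/Gotoh; a pure-Python quadratic DP serves as
the independent oracle in the tests.

## All-against-all and distance estimation

Every inter-genome protein pair is aligned locally with the matrix at the
reference distance (PAM 120, the grid midpoint on the usable range). A hit
is significant when its score is ≥ 130 matrix units and the alignment span
covers ≥ 60% of the shorter sequence; both thresholds are configuration
values recorded in the run metadata, chosen so that uniform-random 100-mers
essentially never pass (verified property) while genuine homologs at the
simulator's divergences always do.

The maximum-likelihood distance of a significant pair is estimated from a
*global* alignment computed under stiff gap penalties (open 40, extend 5).
Two alternatives were measured and rejected during design:

* scoring the local alignment's columns biases the distance down, because a
  local alignment trims mismatch-rich ends by construction (−14 PAM at a
  true distance of 180 on 10-kilo-residue pairs);
* a global alignment under the ordinary gap penalties lets the aligner
  shift frames through mismatch runs to harvest chance matches, with the
  same sign of bias.

With the stiff-gap global profile the estimator shows no measurable bias
over the PAM 20–180 range the calibration suite covers. The log-likelihood of the fixed alignment's
column profile is evaluated across the grid in closed form; the best grid
point is refined by quadratic interpolation (the coarse three-point parabola
on the grid, then a fine unit-spaced parabola at the refined point), and the
variance is the inverse negative curvature of the natural-log likelihood at
the optimum, floored at 0.25 PAM². At a grid edge the edge point itself is
returned — identical sequences report the smallest grid distance. Pairs
longer than 3000 residues are aligned in a diagonal band (5% of the length,
at least ±200 residues), which is exact for the simulator's indel-free
sequences and a documented approximation otherwise.

Within-genome (paralog) pairs are aligned as well and their distances kept
in a separate intra-unit store: the witness-of-non-orthology rule compares
the divergence of two same-genome genes, and treating that distance as
always-unknown would make one of its three conditions vacuous.

## Splice variants

For a gene with several splice variants, the variant maximising the summed
scores of its significant alignments against the representative sequences of
all other genomes' genes is selected — not necessarily the longest — with
ties broken by length and then by variant index. Only selected variants
enter the all-against-all.

## Orthologous pairs

Candidates are mutually closest homologs with uncertainty tolerance: (x, y)
survives iff for every y′ in y's genome, `d(x,y) ≤ d(x,y′) +
k·√(var(x,y)+var(x,y′))` and symmetrically, with k = 1.96 by default (a
two-sided 95% normal band; the uncertainty treatment is this package's own
instantiation). The margin by which each side met the criterion is recorded.

A candidate (x, z) is discarded as pseudo-orthologous when a third genome
contains distinct genes y1, y2 with y1 a candidate partner of x, y2 of z,

    d(x,y1) < d(x,z) − tol,  d(z,y2) < d(x,z) − tol,
    d(y1,y2) > max(d(x,y1), d(z,y2)) + tol,

the signature of a differential gene loss. Each tolerance is 0 PAM plus the
combined standard error of the two distances compared (the SE term can be
switched off, which the exact-arithmetic unit fixtures use). A missing
d(y1, y2) counts as infinite divergence: the absence of a significant hit
between two same-genome genes implies deep divergence. All third units are
scanned, including sister subgenomes in homeology mode. Survivors are tagged
1:1 / 1:m / m:1 / m:m from verified partner counts per genome.

## OMA groups and fingerprints

Groups are cliques in the verified-ortholog graph with at most one gene per
genome, extracted greedily (maximum clique being NP-hard): seed with the
highest-degree unassigned gene, extend by the neighbour adjacent to all
current members from an unrepresented genome, ties broken by degree then
gene id. The validation compares against an exhaustive-enumeration oracle on
small random graphs and requires the greedy result within two members of the
optimum. The fingerprint of a group is the lexicographically smallest 7-mer
present in every member and absent from every other sequence in the dataset
(empty when none exists); k = 7 matches the length of the classical
fingerprint examples.

## Hierarchical orthologous groups and branch events

HOGs are built bottom-up over the rooted species tree: each gene starts as a
singleton at its leaf; at every internal node the child-level HOGs are joined
into connected components, with an edge between HOGs from different children
when at least `min_edges` (default 1) verified pairs connect their members.
A component spanning one child passes through unchanged, so a family's root
level is the node where it first spans two children. The construction is
static and single-pass, which guarantees nesting consistency: membership at
a deeper taxonomic level is always a subset of membership at any ancestral
level. Top-level HOGs are numbered `HOG:NNNNNNN` in order of their smallest
member id, sub-HOGs `.1`, `.2`, … (the id scheme is this package's own).

Branch events are read off the forest: gains at a node are the top-level
HOGs rooted there; for every HOG node and species child, k ≥ 2 contributing
sub-HOGs record k−1 duplications on that branch, and no contributing sub-HOG
records one loss — absence of an entire sub-clade counts once, at the
shallowest branch where the absence begins, which avoids double counting. A
sub-HOG rooted deeper than the child it descends through records one loss on
every side branch along its path. Feeding the simulator's *true* ortholog
relations through this machinery reproduces planted per-branch duplication
and loss counts exactly in single-event-per-family scenarios; a loss on a
branch incident to the root is unidentifiable by any parsimony method (no
outgroup evidence survives) and the simulator therefore never plants one
there.

## GO propagation

Sources are literature-based annotations only (evidence codes EXP, IDA, IPI,
IMP, IGI, IEP). Within each OMA group, a source annotation (gene g_s, term
t) reaches every other member g_t as follows: take the is_a ancestor closure
of t (part_of optionally included, off by default as the conservative
choice), intersect with the corpus of g_t's clade — the set of terms used in
at least one experimental annotation on any gene of that clade, exact terms
only — and emit the most specific surviving terms, unless already implied by
g_t's curated annotations. The clade of a genome is the most specific
configured clade containing it; clades are user-designated major groups
(per-kingdom in the packaged example), defaulting to all named tree nodes.
Inferred annotations carry evidence IEA with full provenance (source gene
and term) and never act as sources, which makes propagation idempotent.

## Homeology

An allopolyploid genome is partitioned into subgenome units (the partition
is an input, mirroring how polyploid annotation projects assign genes to
subgenomes), and the ordinary ortholog pipeline runs between units —
homeologs being precisely orthologs between subgenomes. Filters apply
strictly in order: first the witness filter (witnesses drawn from related
diploid genomes and the remaining units), then a single-pass distance
outlier filter on the witness survivors: pairs farther than
`mean + 2.5·SD` are dropped, with the population SD (divisor n; a sample-SD
flag exists) and no re-estimation after removal. Retained pairs are high
confidence when both genes carry the same chromosome group, low confidence
otherwise — including when a group is missing on either side. The summary
reports distance means/SDs both before and after outlier removal, since
either convention is defensible.

## Synteny matrices

The synteny view around a query gene is a (2w+1)-column matrix, w = 3 by
default: the query row holds the chromosomal neighbourhood ordered by start
coordinate (strand kept as a display attribute), subsequent rows are
centred on each verified ortholog of the query, ordered by the depth of the
species-tree MRCA with the query genome (deepest — most closely related —
first). Every cell carries a colour class: the set of query-row columns
whose gene is a verified ortholog of the cell's gene; multi-member classes
encode many-to-one and many-to-many relations, the empty class renders grey,
and cells past a contig edge are empty. Output is JSON plus a flat TSV;
rendering is out of scope.

## The simulator

Families start at the root of a user-given species tree with branch lengths
in PAM. Sequences evolve by exact sampling from the model's transition
matrices; gene lineages duplicate and die under a birth–death process with
per-gene per-PAM rates, sampled by the Gillespie algorithm along each branch
so that duplicate copies diverge from the true event time. Duplicates insert
adjacent to their template (tandem model); optional inversions reverse a
random gene-order interval per branch. Hybridization merges two designated
leaf genomes into one allopolyploid with labelled subgenomes and inherited
chromosome groups, and can plant contaminant pairs: private two-gene
families at a chosen divergence placed on mismatched chromosome groups.
Ground truth records every sampled event, every gene tree, and the
ortholog/paralog/homeolog relations induced by the gene trees (checked
against an independent LCA-reconciliation oracle in the tests). Everything
is reproducible from a single integer seed.

A `one_event_per_family` mode plants at most one duplication or loss per
family for the event-count exactness oracle. v1 has no indels (an indel rate
is reserved in the configuration), no rate heterogeneity across sites or
lineages, and no sequence model mismatch — the simulator intentionally
matches the scorer's model so that estimator calibration is a sharp test.

## Validation scales and what passing shows

The validation suite runs at sizes a single CPU handles in minutes, chosen
as this package's study conditions: distance calibration on 20 replicate
pairs of 10 000 residues at PAM 20/60/120/180; end-to-end ortholog recovery
on a five-genome tree (branches 10–60 PAM) with 100 root families at
duplication and loss rates of 0.002 events/gene/PAM and 200-residue
proteins; an allotetraploid whose progenitors diverged 60 PAM with 100
families of 400 residues and ten planted contaminant pairs at 200 PAM (3.3×
the homeolog mean — long enough sequences that the contaminants clear the
significance threshold and genuinely exercise the filters); twenty
single-event scenarios for the event oracle.

Passing these shows the pipeline is correct and calibrated *under its own
model*: well-specified substitution process, indel-free full-length
homologs, complete proteomes, known subgenome partition. It does not show
robustness to misannotated or fragmentary genes, domain-level (partial)
homology, model misspecification, or genome-scale data volumes; real-data
headline figures from large orthology databases are not reproducible at
this scale and are not targets of the suite.

## Known limitations

* No indel process in the simulator, hence alignment-span filtering is only
  weakly exercised.
* The witness and mutually-closest tolerances assume approximately normal
  distance errors; the variance floor (0.25 PAM²) makes the tolerance
  conservative for near-identical sequences.
* Fingerprint search is exhaustive over member k-mers and intended for
  datasets that fit in memory.
* The greedy clique heuristic can undershoot the optimal OMA group by a
  small margin (bounded at 2 in the validation graphs).
* Subgenome assignment is an input; the package does not infer it.
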