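# Methods

## Data model

The unit of classification is the **enzyme functional domain (EFD)**: the
portion of a chain responsible for one annotated function, containing at
least one **superfamily domain (SFD)** span that performs the conserved
chemistry.  A chain may carry several EFDs (multi-functional proteins),
each independently classifiable; their SFD spans may not overlap.  All
coordinates are 1-based and inclusive, matching curator convention in
protein databases; alignment columns are likewise 1-based.

The hierarchy is a tree of `HierarchyNode`s — one superfamily root,
subgroups (which may nest), families as leaves — each carrying its member
id set, seed alignment, profile, calibrated cutoffs and conserved-residue
specs.  `validate_hierarchy` reports (never raises) violations of
containment, level structure and residue-spec satisfiability; a
superfamily- or subgroup-level spec must be satisfiable (at least one
allowed residue observed in the column) in every descendant family's seed
alignment, since conservation claimed at a higher level must hold for all
descendants.

## Scoring

Sequence–sequence alignment (local for network edges, global for identity)
uses BLOSUM62 with affine gaps: opening a gap costs `gap_open + gap_extend`
(11 + 1 by default) and each further position `gap_extend`, the BLAST
convention.  The implementation is Biopython's C `PairwiseAligner`; the
test suite checks it against an independent hand-written quadratic DP.

Profile–sequence comparison uses a position-specific scoring model built
from the seed alignment: per-column log2-odds of residue frequencies with
one pseudocount per residue against a uniform background,
`log2(((c_r + 1)/(n + 20)) / (1/20))`.  Columns with more than 50 % gaps
are not match columns; `column_map` records the surviving seed-MSA columns
so residue specs can be located after alignment.  The profile is scored
**glocally** — every profile column consumed, free start/end in the target
— which mirrors sweeping a whole-domain model along a longer chain and
makes the score robust to unrelated fused domains.  Internally the DP uses
the column scores rounded to half-bit integers (the same convention that
makes BLOSUM62 integral), which keeps the traceback exact; `X` scores zero
against every column.  The traceback provides the profile-column → target-
position map used by residue checks and by query-to-MSA alignment.

Both routes share one statistical convention: `bits = (λ·S − ln K)/ln 2`
and `E = m·n·2^(−bits)` with `m` the query length (profile width for
profile hits), `n` the searched residue count, and the standard gapped-
BLOSUM62 constants λ = 0.267, K = 0.041 (configurable).  Applying the same
identity to the integer glocal score is a pragmatic convention — the
calibration below consumes only the *ranking* of bit scores, so any
monotone rescaling would calibrate identically.  External search results
(HMMER `--tblout`, BLAST `-outfmt 6`) import with their bit scores taken
verbatim, making the calibration backend-agnostic; calibration uses the
best score per target.

## Threshold calibration

Given the descending bit scores of a database search and the seed id set:

* drop candidate — the highest score before the first relative fall of at
  least `drop_fraction` (default 0.10) between consecutive ranked scores;
  only pairs led by a positive score are eligible (junk targets can go
  negative under a log-odds profile);
* seed-capture candidate — the score of the last seed to appear in the
  ranking (undefined if a seed is missing).

`TC` is the lower of the two candidates when both exist, else whichever
exists; `NC` is the next strictly lower ranked score (tied runs are one
rank), or `TC` itself when nothing follows; `GA = (TC + NC)/2`, an
arithmetic mid-point of bit scores.  When neither candidate exists the
calibration raises — that case requires a curator, who may also override
the GA (`manual_ga`).  When the seed-capture score falls below the drop's
noise region the lower candidate still wins, but a diagnostic flags the
node for review.  The GA is intentionally lax: residue checks downstream
supply specificity, so the cost of a slightly generous threshold is small
while a tight one silently loses trusted members.

## Annotation transfer

A query descends the hierarchy: superfamily GA first (failing it means no
assignment), then every child whose bit score meets its own GA is followed.
Family candidacy additionally requires all family residue specs to pass:
each spec's seed-MSA column is mapped through the profile's `column_map`
and the hit's column trace to the aligned query residue; a deleted column
fails.  Residue specs at superfamily/subgroup level are evaluated and
reported but do not block assignment — enforcement above family level
would discard queries whose deeper evidence is intact, while family level
is where over-annotation damages downstream databases; the `evidence`
field (`hmm_plus_residues` vs `hmm_only`) preserves the distinction for
curators.  Among passing nodes the deepest wins, ties by higher bit score
then node name; sibling nodes that also passed are listed in diagnostics.
Queries with declared domain ranges are classified as EFD slices.

## Seed selection

Inputs at or under the cap (default 250) are returned unchanged.
Otherwise fragments shorter than half the median length are dropped (long
and short outliers distort alignments and profiles), then the identity
ladder 0.9, 0.8, …, 0.4 is walked: at each rung the whole filtered set is
greedily clustered — sequences visited by (length desc, id asc), each
joining the first representative it matches at ≥ the rung's identity —
stopping at the first rung whose representative count fits the cap.
Re-clustering the full set at every rung (rather than refining the
previous rung's representatives) guarantees that every input is within the
final rung's identity of some retained representative.  If even the lowest
rung exceeds the cap, the cap longest representatives are kept.  Identity
is `identical positions / alignment columns` of the optimal BLOSUM62
global alignment.  Two conservative screens skip alignments that provably
cannot reach the threshold `r`: `min(len)/max(len) < r`, and
`editDistance > min(len)·(1−r)/r` (bit-parallel edit distance; the bound
follows because an alignment with identity ≥ r has at most
`min(len)·(1−r)/r` mismatches plus gap columns, and the edit distance is a
lower bound on that count).  A property test confirms the screened
procedure equals the naive quadratic one.

## Similarity networks

`build_network` aligns all pairs once; each unordered pair keeps the
larger (less significant) of its two directional E-values — the
conservative symmetrisation — and an edge exists iff it passes the build
threshold.  Edges carry E-value, bit score and percent identity so
curators can re-threshold without recomputing.  Thresholding keeps all
nodes; sweeps require strictly decreasing cutoffs and report edge counts,
component counts and memberships (edge deletion makes the former
non-increasing and the latter non-decreasing by construction).
Representative networks reuse the greedy clustering; cluster attributes
are summarised as the unique value list plus the modal value (ties broken
lexicographically), and rep-nodes are linked iff any member pair has an
edge, weighted by the best such pair.  XGMML export writes typed `att`
elements (integer/real/string/list) and round-trips losslessly; the
dissemination bundle zips the XGMML with a README and the node-length
histogram (TSV + rendered PNG; bin counts sum to the node count).

## Synthetic superfamilies

The generator draws a uniform-background ancestor (280 residues), mutates
it into subgroup ancestors (per-site substitution probability 0.45), those
into family ancestors (0.25), and those into members (0.08), protecting
planted positions: 4 superfamily-conserved residues fixed across everyone,
3 subgroup positions re-drawn per subgroup then frozen, 3 family positions
re-drawn per family then frozen (positions sampled once per superfamily,
disjoint across levels).  30 % of members gain an unrelated random extra
domain (80–160 residues) appended to the chain; the ground truth records
the EFD span.  Divergence defaults were chosen so that the three levels
are statistically separable the way a real functionally diverse
superfamily's are (within-family identity ≈ 0.85, cross-family ≈ 0.6,
cross-subgroup ≈ 0.4 — ordered, with usable gaps) while still leaving the
classification non-trivial.  Seed alignments are exact by construction
(substitution-only members stack ungapped; in the optional indel mode,
rate 0.01, deletions appear as gaps and insertions live only in chains).
Query sets hold out fresh draws per family (20 by default) plus knockouts
(20 % of the intact count) in which one family-level catalytic residue is
substituted to a disallowed residue.

What the generator does **not** emulate: tree-shaped within-group
phylogeny, rate heterogeneity across sites, realistic indel processes,
compositional bias, and homologous-but-distinct neighbouring superfamilies.
Passing tests on this material therefore demonstrate the machinery —
calibration, gating, residue checks, network behaviour — under a clean,
separable signal; they do not measure performance on real, unevenly
diverged superfamilies.

## Problem sizes and numerics

The test suite and examples run the default study conditions (3 subgroups
× 2 families × 40 members, seed 1) for calibration, annotation and network
sweeps, and a 1000-member set for seed reduction; these sizes exercise
every code path at full sequence length while keeping the whole suite in
the minutes range on one CPU.  Numerical notes: profile DP is exact
integer arithmetic; bit/E-value identities are floating point and tested
to 1e-9 relative tolerance; `GA` is exactly `(TC+NC)/2` in floats;
greedy-clustering ties break by (length desc, id asc) and attribute-mode
ties lexicographically, making every pipeline stage deterministic for a
given seed.

## Known limitations

The profile model has no insert/delete state probabilities (a single
affine gap penalty stands in for them) and no composition-based score
correction, so its absolute bit scores are not comparable to HMMER's —
only rankings are, which is all calibration needs.  Identity from a single
optimal global alignment is well-defined only up to co-optimal alignment
choice; the clustering contract is therefore stated in terms of the
aligner's deterministic choice.  The EFD model allows discontiguous
partner domains (whether partners must be contiguous with the SFD is left
open by the curation literature); this is an assumption, recorded here.
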