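"""Redundancy-reducing seed selection.

Building a seed alignment from every known member of a superfamily is
counter-productive: curators cannot review it, over-represented lineages
bias the profile, and long alignments slow everything downstream.  The
reduction here walks a descending ladder of identity thresholds, greedily
clustering the set at each rung and keeping one representative per cluster,
until the representative count fits under a cap (default 250) — producing a
bounded set that still samples the whole input.

Identity is the fraction of identical positions over the length of the
optimal global alignment (BLOSUM62, affine gaps).  Two provably
conservative screens skip the expensive alignment when a pair cannot reach
the threshold ``r``:

* length ratio — identity ≤ min(len)/max(len);
* edit distance — identity ≥ r forces editDistance ≤ min(len)·(1−r)/r,
  checked with a banded bit-parallel edit-distance computation (edlib).

Neither screen can discard a pair that would have clustered, so screened
greedy clustering is exactly equivalent to the naive quadratic version.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import edlib

from .model import ModelError, SequenceRecord
from .scoring import ScoringParams


class SeedSelectionError(ValueError):
    pass


@dataclass
class SeedConfig:
    cap: int = 250
    identity_ladder: Tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4)
    min_length_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.cap < 1:
            raise SeedSelectionError("cap must be >= 1")
        ladder = tuple(self.identity_ladder)
        if not ladder or any(not (0.0 < r <= 1.0) for r in ladder):
            raise SeedSelectionError("ladder values must be in (0, 1]")
        if any(b >= a for a, b in zip(ladder, ladder[1:])):
            raise SeedSelectionError("identity ladder must be strictly decreasing")
        self.identity_ladder = ladder


def pairwise_identity(a: SequenceRecord, b: SequenceRecord,
                      params: Optional[ScoringParams] = None) -> float:
    """Identity fraction of the optimal global alignment of a and b.

    Identical aligned positions divided by total alignment columns (gap
    columns included); symmetric in its arguments.
    """
    if not a.sequence or not b.sequence:
        raise SeedSelectionError("empty sequence")
    params = params or ScoringParams()
    aligner = params.aligner("global")
    aln = aligner.align(a.sequence, b.sequence)[0]
    counts = aln.counts()
    return counts.identities / aln.shape[1]


def _cannot_reach(a: SequenceRecord, b: SequenceRecord, r: float) -> bool:
    """True only if identity(a, b) < r is certain without aligning."""
    la, lb = len(a.sequence), len(b.sequence)
    lo, hi = min(la, lb), max(la, lb)
    if lo < r * hi:  # identity <= lo/alignment_length <= lo/hi
        return True
    # identity >= r forces editDistance <= lo*(1-r)/r
    limit = int(lo * (1.0 - r) / r)
    res = edlib.align(a.sequence, b.sequence, mode="NW", task="distance",
                      k=limit)
    return res["editDistance"] == -1


@dataclass
class Cluster:
    representative: SequenceRecord
    members: List[SequenceRecord] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def _sorted_for_clustering(seqs: List[SequenceRecord]) -> List[SequenceRecord]:
    return sorted(seqs, key=lambda s: (-len(s.sequence), s.id))


def greedy_cluster(seqs: List[SequenceRecord], identity: float,
                   params: Optional[ScoringParams] = None,
                   cache: Optional[Dict[tuple, float]] = None,
                   use_screens: bool = True) -> List[Cluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are visited by (length desc, id asc); each joins the first
    existing cluster whose representative it matches at >= ``identity``,
    else seeds a new cluster.  The sort makes the result independent of the
    input order.  ``cache`` memoises exact identities across ladder rungs.
    """
    if not seqs:
        raise SeedSelectionError("no sequences to cluster")
    if cache is None:
        cache = {}
    clusters: List[Cluster] = []
    for seq in _sorted_for_clustering(seqs):
        placed = False
        for cl in clusters:
            rep = cl.representative
            key = (seq.id, rep.id) if seq.id < rep.id else (rep.id, seq.id)
            ident = cache.get(key)
            if ident is None:
                if use_screens and _cannot_reach(seq, rep, identity):
                    continue
                ident = pairwise_identity(seq, rep, params)
                cache[key] = ident
            if ident >= identity:
                cl.members.append(seq)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=seq, members=[seq]))
    return clusters


@dataclass
class SeedReduction:
    seeds: List[SequenceRecord]
    rung: Optional[float]  # identity threshold that satisfied the cap, if any
    truncated: bool
    dropped_fragments: List[str]
    assignments: List[tuple]  # (input id, representative id, rung)

    def report_rows(self):
        for rid, rep, rung in self.assignments:
            yield {"id": rid, "representative": rep,
                   "rung": "" if rung is None else f"{rung:.2f}"}


def reduce_seed_set_detailed(seqs: List[SequenceRecord],
                             cfg: Optional[SeedConfig] = None,
                             params: Optional[ScoringParams] = None
                             ) -> SeedReduction:
    """Full reduction with per-sequence bookkeeping (see reduce_seed_set)."""
    cfg = cfg or SeedConfig()
    if not seqs:
        raise SeedSelectionError("no sequences")
    if len(seqs) <= cfg.cap:
        return SeedReduction(seeds=list(seqs), rung=None, truncated=False,
                             dropped_fragments=[],
                             assignments=[(s.id, s.id, None) for s in seqs])

    median_len = statistics.median(len(s.sequence) for s in seqs)
    min_len = cfg.min_length_fraction * median_len
    kept = [s for s in seqs if len(s.sequence) >= min_len]
    dropped = [s.id for s in seqs if len(s.sequence) < min_len]
    if not kept:
        raise SeedSelectionError("no full-length sequences after fragment filter")

    cache: Dict[tuple, float] = {}
    clusters: List[Cluster] = []
    final_rung: Optional[float] = None
    for rung in cfg.identity_ladder:
        clusters = greedy_cluster(kept, rung, params, cache)
        final_rung = rung
        if len(clusters) <= cfg.cap:
            break

    truncated = len(clusters) > cfg.cap
    if truncated:
        clusters = sorted(
            clusters,
            key=lambda c: (-len(c.representative.sequence), c.representative.id),
        )[: cfg.cap]

    kept_reps = {c.representative.id for c in clusters}
    assignments = []
    for cl in clusters:
        for m in cl.members:
            assignments.append((m.id, cl.representative.id, final_rung))
    if truncated:
        assigned = {a[0] for a in assignments}
        for s in kept:
            if s.id not in assigned:
                assignments.append((s.id, "", final_rung))
    return SeedReduction(
        seeds=[c.representative for c in clusters],
        rung=final_rung, truncated=truncated,
        dropped_fragments=dropped, assignments=assignments,
    )


def reduce_seed_set(seqs: List[SequenceRecord],
                    cfg: Optional[SeedConfig] = None,
                    params: Optional[ScoringParams] = None
                    ) -> List[SequenceRecord]:
    """Reduce a sequence set to a bounded, space-sampling seed set.

    Inputs already at or under the cap are returned unchanged.  Otherwise:
    fragments shorter than ``min_length_fraction`` of the median length are
    dropped; then the identity ladder is walked from its highest rung,
    clustering the filtered set at each rung, stopping at the first rung
    whose representative count fits the cap.  If even the lowest rung
    exceeds the cap, the ``cap`` longest representatives are kept (ties by
    id).  The output is always a subset of the input.
    """
    return reduce_seed_set_detailed(seqs, cfg, params).seeds
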