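"""Bit scores and E-values for sequence–sequence and profile–sequence search.

Two comparison routes share one statistical convention:

* ``align_local`` — Smith–Waterman with affine gaps (BLOSUM62 by default),
  delegated to Biopython's C ``PairwiseAligner``.
* ``build_profile`` / ``search`` — a position-specific log-odds profile
  built from a seed alignment and scored *glocally* (global in the profile,
  local in the target), mirroring how whole-domain models are swept along
  candidate sequences.  The dynamic programme is integer-scored (half-bit
  units, the BLOSUM62 convention) so tracebacks are exact.

Raw scores are converted to bit scores with Karlin–Altschul statistics,
``bits = (λ·S − ln K) / ln 2``, and E-values as ``E = m·n·2^(−bits)`` with
``m`` the query length and ``n`` the residue count of the searched database.
Bit scores, not E-values, drive threshold calibration because they are
independent of database size.

External search programs can be plugged in through ``import_hits`` (HMMER
``--tblout`` and BLAST ``-outfmt 6`` dialects); calibration consumes only
the ranked bit scores, so it is backend-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices

from .model import AA20, GAP_CHARS, DomainRange, ModelError, SequenceRecord
from .io import Alignment

_AA_INDEX = {c: i for i, c in enumerate(AA20)}
_AA_INDEX["X"] = 20  # unknown: scores 0 against every profile column

#: default gapped-BLOSUM62 Karlin–Altschul parameters (standard published values)
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

_NEG = -(2 ** 40)


class ScoringError(ValueError):
    pass


@dataclass
class ScoringParams:
    """Scoring scheme and alignment statistics.

    ``gap_open`` is the cost of opening a gap (the first gapped position
    costs ``gap_open + gap_extend``, each further position ``gap_extend`` —
    the BLAST convention for "open 11, extend 1").  ``db_size`` is the total
    residue count of the searched database; when unset, the target sequence
    length is used.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = DEFAULT_LAMBDA
    K: float = DEFAULT_K
    db_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ScoringError("lambda and K must be positive")
        if self.gap_extend > self.gap_open:
            raise ScoringError("gap_extend must not exceed gap_open")
        self._matrix = substitution_matrices.load(self.matrix_name)

    @property
    def substitution_matrix(self):
        return self._matrix

    def aligner(self, mode: str) -> _BioAlign.PairwiseAligner:
        a = _BioAlign.PairwiseAligner()
        a.substitution_matrix = self._matrix
        a.open_gap_score = -(self.gap_open + self.gap_extend)
        a.extend_gap_score = -self.gap_extend
        a.mode = mode
        return a


def bit_score(raw: float, params: ScoringParams) -> float:
    return (params.lam * raw - math.log(params.K)) / math.log(2)


def evalue(bits: float, query_len: int, db_size: int) -> float:
    # 2^(-bits) via exp to stay in float range for typical scores
    return float(query_len) * float(db_size) * math.pow(2.0, -bits)


@dataclass
class Hit:
    """One ranked match of a query (sequence or profile) to a target.

    ``column_trace`` maps 1-based query positions (profile columns for
    profile hits) to 1-based target residue indices, for residue checks.
    """

    query: str
    target: str
    raw_score: int
    bit_score: float
    evalue: float
    aligned_range: Optional[DomainRange] = None
    column_trace: Dict[int, int] = field(default_factory=dict)


def _make_hit(query: str, target: str, raw: int, qlen: int, n: int,
              params: ScoringParams, aligned_range, trace) -> Hit:
    bits = bit_score(raw, params)
    return Hit(query=query, target=target, raw_score=int(raw),
               bit_score=bits, evalue=evalue(bits, qlen, n),
               aligned_range=aligned_range, column_trace=trace)


@dataclass
class HitTable:
    """Hits sorted by descending bit score (ties by target id)."""

    hits: List[Hit]
    db_size: int = 0

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: (-h.bit_score, h.target))
        seen = set()
        for h in self.hits:
            key = (h.query, h.target)
            if key in seen:
                raise ScoringError(f"duplicate hit for {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def scores(self) -> List[float]:
        return [h.bit_score for h in self.hits]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("query\ttarget\tbit_score\tevalue\ttstart\ttend\n")
            for h in self.hits:
                ts = h.aligned_range.start if h.aligned_range else ""
                te = h.aligned_range.end if h.aligned_range else ""
                fh.write(
                    f"{h.query}\t{h.target}\t{h.bit_score:.4f}"
                    f"\t{h.evalue:.6g}\t{ts}\t{te}\n"
                )


# ---------------------------------------------------------------------------
# Sequence–sequence local alignment


def align_local(a: SequenceRecord, b: SequenceRecord,
                params: Optional[ScoringParams] = None) -> Hit:
    """Optimal local alignment of two sequences (affine gaps).

    Returns a Hit with the query→target position trace of one optimal
    alignment; the score is symmetric in (a, b).
    """
    params = params or ScoringParams()
    if not a.sequence or not b.sequence:
        raise ScoringError("empty sequence")
    aligner = params.aligner("local")
    aln = aligner.align(a.sequence, b.sequence)[0]
    raw = int(round(aln.score))
    trace: Dict[int, int] = {}
    tmin, tmax = None, None
    qblocks, tblocks = aln.aligned
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        for off in range(qe - qs):
            trace[qs + off + 1] = ts + off + 1
        tmin = ts + 1 if tmin is None else min(tmin, ts + 1)
        tmax = te if tmax is None else max(tmax, te)
    rng = DomainRange(tmin, tmax) if tmin is not None else None
    n = params.db_size or len(b.sequence)
    return _make_hit(a.id, b.id, raw, len(a.sequence), n, params, rng, trace)


def percent_identity_from_hit(hit: Hit, a: SequenceRecord,
                              b: SequenceRecord) -> float:
    """Identical aligned positions / aligned length, from a local hit."""
    if not hit.column_trace:
        return 0.0
    ident = sum(
        1 for q, t in hit.column_trace.items()
        if a.sequence[q - 1] == b.sequence[t - 1]
    )
    return 100.0 * ident / len(hit.column_trace)


# ---------------------------------------------------------------------------
# Profile construction


@dataclass
class ProfileModel:
    """Per-column log-odds scores derived from a seed alignment.

    ``columns`` holds the real-valued log2-odds (+1 pseudocount per residue
    against a uniform background); ``int_scores`` is the same matrix rounded
    to half-bit integers (plus a zero-scoring X column) used by the DP.
    ``column_map[i]`` gives the 1-based seed-MSA column behind profile
    column ``i+1``; columns with more than 50 % gaps are not match columns.
    """

    columns: np.ndarray  # (width, 20) float64, log2-odds
    int_scores: np.ndarray  # (width, 21) int32, half-bit units
    column_map: List[int]
    source_node: str = ""
    seed_ids: List[str] = field(default_factory=list)

    @property
    def width(self) -> int:
        return int(self.columns.shape[0])

    def msa_to_profile_column(self, msa_column: int) -> int:
        """1-based profile column for a 1-based seed-MSA column."""
        try:
            return self.column_map.index(msa_column) + 1
        except ValueError:
            raise ScoringError(
                f"spec/profile mismatch: MSA column {msa_column} is not a "
                f"match column of profile {self.source_node!r}"
            ) from None


def build_profile(msa: Alignment, params: Optional[ScoringParams] = None,
                  source_node: str = "") -> ProfileModel:
    """Build a position-specific scoring profile from a seed alignment.

    Column score for residue r: ``log2(((count_r + 1) / (rows + 20)) / (1/20))``
    — observed counts with one pseudocount per residue, against a uniform
    background.  Columns with more than 50 % gap characters are excluded.
    """
    n_rows = len(msa.rows)
    if n_rows < 2:
        raise ScoringError("insufficient depth: profile needs >= 2 rows")
    cols: List[np.ndarray] = []
    column_map: List[int] = []
    background = 1.0 / 20.0
    for c in range(1, msa.width + 1):
        col = msa.column(c)
        gaps = sum(1 for ch in col if ch in GAP_CHARS)
        if gaps * 2 > n_rows:
            continue
        counts = np.zeros(20)
        for ch in col:
            i = _AA_INDEX.get(ch)
            if i is not None and i < 20:
                counts[i] += 1
        freqs = (counts + 1.0) / (n_rows + 20.0)
        cols.append(np.log2(freqs / background))
        column_map.append(c)
    if not cols:
        raise ScoringError("no match columns (all gap-majority)")
    columns = np.vstack(cols)
    ints = np.zeros((columns.shape[0], 21), dtype=np.int32)
    ints[:, :20] = np.rint(2.0 * columns).astype(np.int32)  # half-bit units
    return ProfileModel(columns=columns, int_scores=ints,
                        column_map=column_map, source_node=source_node,
                        seed_ids=list(msa.ids))


# ---------------------------------------------------------------------------
# Glocal profile DP (global in profile, local in target)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX.get(c, 20) for c in seq), dtype=np.intp,
                       count=len(seq))


def _glocal_dp(profile: ProfileModel, seq: str, open_cost: int, ext: int):
    """Integer DP; returns (score, matched {profile col -> 1-based seq pos})."""
    W = profile.width
    L = len(seq)
    x = _encode(seq)
    S = profile.int_scores  # (W, 21)
    M = np.full((W + 1, L + 1), _NEG, dtype=np.int64)
    D = np.full((W + 1, L + 1), _NEG, dtype=np.int64)
    I = np.full((W + 1, L + 1), _NEG, dtype=np.int64)
    M[0, :] = 0  # free start anywhere in the target
    j_idx = np.arange(L + 1, dtype=np.int64)
    for i in range(1, W + 1):
        prev = np.maximum(np.maximum(M[i - 1], D[i - 1]), I[i - 1])
        M[i, 1:] = S[i - 1, x] + prev[:-1]
        D[i] = np.maximum(M[i - 1] - open_cost, D[i - 1] - ext)
        # I[i, j] = max(M[i, j-1] - open, I[i, j-1] - ext), via running max
        run = np.maximum.accumulate(M[i] + ext * j_idx)
        I[i, 1:] = run[:-1] - open_cost - ext * (j_idx[1:] - 1)
    final = np.maximum(M[W], D[W])
    j = int(np.argmax(final))
    score = int(final[j])
    # traceback by exact integer equalities
    state = "M" if M[W, j] >= D[W, j] else "D"
    i = W
    trace: Dict[int, int] = {}
    while i > 0:
        if state == "M":
            trace[i] = j
            prev = max(M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            target = M[i, j] - S[i - 1, x[j - 1]]
            assert prev == target
            i, j = i - 1, j - 1
            if i == 0:
                break
            if M[i, j] == target:
                state = "M"
            elif D[i, j] == target:
                state = "D"
            else:
                state = "I"
        elif state == "D":
            if D[i, j] == M[i - 1, j] - open_cost:
                state = "M"
            else:
                state = "D"
            i -= 1
        else:  # I: inserted target residue, not matched to any column
            if I[i, j] == M[i, j - 1] - open_cost:
                state = "M"
            else:
                state = "I"
            j -= 1
        if state == "M" and i == 0:
            break
    return score, trace


def score_profile(profile: ProfileModel, target: SequenceRecord,
                  params: Optional[ScoringParams] = None) -> Hit:
    """Score one target sequence against a profile (glocal, affine gaps)."""
    params = params or ScoringParams()
    open_cost = params.gap_open + params.gap_extend
    raw, trace = _glocal_dp(profile, target.sequence, open_cost,
                            params.gap_extend)
    if trace:
        positions = sorted(trace.values())
        rng = DomainRange(positions[0], positions[-1])
    else:
        rng = None
    n = params.db_size or len(target.sequence)
    return _make_hit(profile.source_node or "profile", target.id, raw,
                     profile.width, n, params, rng, trace)


def search(profile: ProfileModel, db: List[SequenceRecord],
           params: Optional[ScoringParams] = None) -> HitTable:
    """Score every database sequence against the profile.

    One hit per target (its best glocal score); the result is invariant to
    database input order.  ``db_size`` is the total residue count of ``db``.
    """
    if not db:
        raise ScoringError("empty database")
    params = params or ScoringParams()
    n = sum(len(s.sequence) for s in db)
    sized = ScoringParams(matrix_name=params.matrix_name,
                          gap_open=params.gap_open,
                          gap_extend=params.gap_extend,
                          lam=params.lam, K=params.K, db_size=n)
    hits = [score_profile(profile, s, sized) for s in db]
    return HitTable(hits=hits, db_size=n)


# ---------------------------------------------------------------------------
# External hit-table import


def import_hits(path, dialect: str) -> HitTable:
    """Read an external search result (HMMER --tblout or BLAST -outfmt 6).

    Bit scores and E-values are taken verbatim from the file; duplicate
    (query, target) pairs keep the best bit score.  Malformed numeric fields
    raise with the offending line number.
    """
    if dialect not in ("hmmer_tblout", "blast_tab6"):
        raise ScoringError(f"unknown dialect {dialect!r}")
    best: Dict[tuple, Hit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if dialect == "hmmer_tblout":
                f = line.split()
                if len(f) < 6:
                    raise ScoringError(
                        f"{path}:{lineno}: expected >= 6 whitespace-separated "
                        f"fields in tblout line"
                    )
                target, query = f[0], f[2]
                ev_s, bits_s = f[4], f[5]
                rng = None
            else:
                f = line.split("\t")
                if len(f) < 12:
                    raise ScoringError(
                        f"{path}:{lineno}: expected 12 tab-separated fields "
                        f"in outfmt-6 line"
                    )
                query, target = f[0], f[1]
                ev_s, bits_s = f[10], f[11]
                try:
                    ss, se = int(f[8]), int(f[9])
                    rng = DomainRange(min(ss, se), max(ss, se))
                except ValueError as exc:
                    raise ScoringError(
                        f"{path}:{lineno}: non-numeric subject coordinates"
                    ) from exc
            try:
                ev = float(ev_s)
                bits = float(bits_s)
            except ValueError as exc:
                raise ScoringError(
                    f"{path}:{lineno}: non-numeric score field "
                    f"({ev_s!r}, {bits_s!r})"
                ) from exc
            # nearest integer raw score consistent with the K-A identity
            raw = int(round((bits * math.log(2) + math.log(DEFAULT_K))
                            / DEFAULT_LAMBDA))
            hit = Hit(query=query, target=target, raw_score=raw,
                      bit_score=bits, evalue=ev, aligned_range=rng)
            key = (query, target)
            if key not in best or hit.bit_score > best[key].bit_score:
                best[key] = hit
    return HitTable(hits=list(best.values()))
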