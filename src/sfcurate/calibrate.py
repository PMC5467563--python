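"""Gathering-threshold calibration for profile models.

A profile's membership thresholds are read off the ranked bit scores of a
database search together with the known seed membership:

* **TC (trusted cut-off)** — the highest score before either a large
  (default 10 %) relative drop between consecutive ranked scores, or the
  score at which the whole seed set has been captured; when both candidates
  exist, the *lower* of the two is used.
* **NC (noise cut-off)** — the score of the hit immediately following the
  TC in the ranking (equal-score runs count as one rank).  When the TC is
  the last hit — in particular when seed capture is the only candidate and
  nothing follows — NC equals TC.
* **GA (gathering threshold)** — the arithmetic mid-point ``(TC + NC) / 2``.

The GA is deliberately lax: family membership is confirmed downstream by
conserved-residue checks, so the threshold's job is to not lose trusted
hits.  A curator may override the GA (``manual_ga``); when neither
candidate is computable the calibration refuses and defers to the curator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Set

from .scoring import HitTable


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationConfig:
    """``drop_fraction`` defines a "large drop": a relative fall of at least
    this fraction between consecutive ranked scores (default 0.10)."""

    drop_fraction: float = 0.10
    manual_ga: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.drop_fraction < 1.0):
            raise CalibrationError("drop_fraction must be in (0, 1)")


@dataclass
class Cutoffs:
    tc: float
    nc: float
    ga: float
    method: str  # drop | seed_capture | lower_of_both | manual
    diagnostics: str = ""

    def __post_init__(self) -> None:
        if self.nc > self.tc:
            raise CalibrationError(f"NC ({self.nc}) must not exceed TC ({self.tc})")
        if self.method != "manual" and self.ga != (self.tc + self.nc) / 2.0:
            raise CalibrationError("GA must be the TC/NC mid-point")

    def to_dict(self) -> dict:
        return {"tc": self.tc, "nc": self.nc, "ga": self.ga,
                "method": self.method, "diagnostics": self.diagnostics}

    @classmethod
    def from_dict(cls, d: dict) -> "Cutoffs":
        return cls(tc=d["tc"], nc=d["nc"], ga=d["ga"], method=d["method"],
                   diagnostics=d.get("diagnostics", ""))


def _check_descending(scores: Sequence[float]) -> None:
    for a, b in zip(scores, scores[1:]):
        if b > a:
            raise CalibrationError("scores must be sorted descending")


def find_drop(scores: Sequence[float], drop_fraction: float = 0.10) -> Optional[int]:
    """Index of the score *before* the first large relative drop.

    Scans the descending list from the top and returns the smallest ``i``
    with ``(scores[i] − scores[i+1]) / scores[i] ≥ drop_fraction``; ``None``
    if no consecutive pair drops that much.  Scores must be positive and
    sorted descending.
    """
    _check_descending(scores)
    for s in scores:
        if s <= 0:
            raise CalibrationError("find_drop requires positive scores")
    for i in range(len(scores) - 1):
        if (scores[i] - scores[i + 1]) / scores[i] >= drop_fraction:
            return i
    return None


def seed_capture_score(table: HitTable, seed_ids: Set[str]) -> Optional[float]:
    """Bit score at which the entire seed set has been matched.

    Walking the ranking from the top, this is the score of the last seed to
    appear; ``None`` if any seed is absent from the table entirely.
    """
    if not seed_ids:
        raise CalibrationError("empty seed set")
    remaining = set(seed_ids)
    capture = None
    for hit in table:
        if hit.target in remaining:
            remaining.discard(hit.target)
            capture = hit.bit_score
            if not remaining:
                return capture
    return None


def _next_lower_score(scores: Sequence[float], tc: float) -> Optional[float]:
    """First score strictly below tc in the descending list (equal-score
    runs are one rank); None if tc is (tied-)last."""
    for s in scores:
        if s < tc:
            return s
    return None


def compute_cutoffs(table: HitTable, seed_ids: Set[str],
                    cfg: Optional[CalibrationConfig] = None) -> Cutoffs:
    """Calibrate TC/NC/GA from a ranked hit table and the seed membership.

    Candidates: the score before the first large drop, and the seed-capture
    score.  TC is the lower of the two when both exist, else whichever
    exists; NC is the next (strictly lower) ranked score after TC, or TC
    itself when nothing follows; GA = (TC + NC) / 2.  ``manual_ga``
    overrides the mid-point.  If neither candidate can be computed the
    calibration fails — that decision belongs to a curator.
    """
    cfg = cfg or CalibrationConfig()
    if len(table) == 0:
        raise CalibrationError("calibration failed: empty hit table")
    scores = table.scores()
    diagnostics: List[str] = []

    # like find_drop, but tolerate non-positive tail scores from junk targets:
    # only pairs led by a positive score are eligible
    drop_idx = None
    for i in range(len(scores) - 1):
        if scores[i] > 0 and (scores[i] - scores[i + 1]) / scores[i] >= cfg.drop_fraction:
            drop_idx = i
            break
    candidate_drop = scores[drop_idx] if drop_idx is not None else None
    candidate_seed = seed_capture_score(table, seed_ids)

    if candidate_drop is None and candidate_seed is None:
        raise CalibrationError(
            "calibration failed: curator decision required "
            "(no large drop and seed set not fully captured)"
        )

    if candidate_drop is not None and candidate_seed is not None:
        tc = min(candidate_drop, candidate_seed)
        method = "lower_of_both"
        if candidate_seed < candidate_drop:
            nc_after_drop = _next_lower_score(scores, candidate_drop)
            if nc_after_drop is not None and candidate_seed < nc_after_drop:
                diagnostics.append(
                    "seed-capture score lies below the drop's noise score; "
                    "flagged for curator review"
                )
    elif candidate_drop is not None:
        tc = candidate_drop
        method = "drop"
    else:
        tc = candidate_seed
        method = "seed_capture"

    nc = _next_lower_score(scores, tc)
    if nc is None:
        nc = tc
        if method == "seed_capture":
            diagnostics.append("seed-capture score is the last hit; TC = NC")

    ga = (tc + nc) / 2.0
    if cfg.manual_ga is not None:
        ga = cfg.manual_ga
        method = "manual"
        diagnostics.append("gathering threshold set manually")

    return Cutoffs(tc=tc, nc=nc, ga=ga, method=method,
                   diagnostics="; ".join(diagnostics))


def calibrate_hierarchy(root, db, params=None,
                        cfg: Optional[CalibrationConfig] = None) -> None:
    """Build profiles and cutoffs for every node of a hierarchy, in place.

    Each node's profile is built from its seed alignment and searched
    against ``db`` (best score per target); the node's seed ids are the
    rows of its seed alignment.
    """
    from .scoring import build_profile, search

    for node in root.walk():
        if node.seed_msa is None:
            continue
        if node.profile is None:
            node.profile = build_profile(node.seed_msa, params,
                                         source_node=node.name)
        table = search(node.profile, db, params)
        node.cutoffs = compute_cutoffs(table, set(node.profile.seed_ids), cfg)
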