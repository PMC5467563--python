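"""Hierarchical annotation transfer with a residue-conservation guard.

A query is assigned to the *deepest* hierarchy level its evidence supports.
Profile bit score against each node's gathering threshold (GA) gates the
descent; at family level — where over-annotation does the most damage — the
score alone is never enough: every family-level conserved-residue spec must
also be satisfied by the aligned query residue.  A query that matches a
family's profile but fails its residue checks is annotated at the parent
level instead, with the failed checks reported.

Residue specs defined at superfamily or subgroup level are evaluated and
reported wherever present, but only enforce at family level; the resulting
``evidence`` field distinguishes score-only assignments (``hmm_only``) from
residue-confirmed ones (``hmm_plus_residues``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import pandas as pd

from .model import (
    EnzymeFunctionalDomain,
    HierarchyNode,
    ModelError,
    SequenceRecord,
    efd_slice,
)
from .scoring import Hit, ScoringParams, score_profile


class AnnotationError(ValueError):
    pass


@dataclass
class ResidueCheck:
    node: str
    msa_column: int
    allowed: frozenset
    observed: Optional[str]  # None when the column is deleted in the query
    passed: bool
    role: str = ""


@dataclass
class LevelScore:
    node: str
    level: str
    bit_score: float
    ga: float
    passed: bool


@dataclass
class AnnotationResult:
    query: str
    assigned_level: str  # none | superfamily | subgroup | family
    assigned_node: Optional[str]
    per_level_scores: Dict[str, LevelScore] = field(default_factory=dict)
    residue_report: List[ResidueCheck] = field(default_factory=list)
    evidence: str = "hmm_only"
    diagnostics: List[str] = field(default_factory=list)


def check_residues(hit: Hit, node: HierarchyNode,
                   query: SequenceRecord) -> List[ResidueCheck]:
    """Verify a node's conserved-residue specs on an aligned query.

    Each spec's seed-MSA column is mapped to a profile match column, and
    the query residue aligned there is read through the hit's column trace.
    A spec passes iff that residue is in the allowed set; a spec whose
    column is deleted in the query (no trace entry) fails.
    """
    if node.profile is None:
        raise AnnotationError(f"node {node.name} has no profile")
    if not node.residue_specs:
        raise AnnotationError(f"node {node.name} has no residue specs")
    report = []
    for spec in node.residue_specs:
        pcol = node.profile.msa_to_profile_column(spec.msa_column)
        qpos = hit.column_trace.get(pcol)
        observed = query.sequence[qpos - 1] if qpos is not None else None
        report.append(ResidueCheck(
            node=node.name,
            msa_column=spec.msa_column,
            allowed=spec.allowed_residues,
            observed=observed,
            passed=observed is not None and observed in spec.allowed_residues,
            role=spec.role,
        ))
    return report


def _evaluate_node(node: HierarchyNode, query: SequenceRecord,
                   params: Optional[ScoringParams]):
    if node.profile is None or node.cutoffs is None:
        raise AnnotationError(f"uncalibrated node: {node.name}")
    hit = score_profile(node.profile, query, params)
    score_ok = hit.bit_score >= node.cutoffs.ga
    checks: List[ResidueCheck] = []
    if score_ok and node.residue_specs:
        checks = check_residues(hit, node, query)
    return hit, score_ok, checks


def assign(query: SequenceRecord, root: HierarchyNode,
           params: Optional[ScoringParams] = None) -> AnnotationResult:
    """Assign one query to the deepest supportable hierarchy node.

    The superfamily profile is evaluated first; a query below the
    superfamily GA is left unassigned.  Otherwise every child whose bit
    score reaches its own GA is followed recursively.  Family candidacy
    additionally requires all family residue specs to pass.  Among the
    candidates, the deepest level wins; ties go to the higher bit score,
    then to the lexicographically smaller node name.
    """
    result = AnnotationResult(query=query.id, assigned_level="none",
                              assigned_node=None)

    hit, score_ok, checks = _evaluate_node(root, query, params)
    result.per_level_scores[root.name] = LevelScore(
        root.name, root.level, hit.bit_score, root.cutoffs.ga, score_ok)
    result.residue_report.extend(checks)
    if not score_ok:
        return result

    candidates = []  # (depth, node, hit, residues_all_passed)

    def residues_ok(node_checks):
        return all(c.passed for c in node_checks)

    def visit(node, hit, node_checks, depth):
        if node.level == "family":
            if residues_ok(node_checks):
                candidates.append((depth, node, hit, bool(node_checks)))
            else:
                result.diagnostics.append(
                    f"family {node.name} passed its GA but failed "
                    f"residue check(s); held at parent level"
                )
            return
        candidates.append((depth, node, hit, bool(node_checks) and
                           residues_ok(node_checks)))
        for child in node.children:
            c_hit, c_ok, c_checks = _evaluate_node(child, query, params)
            result.per_level_scores[child.name] = LevelScore(
                child.name, child.level, c_hit.bit_score,
                child.cutoffs.ga, c_ok)
            result.residue_report.extend(c_checks)
            if c_ok:
                visit(child, c_hit, c_checks, depth + 1)

    visit(root, hit, checks, 0)

    candidates.sort(key=lambda c: (-c[0], -c[2].bit_score, c[1].name))
    depth, node, best_hit, residue_backed = candidates[0]
    runners = [c for c in candidates[1:] if c[0] == depth]
    for _, other, other_hit, _ in runners:
        result.diagnostics.append(
            f"{other.level} {other.name} also passed at this level "
            f"(bit score {other_hit.bit_score:.1f})"
        )
    result.assigned_node = node.name
    result.assigned_level = node.level
    result.evidence = "hmm_plus_residues" if residue_backed else "hmm_only"
    return result


def _lineage(root: HierarchyNode, name: str) -> Dict[str, str]:
    """Level -> node name for the named node's path from the root."""
    for node in root.walk():
        if node.name == name:
            out = {}
            cur = node
            while cur is not None:
                out.setdefault(cur.level, cur.name)
                cur = cur.parent
            return out
    return {}


def batch_annotate(db: List[SequenceRecord], root: HierarchyNode,
                   params: Optional[ScoringParams] = None,
                   efds: Optional[Dict[str, EnzymeFunctionalDomain]] = None
                   ) -> pd.DataFrame:
    """Annotate a set of queries; one TSV-ready row per query, id-ascending.

    When an EFD is supplied for a query id, classification runs on the EFD
    slice (so partner functions on the same chain cannot mislead it) but
    the row keeps the original id.
    """
    ids = [s.id for s in db]
    if len(set(ids)) != len(ids):
        raise AnnotationError("id collision in query set")
    rows = []
    for rec in sorted(db, key=lambda s: s.id):
        query = rec
        if efds and rec.id in efds:
            query = efd_slice(rec, efds[rec.id])
        res = assign(query, root, params)
        lineage = (_lineage(root, res.assigned_node)
                   if res.assigned_node else {})

        def bits_for(level):
            name = lineage.get(level)
            if name and name in res.per_level_scores:
                return round(res.per_level_scores[name].bit_score, 2)
            return ""

        rows.append({
            "id": rec.id,
            "sf": lineage.get("superfamily", ""),
            "subgroup": lineage.get("subgroup", ""),
            "family": lineage.get("family", ""),
            "sf_bits": bits_for("superfamily"),
            "subgroup_bits": bits_for("subgroup"),
            "family_bits": bits_for("family"),
            "assigned_level": res.assigned_level,
            "evidence": res.evidence,
        })
    columns = ["id", "sf", "subgroup", "family", "sf_bits", "subgroup_bits",
               "family_bits", "assigned_level", "evidence"]
    return pd.DataFrame(rows, columns=columns)
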