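"""Readers and writers for the formats the curation pipeline touches.

FASTA and Stockholm parsing delegate to Biopython; the Stockholm path uses
the ``Bio.Align`` Alignment API because it preserves arbitrary ``#=GC``
column-annotation lines, which carry the functional-residue column mask
under the reserved tag ``FUNC_RES`` (``x`` marks a functional column, ``.``
everything else).  Hierarchies are serialized as a single JSON document with
per-node seed alignments written as Stockholm files next to it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

from Bio import Align as _BioAlign
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .model import (
    AA20,
    GAP_CHARS,
    FunctionalResidueSpec,
    HierarchyNode,
    ModelError,
    SequenceRecord,
)

FUNC_RES_TAG = "FUNC_RES"

#: ambiguity codes silently narrowed to X on input (with a warning)
AMBIGUOUS_TO_X = set("BJZOU")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Alignment container


@dataclass
class Alignment:
    """A multiple sequence alignment with per-column annotations.

    ``rows`` are ordered ``(id, gapped_sequence)`` pairs of equal width.
    ``column_annotations`` maps a ``#=GC`` tag to a width-long string; the
    ``FUNC_RES`` tag is the functional-residue column mask.
    """

    rows: List[Tuple[str, str]]
    column_annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("alignment has no rows")
        w = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != w:
                raise FormatError(
                    f"ragged alignment: row {rid!r} has width {len(seq)}, "
                    f"expected {w}"
                )
        for tag, ann in self.column_annotations.items():
            if len(ann) != w:
                raise FormatError(
                    f"column annotation {tag!r} has width {len(ann)}, "
                    f"expected {w}"
                )

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> List[str]:
        return [rid for rid, _ in self.rows]

    def column(self, col: int) -> str:
        """1-based column as a string (gap characters included)."""
        if not (1 <= col <= self.width):
            raise FormatError(f"column {col} outside alignment width {self.width}")
        return "".join(seq[col - 1] for _, seq in self.rows)

    def ungapped(self, rid: str) -> str:
        for r, seq in self.rows:
            if r == rid:
                return "".join(c for c in seq if c not in GAP_CHARS)
        raise KeyError(rid)

    def functional_columns(self) -> List[int]:
        """1-based columns marked in the FUNC_RES mask."""
        mask = self.column_annotations.get(FUNC_RES_TAG, "")
        return [i + 1 for i, c in enumerate(mask) if c not in ".-"]

    def residue_specs(self, role: str = "") -> List[FunctionalResidueSpec]:
        """Turn the FUNC_RES mask into residue specs.

        The allowed set at each marked column is the set of (non-gap)
        residues observed in the seed alignment at that column.
        """
        specs = []
        for col in self.functional_columns():
            residues = frozenset(c for c in self.column(col) if c in AA20)
            if residues:
                specs.append(FunctionalResidueSpec(col, residues, role))
        return specs

    def to_records(self) -> List[SequenceRecord]:
        return [
            SequenceRecord(rid, "".join(c for c in seq if c not in GAP_CHARS))
            for rid, seq in self.rows
        ]


# ---------------------------------------------------------------------------
# FASTA


def _clean_sequence(seq: str, rid: str) -> str:
    if seq != seq.upper():
        warnings.warn(f"{rid}: lowercase residues uppercased")
        seq = seq.upper()
    bad = set(seq) - set(AA20 + "X")
    amb = bad & AMBIGUOUS_TO_X
    if amb:
        warnings.warn(
            f"{rid}: ambiguity code(s) {sorted(amb)} substituted with X"
        )
        for c in amb:
            seq = seq.replace(c, "X")
        bad -= amb
    if bad:
        raise FormatError(f"{rid}: illegal residue character(s) {sorted(bad)}")
    return seq


def read_fasta(path) -> List[SequenceRecord]:
    """Read a protein FASTA file into SequenceRecords.

    Duplicate ids are rejected; lowercase is uppercased with a warning;
    the ambiguity codes B/J/Z/O/U are substituted with X (warning); any
    other non-standard character is an error.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(rec.id, seq, desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Stockholm


def read_stockholm(path) -> Alignment:
    """Read a single-alignment Stockholm 1.0 file, keeping #=GC lines."""
    try:
        aln = _BioAlign.read(str(path), "stockholm")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    rows = [(rec.id, str(aln[i])) for i, rec in enumerate(aln.sequences)]
    anns = dict(getattr(aln, "column_annotations", {}) or {})
    # Bio.Align maps some Pfam tags to long names; map them back
    renames = {"consensus sequence": "seq_cons", "secondary structure": "SS_cons"}
    anns = {renames.get(k, k): v for k, v in anns.items()}
    return Alignment(rows=rows, column_annotations=anns)


def write_stockholm(aln: Alignment, path) -> None:
    path = Path(path)
    name_w = max(max(len(rid) for rid in aln.ids), len("#=GC " + FUNC_RES_TAG))
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for rid, seq in aln.rows:
            fh.write(f"{rid:<{name_w}}  {seq}\n")
        for tag, ann in aln.column_annotations.items():
            label = f"#=GC {tag}"
            fh.write(f"{label:<{name_w}}  {ann}\n")
        fh.write("//\n")


def write_fasta_alignment(aln: Alignment, path) -> None:
    """Convenience gapped-FASTA export of an alignment."""
    with open(path, "w") as fh:
        for rid, seq in aln.rows:
            fh.write(f">{rid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Query-to-MSA alignment and text rendering


def align_query_to_msa(query: SequenceRecord, node: HierarchyNode) -> Alignment:
    """Append ``query`` to a node's seed alignment as the final row.

    The query is threaded through the node's profile: each profile match
    column receives the query residue aligned to it (via the alignment
    trace), other columns receive gaps.  Query residues inserted between
    profile columns are not displayed.  Existing rows are untouched.
    """
    from .scoring import score_profile  # deferred: scoring imports model only

    if node.profile is None:
        raise ModelError(f"node {node.name} has no profile")
    if node.seed_msa is None:
        raise ModelError(f"node {node.name} has no seed alignment")
    hit = score_profile(node.profile, query)
    if hit.raw_score <= 0:
        raise ModelError(f"query {query.id} is unalignable to {node.name}")
    width = node.seed_msa.width
    row = ["-"] * width
    for pcol, qpos in hit.column_trace.items():
        mcol = node.profile.column_map[pcol - 1]  # 1-based MSA column
        row[mcol - 1] = query.sequence[qpos - 1]
    return Alignment(
        rows=list(node.seed_msa.rows) + [(query.id, "".join(row))],
        column_annotations=dict(node.seed_msa.column_annotations),
    )


def render_alignment_text(aln: Alignment) -> str:
    """Plain-text rendering with a caret line under functional columns."""
    name_w = max(len(rid) for rid in aln.ids)
    lines = [f"{rid:<{name_w}}  {seq}" for rid, seq in aln.rows]
    marks = set(aln.functional_columns())
    if marks:
        caret = "".join("^" if i + 1 in marks else " " for i in range(aln.width))
        lines.append(f"{'':<{name_w}}  {caret}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Hierarchy JSON (+ Stockholm side files)


def _node_to_json(node: HierarchyNode, msa_dir: Optional[Path], base: Path):
    d = {
        "level": node.level,
        "name": node.name,
        "members": sorted(node.members),
        "reaction_note": node.reaction_note,
        "residue_specs": [
            {
                "msa_column": s.msa_column,
                "allowed_residues": "".join(sorted(s.allowed_residues)),
                "role": s.role,
            }
            for s in node.residue_specs
        ],
        "cutoffs": None,
        "seed_msa": None,
        "children": [
            _node_to_json(c, msa_dir, base) for c in node.children
        ],
    }
    if node.cutoffs is not None:
        d["cutoffs"] = node.cutoffs.to_dict()
    if node.seed_msa is not None and msa_dir is not None:
        fname = f"{node.level}_{node.name}.sto".replace("/", "_")
        write_stockholm(node.seed_msa, msa_dir / fname)
        d["seed_msa"] = str((msa_dir / fname).relative_to(base))
    return d


def save_hierarchy(root: HierarchyNode, path) -> None:
    """Write the tree as JSON; seed MSAs go to ``<stem>_msa/`` beside it."""
    path = Path(path)
    msa_dir = path.parent / (path.stem + "_msa")
    msa_dir.mkdir(parents=True, exist_ok=True)
    doc = _node_to_json(root, msa_dir, path.parent)
    path.write_text(json.dumps(doc, indent=1))


def _node_from_json(d: dict, base: Path) -> HierarchyNode:
    from .calibrate import Cutoffs

    specs = [
        FunctionalResidueSpec(
            s["msa_column"], frozenset(s["allowed_residues"]), s.get("role", "")
        )
        for s in d.get("residue_specs", [])
    ]
    node = HierarchyNode(
        level=d["level"],
        name=d["name"],
        members=d.get("members", ()),
        residue_specs=specs,
        reaction_note=d.get("reaction_note", ""),
    )
    if d.get("seed_msa"):
        node.seed_msa = read_stockholm(base / d["seed_msa"])
    if d.get("cutoffs"):
        node.cutoffs = Cutoffs.from_dict(d["cutoffs"])
    for c in d.get("children", []):
        node.add_child(_node_from_json(c, base))
    return node


def load_hierarchy(path) -> HierarchyNode:
    path = Path(path)
    doc = json.loads(path.read_text())
    return _node_from_json(doc, path.parent)


# ---------------------------------------------------------------------------
# Per-sequence annotation TSV (fixed column order)

ANNOTATION_COLUMNS = [
    "id", "sf", "subgroup", "family", "evidence_level", "species", "ec", "notes",
]


def write_sequence_annotations(
    records: Iterable[SequenceRecord], root: HierarchyNode, path
) -> None:
    """Export one row per sequence with its hierarchy placement and metadata.

    Placement is by curated membership (the deepest node whose member set
    contains the id), independent of any profile scoring.
    """
    import pandas as pd

    placement = {}
    for node in root.walk():
        for m in node.members:
            placement.setdefault(m, {})[node.level] = node.name
    rows = []
    for r in records:
        p = placement.get(r.id, {})
        level = "family" if "family" in p else (
            "subgroup" if "subgroup" in p else (
                "superfamily" if "superfamily" in p else "none"))
        rows.append({
            "id": r.id,
            "sf": p.get("superfamily", ""),
            "subgroup": p.get("subgroup", ""),
            "family": p.get("family", ""),
            "evidence_level": level,
            "species": r.metadata.get("species", ""),
            "ec": r.metadata.get("ec", ""),
            "notes": r.metadata.get("notes", ""),
        })
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
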