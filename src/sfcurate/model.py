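"""Core data model for hierarchical enzyme-superfamily curation.

The classification hierarchy has three levels of granularity — superfamily,
subgroup(s) and family — where a superfamily is a set of homologous enzymes
conserving an aspect of chemical function, a subgroup is a similarity-defined
subdivision sharing additional functional features, and a family is an
isofunctional set (same overall reaction, similar mechanism).  Subgroups may
nest.

Annotation is attached to *enzyme functional domains* (EFDs) rather than to
whole chains: the EFD is the portion of a sequence responsible for one
annotated function, and within it the *superfamily domain* (SFD) is the part
that performs the chemistry conserved across the superfamily.  Multi-domain
and multi-functional proteins therefore carry one EFD per function, each
independently classifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

AA20 = "ACDEFGHIKLMNPQRSTVWY"
SEQUENCE_ALPHABET = frozenset(AA20 + "X")

LEVELS = ("superfamily", "subgroup", "family")

GAP_CHARS = frozenset("-.")


class ModelError(ValueError):
    """Raised on violated structural preconditions (bad ranges, bad residues)."""


@dataclass
class SequenceRecord:
    """A protein sequence with free-form metadata.

    ``sequence`` is restricted to the 20 standard amino acids plus ``X``
    (unknown); lowercase input is normalised to uppercase by the I/O layer.
    """

    id: str
    sequence: str
    description: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("sequence id must be non-empty")
        if len(self.sequence) < 1:
            raise ModelError(f"{self.id}: sequence must be non-empty")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ModelError(
                f"{self.id}: illegal residue character(s) {sorted(bad)!r}; "
                f"alphabet is {AA20}X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainRange:
    """A 1-based, inclusive residue span on an owner sequence.

    ``homology_class`` distinguishes the superfamily domain proper
    (``sf_domain``), additional domains required for the function
    (``efd_partner``), and spans unrelated to the annotated function
    (``unrelated``).
    """

    start: int
    end: int
    label: str = ""
    homology_class: str = "sf_domain"

    HOMOLOGY_CLASSES = ("sf_domain", "efd_partner", "unrelated")

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ModelError(f"invalid domain range {self.start}..{self.end}")
        if self.homology_class not in self.HOMOLOGY_CLASSES:
            raise ModelError(f"unknown homology class {self.homology_class!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "DomainRange") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class EnzymeFunctionalDomain:
    """One function's worth of domains on a sequence (the EFD).

    ``ranges`` may be discontiguous; they must be pairwise non-overlapping
    and contain at least one ``sf_domain`` span (the SFD).
    """

    owner: str
    ranges: list  # ordered list of DomainRange
    function_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ModelError(f"EFD on {self.owner}: needs at least one range")
        for i, a in enumerate(self.ranges):
            for b in self.ranges[i + 1:]:
                if a.overlaps(b):
                    raise ModelError(
                        f"EFD on {self.owner}: overlapping ranges "
                        f"{a.start}..{a.end} and {b.start}..{b.end}"
                    )
        if not self.sfd_ranges:
            raise ModelError(f"EFD on {self.owner}: no sf_domain range (SFD)")

    @property
    def sfd_ranges(self) -> list:
        return [r for r in self.ranges if r.homology_class == "sf_domain"]

    def length(self) -> int:
        return sum(len(r) for r in self.ranges)


def efd_slice(record: SequenceRecord, efd: EnzymeFunctionalDomain) -> SequenceRecord:
    """Extract the EFD subsequence of ``record`` as a new record.

    Classification operates on EFD slices rather than full chains so that a
    multi-functional protein cannot drag sequences matching only one of its
    functions into another function's dataset.  Ranges are concatenated in
    their stored order and the id gains a range-descriptor suffix.
    """
    if efd.owner != record.id:
        raise ModelError(f"EFD owner {efd.owner!r} != record id {record.id!r}")
    n = len(record.sequence)
    parts = []
    for r in efd.ranges:
        if r.end > n:
            raise ModelError(
                f"invalid domain range {r.start}..{r.end} on {record.id} "
                f"(length {n})"
            )
        parts.append(record.sequence[r.start - 1: r.end])
    desc = "_".join(f"{r.start}-{r.end}" for r in efd.ranges)
    return SequenceRecord(
        id=f"{record.id}/{desc}",
        sequence="".join(parts),
        description=record.description,
        metadata=dict(record.metadata, efd_of=record.id),
    )


@dataclass(frozen=True)
class FunctionalResidueSpec:
    """A conserved functional residue, addressed by seed-MSA column.

    ``msa_column`` is 1-based in the owning node's seed alignment;
    ``allowed_residues`` is the set of amino acids accepted at that column;
    ``role`` is free text (e.g. "metal ligand", "general acid-base").
    """

    msa_column: int
    allowed_residues: frozenset
    role: str = ""

    def __post_init__(self) -> None:
        if self.msa_column < 1:
            raise ModelError("msa_column must be >= 1")
        allowed = frozenset(self.allowed_residues)
        object.__setattr__(self, "allowed_residues", allowed)
        if not allowed or not allowed <= frozenset(AA20):
            raise ModelError(
                f"allowed_residues must be a non-empty subset of {AA20}"
            )


class HierarchyNode:
    """One classification unit: a superfamily, subgroup or family.

    Carries the member id set, the seed alignment the profile is built from,
    the profile itself once built, calibrated cutoffs, and the level's
    conserved-residue specifications.  Families are leaves; subgroups may
    parent further subgroups.
    """

    def __init__(
        self,
        level: str,
        name: str,
        members: Optional[Iterable] = None,
        seed_msa=None,
        residue_specs: Optional[list] = None,
        reaction_note: str = "",
    ):
        if level not in LEVELS:
            raise ModelError(f"unknown hierarchy level {level!r}")
        self.level = level
        self.name = name
        self.parent: Optional[HierarchyNode] = None
        self.children: list = []
        self.members: set = set(members or ())
        self.seed_msa = seed_msa  # io.Alignment or None
        self.profile = None  # scoring.ProfileModel or None
        self.cutoffs = None  # calibrate.Cutoffs or None
        self.residue_specs: list = list(residue_specs or ())
        self.reaction_note = reaction_note

    def add_child(self, child: "HierarchyNode") -> "HierarchyNode":
        child.parent = self
        self.children.append(child)
        return child

    def walk(self):
        """Yield this node and all descendants, depth-first, parents first."""
        yield self
        for c in self.children:
            yield from c.walk()

    def families(self):
        return [n for n in self.walk() if n.level == "family"]

    def __repr__(self) -> str:
        return (
            f"HierarchyNode({self.level} {self.name!r}, "
            f"{len(self.members)} members, {len(self.children)} children)"
        )


@dataclass
class Violation:
    kind: str  # containment | level | residue spec unsatisfiable | ...
    node: str
    detail: str


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    def add(self, kind: str, node: str, detail: str) -> None:
        self.violations.append(Violation(kind, node, detail))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff clean
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "hierarchy OK"
        return "\n".join(
            f"[{v.kind}] {v.node}: {v.detail}" for v in self.violations
        )


def _spec_satisfiable(spec: FunctionalResidueSpec, msa) -> bool:
    """A residue spec is satisfiable by an alignment if at least one row
    carries an allowed residue in the spec's column."""
    col = msa.column(spec.msa_column)
    return any(c in spec.allowed_residues for c in col)


def validate_hierarchy(root: HierarchyNode) -> ValidationReport:
    """Check structural invariants of a classification tree.

    Violations are reported, never raised: the report is the curator's
    worklist.  Checks: the root is a superfamily and the only parentless
    node; families are leaves; child member sets are contained in their
    parents'; residue-spec columns fall inside their node's seed alignment;
    and every superfamily- or subgroup-level spec is satisfiable by each
    descendant family's seed alignment (conservation at a higher level must
    hold for all descendants).
    """
    report = ValidationReport()
    if root.level != "superfamily":
        report.add("level", root.name, f"root has level {root.level}, expected superfamily")
    if root.parent is not None:
        report.add("level", root.name, "superfamily must not have a parent")
    for node in root.walk():
        if node.level == "family" and node.children:
            report.add("level", node.name, "family nodes must be leaves")
        if node.level == "subgroup" and node.parent is None:
            report.add("level", node.name, "subgroup without parent")
        for child in node.children:
            missing = child.members - node.members
            if missing:
                report.add(
                    "containment",
                    child.name,
                    f"{len(missing)} member(s) absent from parent "
                    f"{node.name}: {sorted(missing)[:5]}",
                )
        if node.seed_msa is not None:
            for spec in node.residue_specs:
                if spec.msa_column > node.seed_msa.width:
                    report.add(
                        "residue spec out of range",
                        node.name,
                        f"column {spec.msa_column} > alignment width "
                        f"{node.seed_msa.width}",
                    )
        # higher-level specs must be satisfiable in every descendant family
        if node.level in ("superfamily", "subgroup") and node.residue_specs:
            for fam in node.families():
                if fam.seed_msa is None:
                    continue
                for spec in node.residue_specs:
                    if spec.msa_column > fam.seed_msa.width:
                        report.add(
                            "residue spec unsatisfiable",
                            node.name,
                            f"column {spec.msa_column} outside family "
                            f"{fam.name} alignment",
                        )
                    elif not _spec_satisfiable(spec, fam.seed_msa):
                        report.add(
                            "residue spec unsatisfiable",
                            node.name,
                            f"column {spec.msa_column} of family {fam.name} "
                            f"seed MSA has no residue in "
                            f"{sorted(spec.allowed_residues)}",
                        )
    return report


def check_unique_ids(records: Iterable[SequenceRecord]) -> None:
    seen = set()
    for r in records:
        if r.id in seen:
            raise ModelError(f"id collision: {r.id!r}")
        seen.add(r.id)
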