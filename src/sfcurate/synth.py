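"""Synthetic functionally-diverse superfamilies with known ground truth.

The generator emulates the structure the curation pipeline is built for: a
common ancestor diverges into subgroups, each subgroup into isofunctional
families, with conserved functional residues planted at every level of the
hierarchy and held fixed down-lineage — superfamily-level residues are
identical in every member, subgroup-level residues within a subgroup,
family-level residues within a family.  A fraction of members additionally
carry an unrelated extra domain appended to the chain, creating the
multi-domain architectures that make whole-chain classification unsafe
(the ground truth records the enzyme-functional-domain span).

Substitutions are i.i.d. per site on a uniform residue background; an
optional indel mode deletes or inserts sites at a small rate (deletions
appear as gaps in the seed alignments, insertions live only in the
sequences).  This is deliberately the simplest model that still exercises
alignment, profile scoring and residue checks; see the methods note for
what it does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io import FUNC_RES_TAG, Alignment, save_hierarchy, write_fasta
from .model import (
    AA20,
    DomainRange,
    EnzymeFunctionalDomain,
    FunctionalResidueSpec,
    HierarchyNode,
    SequenceRecord,
)

_AA = np.array(list(AA20))


class SynthError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Study conditions for the synthetic superfamily.

    Divergences are per-site substitution probabilities applied at each
    branching of the hierarchy (subgroup ancestors from the superfamily
    ancestor, family ancestors from their subgroup ancestor, members from
    their family ancestor); they must increase with hierarchical distance.
    ``total_members``, when set, overrides ``members_per_family`` by
    distributing a fixed total across the families as evenly as possible.
    """

    seed: int = 0
    ancestor_length: int = 280
    n_subgroups: int = 3
    families_per_subgroup: int = 2
    members_per_family: int = 40
    total_members: Optional[int] = None
    subgroup_divergence: float = 0.45
    family_divergence: float = 0.25
    within_family_divergence: float = 0.08
    sf_residues: int = 4
    subgroup_residues: int = 3
    family_residues: int = 3
    extra_domain_prob: float = 0.3
    extra_domain_length: Tuple[int, int] = (80, 160)
    indel_rate: float = 0.0
    mutant_fraction: float = 0.2
    queries_per_family: int = 20

    def __post_init__(self) -> None:
        divs = (self.within_family_divergence, self.family_divergence,
                self.subgroup_divergence)
        if any(not (0.0 <= d < 1.0) for d in divs):
            raise SynthError("divergences must be in [0, 1)")
        if not (divs[0] < divs[1] < divs[2]):
            raise SynthError(
                "divergences must increase: within_family < family < subgroup")
        n_planted = self.sf_residues + self.subgroup_residues + self.family_residues
        if n_planted >= self.ancestor_length:
            raise SynthError(
                f"{n_planted} planted positions do not fit in "
                f"{self.ancestor_length} residues")

    @property
    def n_families(self) -> int:
        return self.n_subgroups * self.families_per_subgroup

    def family_sizes(self) -> List[int]:
        if self.total_members is None:
            return [self.members_per_family] * self.n_families
        base, extra = divmod(self.total_members, self.n_families)
        return [base + (1 if i < extra else 0) for i in range(self.n_families)]


def _random_seq(rng, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length)


def _mutate(rng, seq: np.ndarray, p: float, protected: np.ndarray) -> np.ndarray:
    """i.i.d. substitution at rate p, never touching protected positions.

    A substituted site always changes (draw among the 19 other residues).
    """
    out = seq.copy()
    mask = rng.random(seq.size) < p
    mask[protected] = False
    idx = np.nonzero(mask)[0]
    if idx.size:
        shift = rng.integers(1, 20, size=idx.size)
        out[idx] = (out[idx] + shift) % 20
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_AA[seq])


@dataclass
class SynthMember:
    id: str
    subgroup: str
    family: str
    core: np.ndarray  # match-state residues (−1 where deleted)
    sequence: str  # full chain, extra domain included
    efd: EnzymeFunctionalDomain
    has_extra_domain: bool


@dataclass
class SynthResult:
    config: SynthConfig
    root: HierarchyNode
    records: List[SequenceRecord]
    members: List[SynthMember]
    efds: Dict[str, EnzymeFunctionalDomain]
    ground_truth: pd.DataFrame
    planted_positions: Dict[str, List[int]]  # level -> 1-based core positions
    family_residues: Dict[str, Dict[int, str]]  # family -> {position: residue}
    family_ancestors: Dict[str, np.ndarray] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out_dir / "superfamily.fasta")
        save_hierarchy(self.root, out_dir / "hierarchy.json")
        self.ground_truth.to_csv(out_dir / "ground_truth.tsv", sep="\t",
                                 index=False)


def _member_row(core: np.ndarray) -> str:
    return "".join("-" if c < 0 else _AA[c] for c in core)


def _make_alignment(rows: List[Tuple[str, str]],
                    func_columns: List[int], width: int) -> Alignment:
    mask = "".join("x" if (i + 1) in func_columns else "."
                   for i in range(width))
    return Alignment(rows=rows, column_annotations={FUNC_RES_TAG: mask})


def generate_superfamily(cfg: SynthConfig) -> SynthResult:
    """Generate a superfamily, its hierarchy and its ground truth.

    Fully reproducible from ``cfg.seed``: same config, same output.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.ancestor_length

    n_planted = cfg.sf_residues + cfg.subgroup_residues + cfg.family_residues
    planted = rng.choice(L, size=n_planted, replace=False)
    sf_pos = np.sort(planted[: cfg.sf_residues])
    sub_pos = np.sort(planted[cfg.sf_residues:
                              cfg.sf_residues + cfg.subgroup_residues])
    fam_pos = np.sort(planted[cfg.sf_residues + cfg.subgroup_residues:])
    all_planted = np.concatenate([sf_pos, sub_pos, fam_pos])

    ancestor = _random_seq(rng, L)

    members: List[SynthMember] = []
    family_residues: Dict[str, Dict[int, str]] = {}
    subgroup_residues: Dict[str, Dict[int, str]] = {}
    fam_sizes = cfg.family_sizes()
    fam_i = 0
    subgroup_ancestors = {}
    family_ancestors = {}
    for s in range(1, cfg.n_subgroups + 1):
        sg_name = f"sg{s}"
        sg_anc = _mutate(rng, ancestor, cfg.subgroup_divergence, sf_pos)
        # plant this subgroup's conserved residues
        sg_anc[sub_pos] = rng.integers(0, 20, size=sub_pos.size)
        subgroup_ancestors[sg_name] = sg_anc
        subgroup_residues[sg_name] = {
            int(p) + 1: _AA[sg_anc[p]] for p in sub_pos}
        for f in range(1, cfg.families_per_subgroup + 1):
            fam_name = f"{sg_name}_f{f}"
            fam_anc = _mutate(rng, sg_anc, cfg.family_divergence,
                              np.concatenate([sf_pos, sub_pos]))
            fam_anc[fam_pos] = rng.integers(0, 20, size=fam_pos.size)
            family_ancestors[fam_name] = fam_anc
            family_residues[fam_name] = {
                int(p) + 1: _AA[fam_anc[p]] for p in fam_pos}
            for m in range(1, fam_sizes[fam_i] + 1):
                mid = f"{fam_name}_m{m:04d}"
                members.append(_make_member(
                    rng, cfg, mid, sg_name, fam_name, fam_anc, all_planted))
            fam_i += 1

    records = [SequenceRecord(m.id, m.sequence,
                              metadata={"subgroup": m.subgroup,
                                        "family": m.family})
               for m in members]
    efds = {m.id: m.efd for m in members}

    root = _build_hierarchy(cfg, members, ancestor, sf_pos, sub_pos, fam_pos,
                            subgroup_residues, family_residues, L)

    gt_rows = []
    for m in members:
        efd_sfd = m.efd.sfd_ranges[0]
        gt_rows.append({
            "id": m.id,
            "sf": "SF",
            "subgroup": m.subgroup,
            "family": m.family,
            "efd_start": efd_sfd.start,
            "efd_end": efd_sfd.end,
            "has_extra_domain": m.has_extra_domain,
            "length": len(m.sequence),
        })
    ground_truth = pd.DataFrame(gt_rows)

    return SynthResult(
        config=cfg, root=root, records=records, members=members, efds=efds,
        ground_truth=ground_truth,
        planted_positions={
            "superfamily": [int(p) + 1 for p in sf_pos],
            "subgroup": [int(p) + 1 for p in sub_pos],
            "family": [int(p) + 1 for p in fam_pos],
        },
        family_residues=family_residues,
        family_ancestors=family_ancestors,
    )


def _make_member(rng, cfg: SynthConfig, mid: str, sg: str, fam: str,
                 fam_anc: np.ndarray, protected: np.ndarray) -> SynthMember:
    core = _mutate(rng, fam_anc, cfg.within_family_divergence, protected)
    # optional indels: deletions shown as gaps in the seed alignment,
    # insertions live in the chain between match states
    deletions = np.zeros(core.size, dtype=bool)
    insert_after = {}
    if cfg.indel_rate > 0:
        dmask = rng.random(core.size) < cfg.indel_rate / 2.0
        dmask[protected] = False
        deletions = dmask
        imask = rng.random(core.size) < cfg.indel_rate / 2.0
        for pos in np.nonzero(imask)[0]:
            insert_after[int(pos)] = int(rng.integers(0, 20))
    chain = []
    for i, aa in enumerate(core):
        if not deletions[i]:
            chain.append(int(aa))
        if i in insert_after:
            chain.append(insert_after[i])
    core_seq = np.array(chain, dtype=int)
    core_len = core_seq.size

    has_extra = bool(rng.random() < cfg.extra_domain_prob)
    if has_extra:
        elen = int(rng.integers(cfg.extra_domain_length[0],
                                cfg.extra_domain_length[1] + 1))
        extra = _random_seq(rng, elen)
        full = np.concatenate([core_seq, extra])
        ranges = [DomainRange(1, core_len, label="core",
                              homology_class="sf_domain")]
        efd = EnzymeFunctionalDomain(owner=mid, ranges=ranges)
    else:
        full = core_seq
        efd = EnzymeFunctionalDomain(
            owner=mid,
            ranges=[DomainRange(1, core_len, label="core",
                                homology_class="sf_domain")])
    aligned_core = core.copy()
    aligned_core[deletions] = -1
    return SynthMember(id=mid, subgroup=sg, family=fam, core=aligned_core,
                       sequence=_decode(full), efd=efd,
                       has_extra_domain=has_extra)


def _build_hierarchy(cfg, members, ancestor, sf_pos, sub_pos, fam_pos,
                     subgroup_residues, family_residues, width):
    by_family: Dict[str, List[SynthMember]] = {}
    by_subgroup: Dict[str, List[SynthMember]] = {}
    for m in members:
        by_family.setdefault(m.family, []).append(m)
        by_subgroup.setdefault(m.subgroup, []).append(m)

    def rows_for(ms):
        return [(m.id, _member_row(m.core)) for m in ms]

    sf_cols = [int(p) + 1 for p in sf_pos]
    sub_cols = [int(p) + 1 for p in sub_pos]
    fam_cols = [int(p) + 1 for p in fam_pos]

    root = HierarchyNode(
        "superfamily", "SF",
        members=[m.id for m in members],
        seed_msa=_make_alignment(rows_for(members), sf_cols, width),
        residue_specs=[
            FunctionalResidueSpec(c, frozenset(_AA[ancestor[c - 1]]),
                                  role="sf-conserved")
            for c in sf_cols
        ],
        reaction_note="shared partial reaction of the synthetic superfamily",
    )
    for sg_name, sg_members in by_subgroup.items():
        sg = root.add_child(HierarchyNode(
            "subgroup", sg_name,
            members=[m.id for m in sg_members],
            seed_msa=_make_alignment(rows_for(sg_members),
                                     sf_cols + sub_cols, width),
            residue_specs=[
                FunctionalResidueSpec(
                    c, frozenset(subgroup_residues[sg_name][c]),
                    role="subgroup-conserved")
                for c in sub_cols
            ],
        ))
        for fam_name, fam_members in by_family.items():
            if not fam_name.startswith(sg_name + "_"):
                continue
            sg.add_child(HierarchyNode(
                "family", fam_name,
                members=[m.id for m in fam_members],
                seed_msa=_make_alignment(rows_for(fam_members),
                                         sf_cols + sub_cols + fam_cols,
                                         width),
                residue_specs=[
                    FunctionalResidueSpec(
                        c, frozenset(family_residues[fam_name][c]),
                        role="family-conserved (catalytic)")
                    for c in fam_cols
                ],
            ))
    return root


@dataclass
class QuerySet:
    records: List[SequenceRecord]
    labels: pd.DataFrame  # id, subgroup, family, is_mutant, template

    def write(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out_dir / "queries.fasta")
        self.labels.to_csv(out_dir / "query_labels.tsv", sep="\t", index=False)


def generate_queries(cfg: SynthConfig, sf: SynthResult) -> QuerySet:
    """Held-out labelled queries, plus catalytic-residue knockouts.

    Intact queries are fresh draws from each family's ancestor (never part
    of the superfamily set); mutants are copies of intact queries with one
    family-level planted residue substituted to a residue outside the
    allowed set.  Mutant count = round(mutant_fraction × intact count).
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    planted = np.array([p - 1 for lvl in sf.planted_positions.values()
                        for p in lvl])
    fam_pos = [p - 1 for p in sf.planted_positions["family"]]

    intact: List[SequenceRecord] = []
    rows = []
    for fam in sf.root.families():
        fam_anc = sf.family_ancestors[fam.name]
        sg_name = fam.parent.name
        for q in range(1, cfg.queries_per_family + 1):
            core = _mutate(rng, fam_anc, cfg.within_family_divergence, planted)
            qid = f"{fam.name}_q{q:03d}"
            has_extra = bool(rng.random() < cfg.extra_domain_prob)
            seq = core
            if has_extra:
                elen = int(rng.integers(cfg.extra_domain_length[0],
                                        cfg.extra_domain_length[1] + 1))
                seq = np.concatenate([core, _random_seq(rng, elen)])
            intact.append(SequenceRecord(qid, _decode(seq)))
            rows.append({"id": qid, "subgroup": sg_name, "family": fam.name,
                         "is_mutant": False, "template": ""})

    n_mut = int(round(cfg.mutant_fraction * len(intact)))
    mutants: List[SequenceRecord] = []
    templates = rng.choice(len(intact), size=n_mut, replace=False)
    for t in sorted(templates):
        tmpl = intact[t]
        fam_name = rows[t]["family"]
        pos = int(fam_pos[int(rng.integers(0, len(fam_pos)))])
        allowed = sf.family_residues[fam_name][pos + 1]
        current = tmpl.sequence[pos]
        choices = [c for c in AA20 if c != allowed and c != current]
        new = choices[int(rng.integers(0, len(choices)))]
        seq = tmpl.sequence[:pos] + new + tmpl.sequence[pos + 1:]
        qid = tmpl.id + "_mut"
        mutants.append(SequenceRecord(qid, seq))
        rows.append({"id": qid, "subgroup": rows[t]["subgroup"],
                     "family": fam_name, "is_mutant": True,
                     "template": tmpl.id})

    labels = pd.DataFrame(rows, columns=["id", "subgroup", "family",
                                         "is_mutant", "template"])
    return QuerySet(records=intact + mutants, labels=labels)
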