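import math
import random

import numpy as np
import pytest

from oracles import local_affine_score
from sfcurate.io import Alignment
from sfcurate.model import AA20, SequenceRecord
from sfcurate.scoring import (
    ScoringError,
    ScoringParams,
    align_local,
    build_profile,
    import_hits,
    score_profile,
    search,
)


def _rand_seq(rng, n):
    return "".join(rng.choice(AA20) for _ in range(n))


class TestAlignLocal:
    def test_self_alignment_score_is_diagonal_sum(self, params):
        seq = "HEAGAWGHEEASDFKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDE"  # 50 aa
        rec = SequenceRecord("a", seq)
        hit = align_local(rec, SequenceRecord("b", seq), params)
        diag = sum(params.substitution_matrix[c, c] for c in seq)
        assert hit.raw_score == diag
        assert hit.column_trace == {i: i for i in range(1, 51)}

    def test_score_symmetry(self, params):
        rng = random.Random(0)
        for _ in range(20):
            a = SequenceRecord("a", _rand_seq(rng, rng.randint(10, 40)))
            b = SequenceRecord("b", _rand_seq(rng, rng.randint(10, 40)))
            assert align_local(a, b, params).raw_score == \
                align_local(b, a, params).raw_score

    def test_classic_pair_matches_bruteforce(self, params):
        score = align_local(SequenceRecord("a", "HEAGAWGHEE"),
                            SequenceRecord("b", "PAWHEAE"), params).raw_score
        assert score == local_affine_score("HEAGAWGHEE", "PAWHEAE")

    def test_bit_score_and_evalue_identities(self, params):
        rng = random.Random(1)
        a = SequenceRecord("a", _rand_seq(rng, 30))
        b = SequenceRecord("b", _rand_seq(rng, 35))
        hit = align_local(a, b, params)
        expected_bits = (params.lam * hit.raw_score - math.log(params.K)) / math.log(2)
        assert hit.bit_score == pytest.approx(expected_bits, rel=1e-9)
        expected_ev = 30 * 35 * 2.0 ** (-hit.bit_score)
        assert hit.evalue == pytest.approx(expected_ev, rel=1e-9)


class TestBuildProfile:
    def test_conserved_column_scores_maximal_for_its_residue(self):
        msa = Alignment([(f"s{i}", "W" * 5) for i in range(10)])
        prof = build_profile(msa)
        w = "ACDEFGHIKLMNPQRSTVWY".index("W")
        assert all(np.argmax(prof.columns[c]) == w for c in range(5))

    def test_gap_majority_columns_excluded(self):
        msa = Alignment([("a", "AC-A"), ("b", "AC-A"), ("c", "ACAA")])
        prof = build_profile(msa)
        assert prof.column_map == [1, 2, 4]

    def test_column_scores_match_hand_formula(self):
        msa = Alignment([("a", "AC"), ("b", "AC"), ("c", "AG")])
        prof = build_profile(msa)
        # column 1: A x3 -> log2(((3+1)/(3+20)) / 0.05)
        assert prof.columns[0, 0] == pytest.approx(
            math.log2(((3 + 1) / 23) / 0.05))
        # column 2: C x2, G x1, others 0
        c_idx = AA20.index("C")
        g_idx = AA20.index("G")
        a_idx = AA20.index("A")
        assert prof.columns[1, c_idx] == pytest.approx(math.log2(((2 + 1) / 23) / 0.05))
        assert prof.columns[1, g_idx] == pytest.approx(math.log2(((1 + 1) / 23) / 0.05))
        assert prof.columns[1, a_idx] == pytest.approx(math.log2(((0 + 1) / 23) / 0.05))

    def test_single_row_msa_rejected(self):
        with pytest.raises(ScoringError, match="insufficient depth"):
            build_profile(Alignment([("a", "ACDE")]))


class TestSearch:
    def test_seeds_score_positive_against_own_profile(self, small_superfamily, params):
        fam = small_superfamily.root.families()[0]
        prof = build_profile(fam.seed_msa, params, source_node=fam.name)
        seeds = [r for r in small_superfamily.records if r.id in fam.members]
        table = search(prof, seeds, params)
        assert all(h.bit_score > 0 for h in table)

    def test_shuffled_sequences_score_below_intact(self, small_superfamily, params):
        fam = small_superfamily.root.families()[0]
        prof = build_profile(fam.seed_msa, params, source_node=fam.name)
        seeds = [r for r in small_superfamily.records if r.id in fam.members]
        rng = random.Random(13)
        shuffled = []
        for r in seeds:
            s = list(r.sequence)
            rng.shuffle(s)
            shuffled.append(SequenceRecord(r.id + "_shuf", "".join(s)))
        table = search(prof, seeds + shuffled, params)
        intact = np.mean([h.bit_score for h in table if not h.target.endswith("_shuf")])
        shuf = np.mean([h.bit_score for h in table if h.target.endswith("_shuf")])
        assert intact > shuf + 100

    def test_result_invariant_to_db_order(self, small_superfamily, params):
        fam = small_superfamily.root.families()[0]
        prof = build_profile(fam.seed_msa, params, source_node=fam.name)
        db = small_superfamily.records[:20]
        t1 = search(prof, db, params)
        t2 = search(prof, list(reversed(db)), params)
        assert [(h.target, h.bit_score) for h in t1] == \
            [(h.target, h.bit_score) for h in t2]

    def test_trace_maps_profile_columns_to_target_positions(self, small_superfamily, params):
        fam = small_superfamily.root.families()[0]
        prof = build_profile(fam.seed_msa, params, source_node=fam.name)
        rec = [r for r in small_superfamily.records if r.id in fam.members][0]
        hit = score_profile(prof, rec, params)
        # ungapped synthetic member: identity mapping over the core
        assert hit.column_trace[1] == 1
        assert hit.column_trace[prof.width] == prof.width


class TestImportHits:
    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "empty.tbl"
        p.write_text("# nothing here\n")
        assert len(import_hits(p, "hmmer_tblout")) == 0

    def test_tblout_fixture_parses_descending(self, tmp_path):
        p = tmp_path / "hits.tbl"
        p.write_text(
            "#                 query\n"
            "seqA - prof - 1e-50 180.2 0.1\n"
            "seqB - prof - 1e-30 120.7 0.0\n"
            "seqC - prof - 1e-10  55.1 0.2\n"
        )
        table = import_hits(p, "hmmer_tblout")
        assert [h.target for h in table] == ["seqA", "seqB", "seqC"]
        assert [h.bit_score for h in table] == [180.2, 120.7, 55.1]

    def test_blast_tab6_parses_coordinates(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t98.5\t100\t2\t0\t1\t100\t11\t110\t1e-40\t150.3\n")
        table = import_hits(p, "blast_tab6")
        hit = table.hits[0]
        assert (hit.query, hit.target) == ("q1", "s1")
        assert (hit.aligned_range.start, hit.aligned_range.end) == (11, 110)

    def test_malformed_score_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tbl"
        p.write_text("seqA - prof - 1e-50 180.2 0.1\n"
                     "seqB - prof - 1e-30 NOTANUMBER 0.0\n")
        with pytest.raises(ScoringError, match=":2:"):
            import_hits(p, "hmmer_tblout")

    def test_unknown_dialect_rejected(self, tmp_path):
        p = tmp_path / "x"
        p.write_text("")
        with pytest.raises(ScoringError, match="unknown dialect"):
            import_hits(p, "csv")
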