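import random

import pytest

from oracles import brute_greedy_cluster, global_affine_score
from sfcurate.model import AA20, SequenceRecord
from sfcurate.seeds import (
    SeedConfig,
    SeedSelectionError,
    greedy_cluster,
    pairwise_identity,
    reduce_seed_set,
)


def _rand_seq(rng, n):
    return "".join(rng.choice(AA20) for _ in range(n))


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        a = SequenceRecord("a", "ACDEFGHIKLMNPQRSTVWY")
        b = SequenceRecord("b", "ACDEFGHIKLMNPQRSTVWY")
        assert pairwise_identity(a, b) == 1.0

    def test_disjoint_alphabets_give_zero(self):
        assert pairwise_identity(SequenceRecord("a", "AAAA"),
                                 SequenceRecord("b", "TTTT")) == 0.0

    def test_single_mismatch(self):
        ident = pairwise_identity(SequenceRecord("a", "ACDEFG"),
                                  SequenceRecord("b", "ACDEYG"))
        assert ident == pytest.approx(5 / 6)

    def test_symmetry_and_score_agrees_with_dp_oracle(self):
        rng = random.Random(11)
        from sfcurate.scoring import ScoringParams
        aligner = ScoringParams().aligner("global")
        for _ in range(30):
            a = _rand_seq(rng, rng.randint(5, 25))
            b = _rand_seq(rng, rng.randint(5, 25))
            assert aligner.score(a, b) == global_affine_score(a, b)
            ra, rb = SequenceRecord("a", a), SequenceRecord("b", b)
            assert pairwise_identity(ra, rb) == pairwise_identity(rb, ra)

    def test_empty_sequence_errors(self):
        rec = SequenceRecord("a", "ACD")
        bad = SequenceRecord("b", "A")
        bad.sequence = ""  # bypass the constructor check
        with pytest.raises(SeedSelectionError):
            pairwise_identity(rec, bad)


class TestGreedyCluster:
    def test_identical_sequences_collapse(self):
        seqs = [SequenceRecord(f"s{i}", "ACDEFGHIKLMNPQRSTVWY" * 3)
                for i in range(50)]
        clusters = greedy_cluster(seqs, 0.9)
        assert len(clusters) == 1
        assert clusters[0].size == 50

    def test_dissimilar_sequences_stay_singletons(self):
        rng = random.Random(3)
        seqs = [SequenceRecord(f"s{i}", _rand_seq(rng, 60)) for i in range(3)]
        for i in range(3):
            for j in range(i + 1, 3):
                assert pairwise_identity(seqs[i], seqs[j]) < 0.4
        assert len(greedy_cluster(seqs, 0.9)) == 3

    def test_input_order_invariance(self):
        rng = random.Random(5)
        base = _rand_seq(rng, 80)
        seqs = []
        for i in range(12):
            s = list(base)
            for p in rng.sample(range(80), rng.randint(0, 25)):
                s[p] = rng.choice(AA20)
            seqs.append(SequenceRecord(f"s{i:02d}", "".join(s)))
        reps = {c.representative.id for c in greedy_cluster(seqs, 0.8)}
        shuffled = seqs[::-1]
        reps2 = {c.representative.id for c in greedy_cluster(shuffled, 0.8)}
        assert reps == reps2

    @pytest.mark.parametrize("identity", [0.9, 0.7, 0.5])
    def test_screened_clustering_equals_bruteforce(self, identity):
        """The length-ratio and edit-distance screens must never change the
        clustering relative to the naive all-pairs greedy procedure."""
        rng = random.Random(int(identity * 100))
        seqs = []
        for i in range(25):
            if i % 3 and seqs:
                s = list(rng.choice(seqs).sequence)
                for p in rng.sample(range(len(s)), rng.randint(0, len(s) // 3)):
                    s[p] = rng.choice(AA20)
                if rng.random() < 0.3:  # length variation
                    s = s[: rng.randint(30, len(s))]
                seqs.append(SequenceRecord(f"s{i:02d}", "".join(s)))
            else:
                seqs.append(SequenceRecord(f"s{i:02d}", _rand_seq(rng, rng.randint(40, 90))))
        got = [(c.representative.id, sorted(m.id for m in c.members))
               for c in greedy_cluster(seqs, identity)]
        expected = brute_greedy_cluster(seqs, identity, pairwise_identity)
        assert got == expected

    def test_partition_property(self):
        rng = random.Random(9)
        seqs = [SequenceRecord(f"s{i}", _rand_seq(rng, 50)) for i in range(20)]
        clusters = greedy_cluster(seqs, 0.5)
        seen = [m.id for c in clusters for m in c.members]
        assert sorted(seen) == sorted(s.id for s in seqs)


class TestReduceSeedSet:
    def test_under_cap_returns_input_unchanged(self):
        rng = random.Random(1)
        seqs = [SequenceRecord(f"s{i}", _rand_seq(rng, 60)) for i in range(10)]
        assert reduce_seed_set(seqs, SeedConfig(cap=250)) == seqs

    def test_output_subset_and_capped(self):
        rng = random.Random(2)
        base = [_rand_seq(rng, 80) for _ in range(4)]
        seqs = []
        for i in range(80):
            s = list(base[i % 4])
            for p in rng.sample(range(80), 4):
                s[p] = rng.choice(AA20)
            seqs.append(SequenceRecord(f"s{i:03d}", "".join(s)))
        out = reduce_seed_set(seqs, SeedConfig(cap=10))
        ids = {s.id for s in seqs}
        assert {s.id for s in out} <= ids
        assert len(out) <= 10

    def test_every_planted_cluster_contributes_a_representative(self):
        rng = random.Random(4)
        planted = {f"c{k}": _rand_seq(rng, 90) for k in range(4)}
        seqs, label = [], {}
        for k, (name, base) in enumerate(planted.items()):
            for i in range(40):
                s = list(base)
                for p in rng.sample(range(90), 5):
                    s[p] = rng.choice(AA20)
                rid = f"{name}_{i:03d}"
                seqs.append(SequenceRecord(rid, "".join(s)))
                label[rid] = name
        out = reduce_seed_set(seqs, SeedConfig(cap=8))
        assert len(out) <= 8
        assert {label[s.id] for s in out} == set(planted)

    def test_fragments_dropped_first(self):
        rng = random.Random(6)
        full = [SequenceRecord(f"f{i}", _rand_seq(rng, 100)) for i in range(30)]
        frags = [SequenceRecord(f"x{i}", _rand_seq(rng, 20)) for i in range(5)]
        out = reduce_seed_set(full + frags, SeedConfig(cap=20))
        assert all(not s.id.startswith("x") for s in out)

    def test_idempotence(self):
        rng = random.Random(8)
        base = _rand_seq(rng, 70)
        seqs = []
        for i in range(40):
            s = list(base)
            for p in rng.sample(range(70), rng.randint(0, 30)):
                s[p] = rng.choice(AA20)
            seqs.append(SequenceRecord(f"s{i:02d}", "".join(s)))
        once = reduce_seed_set(seqs, SeedConfig(cap=12))
        twice = reduce_seed_set(once, SeedConfig(cap=12))
        assert [s.id for s in once] == [s.id for s in twice]

    def test_ladder_must_decrease(self):
        with pytest.raises(SeedSelectionError):
            SeedConfig(identity_ladder=(0.5, 0.9))
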