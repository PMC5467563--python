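import random
import zipfile

import pandas as pd
import pytest

from sfcurate.model import AA20, SequenceRecord
from sfcurate.network import (
    NetworkError,
    apply_threshold,
    build_network,
    export_bundle,
    length_histogram,
    make_representative,
    paint_attributes,
    read_xgmml,
    threshold_sweep,
    write_xgmml,
)


def _rand_seq(rng, n):
    return "".join(rng.choice(AA20) for _ in range(n))


@pytest.fixture(scope="module")
def small_net(small_superfamily, params):
    return build_network(small_superfamily.records, params, max_evalue=10.0)


class TestBuildNetwork:
    def test_identical_pair_gets_one_edge(self, params):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 4
        net = build_network([SequenceRecord("a", seq), SequenceRecord("b", seq)],
                            params, max_evalue=10.0)
        assert net.n_edges == 1

    def test_unrelated_sequences_disconnect_at_stringent_cutoff(self, params):
        rng = random.Random(0)
        seqs = [SequenceRecord(f"s{i}", _rand_seq(rng, 80)) for i in range(6)]
        net = build_network(seqs, params, max_evalue=1e-10)
        assert net.n_edges == 0
        assert net.n_nodes == 6

    def test_input_order_invariance(self, small_superfamily, params):
        seqs = small_superfamily.records[:10]
        e1 = {tuple(sorted(e)) for e in
              build_network(seqs, params, 10.0).graph.edges}
        e2 = {tuple(sorted(e)) for e in
              build_network(list(reversed(seqs)), params, 10.0).graph.edges}
        assert e1 == e2

    def test_fewer_than_two_sequences_rejected(self, params):
        with pytest.raises(NetworkError):
            build_network([SequenceRecord("a", "ACD")], params, 10.0)


class TestThresholding:
    def test_permissive_cutoff_is_noop(self, small_net):
        assert apply_threshold(small_net, 1e3).n_edges == small_net.n_edges

    def test_stringent_cutoff_keeps_nodes(self, small_net):
        t = apply_threshold(small_net, 1e-300)
        assert t.n_edges == 0
        assert t.n_nodes == small_net.n_nodes

    def test_sweep_monotonicity(self, small_net):
        rep = threshold_sweep(small_net, [1e-6, 1e-20, 1e-30, 1e-60, 1e-120])
        edges = [e.n_edges for e in rep.entries]
        comps = [e.n_components for e in rep.entries]
        assert edges == sorted(edges, reverse=True)
        assert comps == sorted(comps)

    def test_unsorted_cutoffs_rejected(self, small_net):
        with pytest.raises(NetworkError):
            threshold_sweep(small_net, [1e-30, 1e-6])


class TestRepresentativeNetwork:
    def test_identity_one_gives_one_node_per_distinct_sequence(
            self, small_superfamily, params):
        seqs = small_superfamily.records[:8]
        net = make_representative(seqs, 1.0, params=params, max_evalue=10.0)
        assert net.n_nodes == len(seqs)
        assert all(d["size"] == 1 for _, d in net.graph.nodes(data=True))

    def test_members_partition_the_input(self, small_superfamily, params):
        seqs = small_superfamily.records[:20]
        net = make_representative(seqs, 0.7, params=params, max_evalue=10.0)
        members = [m for _, d in net.graph.nodes(data=True) for m in d["members"]]
        assert sorted(members) == sorted(s.id for s in seqs)

    def test_attribute_summary_lists_and_dominant_value(self, params):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 4
        seqs = [SequenceRecord(f"s{i}", seq) for i in range(5)]
        attrs = pd.DataFrame({
            "id": [s.id for s in seqs],
            "ec": ["1.1.1.1", "1.1.1.1", "1.1.1.1", "1.1.1.2", "1.1.1.2"],
        })
        net = make_representative(seqs, 0.9, attrs, params, max_evalue=10.0)
        assert net.n_nodes == 1
        node = list(net.graph.nodes(data=True))[0][1]
        assert node["ec"] == "1.1.1.1"
        assert node["ec_list"] == ["1.1.1.1", "1.1.1.2"]

    def test_empty_attribute_omitted(self, params):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 4
        seqs = [SequenceRecord(f"s{i}", seq) for i in range(3)]
        attrs = pd.DataFrame({"id": [s.id for s in seqs], "ec": ["", "", ""]})
        net = make_representative(seqs, 0.9, attrs, params, max_evalue=10.0)
        node = list(net.graph.nodes(data=True))[0][1]
        assert "ec" not in node


class TestPaintAttributes:
    def test_empty_table_leaves_network_unchanged(self, small_net):
        painted, unmatched = paint_attributes(small_net, pd.DataFrame())
        assert unmatched == []
        assert dict(painted.graph.nodes(data=True)) == \
            dict(small_net.graph.nodes(data=True))

    def test_attributes_land_on_matching_nodes(self, small_net):
        ids = sorted(small_net.graph.nodes)[:3]
        table = pd.DataFrame({"id": ids, "ec": ["1.1.1.1"] * 3})
        painted, unmatched = paint_attributes(small_net, table)
        assert unmatched == []
        for nid in ids:
            assert painted.graph.nodes[nid]["ec"] == "1.1.1.1"

    def test_unknown_id_reported_not_fatal(self, small_net):
        table = pd.DataFrame({"id": ["no_such_node"], "ec": ["1.2.3.4"]})
        painted, unmatched = paint_attributes(small_net, table)
        assert unmatched == ["no_such_node"]
        assert painted.n_nodes == small_net.n_nodes

    def test_duplicate_keys_rejected(self, small_net):
        nid = sorted(small_net.graph.nodes)[0]
        table = pd.DataFrame({"id": [nid, nid], "ec": ["a", "b"]})
        with pytest.raises(NetworkError, match="duplicate"):
            paint_attributes(small_net, table)


class TestExport:
    def test_xgmml_round_trip_is_lossless(self, small_net, tmp_path):
        ids = sorted(small_net.graph.nodes)[:2]
        painted, _ = paint_attributes(
            small_net, pd.DataFrame({"id": ids, "ec": ["1.1.1.1", "2.2.2.2"]}))
        path = tmp_path / "net.xgmml"
        write_xgmml(painted, path)
        back = read_xgmml(str(path))
        assert set(back.graph.nodes) == set(painted.graph.nodes)
        assert {tuple(sorted(e)) for e in back.graph.edges} == \
            {tuple(sorted(e)) for e in painted.graph.edges}
        for nid, d in painted.graph.nodes(data=True):
            assert back.graph.nodes[nid] == d
        for u, v, d in painted.graph.edges(data=True):
            assert back.graph.edges[u, v] == d

    def test_zero_edge_network_exports_valid_xgmml(self, params, tmp_path):
        rng = random.Random(1)
        seqs = [SequenceRecord(f"s{i}", _rand_seq(rng, 60)) for i in range(4)]
        net = build_network(seqs, params, max_evalue=1e-20)
        assert net.n_edges == 0
        path = tmp_path / "empty_edges.xgmml"
        write_xgmml(net, path)
        assert read_xgmml(str(path)).n_nodes == 4

    def test_bundle_contents_and_histogram_conservation(self, small_net, tmp_path):
        out = export_bundle(small_net, tmp_path / "bundle.zip")
        names = set(zipfile.ZipFile(out).namelist())
        assert {"network.xgmml", "README.txt", "lengths.tsv", "lengths.png"} <= names
        hist = length_histogram(small_net)
        assert hist["count"].sum() == small_net.n_nodes
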