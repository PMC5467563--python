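"""Sequence similarity networks (SSNs) for superfamily curation.

Nodes are sequences (or representative clusters); an undirected edge
records the pairwise similarity of its endpoints (E-value, bit score,
percent identity).  Because the two directional E-values of a pair differ
(the query length enters the E-value), the *worse* (larger) of the two is
retained — conservative edges.  Curators sweep the E-value threshold from
permissive to stringent and watch edges fall away until the connected
components track the functional subdivision they are after; thresholding
never removes nodes, so singletons keep showing the coverage of sequence
space.

Networks export to Cytoscape-compatible XGMML, bundled in a zip with a
README and a sequence-length histogram.
"""

from __future__ import annotations

import io as _io
import zipfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import networkx as nx
import pandas as pd
from lxml import etree

from .model import SequenceRecord, check_unique_ids
from .scoring import ScoringParams, align_local, evalue, percent_identity_from_hit
from .seeds import greedy_cluster

XGMML_NS = "http://www.cs.rpi.edu/XGMML"


class NetworkError(ValueError):
    pass


@dataclass
class Network:
    """An undirected similarity graph with typed node/edge attributes."""

    graph: nx.Graph
    kind: str = "full"  # full | representative

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def components(self) -> List[frozenset]:
        return sorted(
            (frozenset(c) for c in nx.connected_components(self.graph)),
            key=lambda c: (-len(c), min(c)),
        )

    def copy(self) -> "Network":
        return Network(graph=self.graph.copy(), kind=self.kind)


def build_network(seqs: List[SequenceRecord],
                  params: Optional[ScoringParams] = None,
                  max_evalue: float = 10.0) -> Network:
    """All-vs-all local alignment network.

    For each unordered pair one alignment is computed; the retained E-value
    is the larger (less significant) of the two directional E-values, and an
    edge exists iff it passes ``max_evalue``.  ``db_size`` for the E-values
    is the total residue count of the input set.
    """
    if len(seqs) < 2:
        raise NetworkError("need at least 2 sequences")
    check_unique_ids(seqs)
    params = params or ScoringParams()
    n = sum(len(s.sequence) for s in seqs)
    g = nx.Graph()
    for s in seqs:
        g.add_node(s.id, length=len(s.sequence))
    for i, a in enumerate(seqs):
        for b in seqs[i + 1:]:
            hit = align_local(a, b, params)
            worse_m = max(len(a.sequence), len(b.sequence))
            ev = evalue(hit.bit_score, worse_m, n)
            if ev <= max_evalue:
                g.add_edge(
                    a.id, b.id,
                    evalue=ev,
                    bit_score=hit.bit_score,
                    pct_identity=percent_identity_from_hit(hit, a, b),
                )
    return Network(graph=g, kind="full")


def apply_threshold(net: Network, evalue_cutoff: float) -> Network:
    """Keep exactly the edges with evalue <= cutoff; nodes always survive."""
    if evalue_cutoff <= 0:
        raise NetworkError("cutoff must be positive")
    out = net.copy()
    drop = [(u, v) for u, v, d in out.graph.edges(data=True)
            if d["evalue"] > evalue_cutoff]
    out.graph.remove_edges_from(drop)
    return out


@dataclass
class SweepEntry:
    cutoff: float
    n_edges: int
    n_components: int
    components: List[frozenset]


@dataclass
class SweepReport:
    entries: List[SweepEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"cutoff": e.cutoff, "n_edges": e.n_edges,
              "n_components": e.n_components} for e in self.entries]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def threshold_sweep(net: Network, cutoffs: List[float]) -> SweepReport:
    """Apply successively more stringent E-value cutoffs and summarise.

    ``cutoffs`` must run from permissive to stringent (strictly decreasing
    E-values).  Each entry reports edge count, component count and
    component membership; edge counts are non-increasing and component
    counts non-decreasing along the sweep.
    """
    if any(b >= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise NetworkError("cutoffs must run from permissive to stringent "
                           "(strictly decreasing)")
    report = SweepReport()
    for c in cutoffs:
        t = apply_threshold(net, c)
        comps = t.components()
        report.entries.append(SweepEntry(
            cutoff=c, n_edges=t.n_edges, n_components=len(comps),
            components=comps))
    return report


@dataclass
class RepNode:
    id: str
    members: List[str]
    summary_attributes: Dict[str, Tuple[List[str], str]] = field(
        default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


def _summarise(values: List[str]) -> Optional[Tuple[List[str], str]]:
    values = [v for v in values if v not in ("", None)]
    if not values:
        return None
    counts = Counter(values)
    top = max(counts.values())
    dominant = min(v for v, c in counts.items() if c == top)  # ties: lexicographic
    return sorted(set(values)), dominant


def make_representative(seqs: List[SequenceRecord], identity: float,
                        attributes: Optional[pd.DataFrame] = None,
                        params: Optional[ScoringParams] = None,
                        max_evalue: float = 10.0,
                        full_net: Optional[Network] = None) -> Network:
    """Collapse an SSN to one node per identity cluster.

    Clusters come from greedy clustering at ``identity`` (identity 1.0
    yields the one-sequence-per-node network for distinct sequences).  Rep
    nodes are linked iff *any* member pair passes the edge rule, with the
    best (smallest) member-pair E-value as the edge weight.  Per-cluster
    attribute summaries keep both the value list and the dominant value.
    """
    if not (0.0 < identity <= 1.0):
        raise NetworkError("identity must be in (0, 1]")
    if full_net is None:
        full_net = build_network(seqs, params, max_evalue)
    clusters = greedy_cluster(seqs, identity, params)
    attr_map: Dict[str, Dict[str, str]] = {}
    if attributes is not None:
        key = attributes.columns[0]
        if attributes[key].duplicated().any():
            raise NetworkError("duplicate key rows in attribute table")
        attr_map = attributes.set_index(key).astype(object).to_dict("index")

    g = nx.Graph()
    member_cluster: Dict[str, str] = {}
    for cl in clusters:
        rid = cl.representative.id
        members = sorted(m.id for m in cl.members)
        node = RepNode(id=rid, members=members)
        for m in members:
            member_cluster[m] = rid
        if attr_map:
            names = sorted({k for row in attr_map.values() for k in row})
            for name in names:
                summary = _summarise(
                    [str(attr_map.get(m, {}).get(name, ""))
                     if attr_map.get(m, {}).get(name) is not None else ""
                     for m in members])
                if summary is not None:
                    node.summary_attributes[name] = summary
        attrs = {"size": node.size, "members": members}
        for name, (vals, dom) in node.summary_attributes.items():
            attrs[name] = dom
            attrs[name + "_list"] = vals
        g.add_node(rid, **attrs)
    for u, v, d in full_net.graph.edges(data=True):
        cu, cv = member_cluster[u], member_cluster[v]
        if cu == cv:
            continue
        if not g.has_edge(cu, cv) or d["evalue"] < g[cu][cv]["evalue"]:
            g.add_edge(cu, cv, **d)
    return Network(graph=g, kind="representative")


def paint_attributes(net: Network, table: pd.DataFrame
                     ) -> Tuple[Network, List[str]]:
    """Merge a node-keyed attribute table onto the network.

    The first column of ``table`` is the node id key; duplicate keys are an
    error.  Returns the painted network and the list of table keys that
    matched no node (nodes missing from the table keep empty attributes).
    """
    out = net.copy()
    if table.empty:
        return out, []
    key = table.columns[0]
    if table[key].duplicated().any():
        dups = table.loc[table[key].duplicated(), key].tolist()
        raise NetworkError(f"duplicate key rows in attribute table: {dups[:5]}")
    unmatched = []
    for _, row in table.iterrows():
        nid = row[key]
        if nid not in out.graph:
            unmatched.append(nid)
            continue
        for col in table.columns[1:]:
            val = row[col]
            if pd.notna(val) and val != "":
                out.graph.nodes[nid][col] = val
    return out, unmatched


# ---------------------------------------------------------------------------
# XGMML


def _att_element(parent, name, value):
    att = etree.SubElement(parent, "att")
    att.set("name", str(name))
    if isinstance(value, bool):
        att.set("type", "string")
        att.set("value", str(value))
    elif isinstance(value, int):
        att.set("type", "integer")
        att.set("value", str(value))
    elif isinstance(value, float):
        att.set("type", "real")
        att.set("value", repr(value))
    elif isinstance(value, (list, tuple)):
        att.set("type", "list")
        for v in value:
            sub = etree.SubElement(att, "att")
            sub.set("name", str(name))
            sub.set("type", "string")
            sub.set("value", str(v))
    else:
        att.set("type", "string")
        att.set("value", str(value))


def write_xgmml(net: Network, handle, label: str = "ssn") -> None:
    """Write the network as Cytoscape-compatible XGMML."""
    graph = etree.Element("graph", nsmap={None: XGMML_NS})
    graph.set("label", label)
    graph.set("directed", "0")
    ids = sorted(net.graph.nodes)
    for nid in ids:
        node = etree.SubElement(graph, "node")
        node.set("id", str(nid))
        node.set("label", str(nid))
        for k in sorted(net.graph.nodes[nid]):
            _att_element(node, k, net.graph.nodes[nid][k])
    for u, v in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges)):
        edge = etree.SubElement(graph, "edge")
        edge.set("source", str(u))
        edge.set("target", str(v))
        edge.set("label", f"{u},{v}")
        for k in sorted(net.graph.edges[u, v]):
            _att_element(edge, k, net.graph.edges[u, v][k])
    tree = etree.ElementTree(graph)
    close = False
    if isinstance(handle, (str, Path)):
        handle = open(handle, "wb")
        close = True
    try:
        tree.write(handle, xml_declaration=True, encoding="UTF-8",
                   pretty_print=True)
    finally:
        if close:
            handle.close()


def _att_value(att) -> object:
    t = att.get("type", "string")
    if t == "integer":
        return int(att.get("value"))
    if t == "real":
        return float(att.get("value"))
    if t == "list":
        return [sub.get("value") for sub in att]
    return att.get("value")


def read_xgmml(source, kind: str = "full") -> Network:
    tree = etree.parse(source)
    root = tree.getroot()
    ns = {"x": XGMML_NS}
    g = nx.Graph()
    for node in root.findall("x:node", ns):
        attrs = {a.get("name"): _att_value(a) for a in node.findall("x:att", ns)}
        g.add_node(node.get("id"), **attrs)
    for edge in root.findall("x:edge", ns):
        attrs = {a.get("name"): _att_value(a) for a in edge.findall("x:att", ns)}
        g.add_edge(edge.get("source"), edge.get("target"), **attrs)
    return Network(graph=g, kind=kind)


# ---------------------------------------------------------------------------
# Dissemination bundle


def length_histogram(net: Network, bin_width: int = 25) -> pd.DataFrame:
    """Node-length histogram; bin counts sum to the node count."""
    lengths = [d.get("length", 0) for _, d in net.graph.nodes(data=True)]
    if not lengths:
        raise NetworkError("network has no nodes")
    lo = (min(lengths) // bin_width) * bin_width
    hi = (max(lengths) // bin_width + 1) * bin_width
    bins = list(range(lo, hi + bin_width, bin_width))
    counts = Counter((l - lo) // bin_width for l in lengths)
    return pd.DataFrame({
        "bin_start": bins[:-1],
        "bin_end": [b - 1 for b in bins[1:]],
        "count": [counts.get(i, 0) for i in range(len(bins) - 1)],
    })


def export_bundle(net: Network, out_path, label: str = "ssn",
                  notes: str = "") -> Path:
    """Package the network for dissemination.

    The zip contains ``network.xgmml``, an explanatory ``README.txt`` with
    the generation parameters and counts, the node-length histogram as both
    a TSV and a PNG.
    """
    if net.n_nodes == 0:
        raise NetworkError("refusing to export an empty network")
    out_path = Path(out_path)
    hist = length_histogram(net)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(hist["bin_start"], hist["count"],
           width=(hist["bin_end"] - hist["bin_start"] + 1).iloc[0],
           align="edge", edgecolor="black")
    ax.set_xlabel("sequence length (residues)")
    ax.set_ylabel("count")
    ax.set_title(f"{label}: node length distribution")
    png = _io.BytesIO()
    fig.savefig(png, format="png", dpi=100)
    plt.close(fig)

    xgmml = _io.BytesIO()
    write_xgmml(net, xgmml, label=label)

    readme = "\n".join([
        f"Sequence similarity network bundle: {label}",
        "",
        f"kind: {net.kind}",
        f"nodes: {net.n_nodes}",
        f"edges: {net.n_edges}",
        f"connected components: {len(net.components())}",
        "",
        "Files:",
        "  network.xgmml  - the network (Cytoscape-compatible XGMML);"
        " edges carry evalue, bit_score and pct_identity attributes",
        "  lengths.tsv    - node length histogram (bin_start, bin_end, count)",
        "  lengths.png    - the same histogram, rendered",
        "",
        notes,
    ])

    with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("network.xgmml", xgmml.getvalue())
        zf.writestr("README.txt", readme)
        zf.writestr("lengths.tsv", hist.to_csv(sep="\t", index=False))
        zf.writestr("lengths.png", png.getvalue())
    return out_path
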