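"""Per-group co-abundance networks and their topological comparison.

Nodes are the most abundant taxa within a sample group; edges are
Spearman correlations passing both a magnitude gate and a BH-FDR gate.
Negative correlations are kept as signed edges; communities and
centralities are computed on absolute weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust, wilcoxon_rank_sum
from .io import FeatureTable, ValidationError

logger = logging.getLogger(__name__)

PROPERTIES = ("degree", "closeness", "betweenness", "eigenvector")


@dataclass
class CoabundanceNetwork:
    group: str
    graph: nx.Graph
    node_abundance: pd.Series
    communities: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": u,
                "target": v,
                "rho": d["rho"],
                "q": d["q"],
                "sign": d["sign"],
            }
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "q", "sign"])


def build_coabundance(
    table: FeatureTable,
    group_samples,
    group_label: str = "",
    top_n: int = 30,
    min_abs_rho: float = 0.3,
    alpha: float = 0.05,
) -> CoabundanceNetwork:
    """Spearman co-abundance network over the group's most abundant taxa.

    Nodes are the ``top_n`` features by mean relative abundance within
    the group (ties broken by feature name); an edge appears when
    |rho| >= ``min_abs_rho`` and the BH q-value over all candidate pairs
    is < ``alpha``. Correlations use average ranks for ties.
    """
    samples = list(group_samples)
    if len(samples) < 5:
        raise ValidationError("co-abundance network needs >=5 samples in the group")
    sub = table.data.loc[:, samples]
    if table.units == "counts":
        sub = sub / sub.sum(axis=0)
    means = sub.mean(axis=1)
    order = means.to_frame("mean").assign(name=means.index)
    order = order.sort_values(["mean", "name"], ascending=[False, True])
    top = order.index[: min(top_n, len(order))].tolist()
    if len(top) < 2:
        raise ValidationError("need at least 2 nodes to build a network")
    x = sub.loc[top].to_numpy(dtype=float)
    rho, p = stats.spearmanr(x, axis=1)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    iu, ju = np.triu_indices(len(top), k=1)
    q = bh_adjust(np.nan_to_num(p[iu, ju], nan=1.0))

    g = nx.Graph()
    for node in top:
        g.add_node(node)
    for (i, j, qv) in zip(iu, ju, q):
        r = rho[i, j]
        if np.isnan(r):
            r = 0.0
        if abs(r) >= min_abs_rho and qv < alpha:
            g.add_edge(
                top[i],
                top[j],
                rho=float(r),
                q=float(qv),
                sign=int(np.sign(r)),
                abs_weight=float(abs(r)),
            )
    net = CoabundanceNetwork(
        group=group_label, graph=g, node_abundance=means.loc[top]
    )
    net.communities = detect_communities(net)
    return net


def detect_communities(net: CoabundanceNetwork) -> dict[str, int]:
    """Greedy modularity communities on absolute edge weights.

    Deterministic given the node ordering; an edgeless graph yields one
    singleton community per node (with a warning).
    """
    g = net.graph
    if g.number_of_edges() == 0:
        logger.warning("edgeless network %r: all singleton communities", net.group)
        return {node: i for i, node in enumerate(g.nodes)}
    comms = nx.community.greedy_modularity_communities(g, weight="abs_weight")
    labels: dict[str, int] = {}
    for cid, members in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
        for node in members:
            labels[node] = cid
    return labels


def node_properties(net: CoabundanceNetwork) -> pd.DataFrame:
    """Degree, closeness, betweenness and eigenvector centrality per node.

    Closeness is (|component|-1)/sum of shortest-path lengths within the
    node's component; betweenness is normalized; eigenvector centrality is
    the nonnegative L2-normalized principal eigenvector of the
    absolute-weight adjacency matrix.
    """
    g = net.graph
    nodes = list(g.nodes)
    degree = dict(g.degree())
    closeness = nx.closeness_centrality(g, wf_improved=False)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    if g.number_of_edges() > 0:
        adj = nx.to_numpy_array(g, nodelist=nodes, weight="abs_weight")
        eigvals, eigvecs = np.linalg.eigh(adj)
        vec = eigvecs[:, np.argmax(eigvals)]
        if vec.sum() < 0:
            vec = -vec
        vec = np.abs(vec)
        norm = np.linalg.norm(vec)
        eigen = vec / norm if norm > 0 else vec
    else:
        eigen = np.zeros(len(nodes))
    frame = pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "eigenvector": eigen,
            "community": [net.communities.get(n, -1) for n in nodes],
            "mean_abundance": net.node_abundance.loc[nodes].to_numpy(),
        },
        index=pd.Index(nodes, name="node"),
    )
    return frame


def compare_properties(
    net_a: CoabundanceNetwork, net_b: CoabundanceNetwork
) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum p per topological property.

    A property constant across both networks gets p = 1 (no evidence of
    a difference is extractable from ranks).
    """
    props_a = node_properties(net_a)
    props_b = node_properties(net_b)
    out: dict[str, float] = {}
    for prop in PROPERTIES:
        a = props_a[prop].to_numpy(dtype=float)
        b = props_b[prop].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            out[prop] = 1.0
            continue
        _, p = wilcoxon_rank_sum(a, b)
        out[prop] = float(p)
    return out
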