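"""Thresholded association networks and tripartite triangle motifs.

Nodes carry one of three modalities: taxa (``T``), functional modules
(``M``) and psychopathology scores (``PP``).  An edge is admitted when the
association's log10 Bayes factor reaches the evidence threshold (0.5,
inclusive, i.e. at least substantial evidence).  A *triangular motif* is a
three-clique with exactly one node of each modality — a taxon and a module
associated with each other and both with the same symptom score — the
topological signature of a possibly metabolism-mediated gut-brain link.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "AssociationNetwork",
    "TriangleMotif",
    "TripartiteMotifAnalysis",
    "build_network",
    "enumerate_tripartite_triangles",
    "motif_table",
    "summarize_motifs",
    "write_network",
]

EDGE_ATTRS = ("log10_bf", "rho", "n_obs", "evidence")


@dataclass
class AssociationNetwork:
    """Undirected graph of thresholded associations.

    ``graph`` is a :class:`networkx.Graph` whose nodes carry a ``modality``
    attribute in {T, M, PP} and whose edges carry log10_bf, rho, n_obs and
    evidence.  Every edge satisfies ``log10_bf >= threshold``.
    """

    graph: nx.Graph
    threshold: float

    def __post_init__(self) -> None:
        for a, b, attrs in self.graph.edges(data=True):
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if attrs["log10_bf"] < self.threshold:
                raise ValueError(
                    f"edge ({a!r}, {b!r}) below threshold {self.threshold}"
                )

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def nodes_of_modality(self, modality: str) -> list:
        return [n for n, d in self.graph.nodes(data=True) if d.get("modality") == modality]


@dataclass(frozen=True)
class TriangleMotif:
    """One taxon-module-symptom triangle with its three edge records."""

    taxon_node: str
    module_node: str
    pp_node: str
    edge_tm: dict
    edge_tp: dict
    edge_mp: dict

    @property
    def direction_pattern(self) -> tuple[int, int, int]:
        """Signs of the three Spearman correlations (T-M, T-PP, M-PP)."""
        return tuple(int(np.sign(e["rho"])) for e in (self.edge_tm, self.edge_tp, self.edge_mp))

    @property
    def edges(self) -> tuple[dict, dict, dict]:
        return (self.edge_tm, self.edge_tp, self.edge_mp)


def build_network(
    edges: pd.DataFrame,
    threshold: float = 0.5,
    nodes: list[tuple[str, str]] | None = None,
) -> AssociationNetwork:
    """Binarise an edge list at the log10-BF threshold.

    Parameters
    ----------
    edges
        Edge list as produced by
        :func:`microtriad.bayes.joint_edge_matrix` (deduplicated on
        unordered pairs).
    threshold
        Inclusive cut on log10 BF10 (default 0.5: H1 at least ~3 times more
        likely than H0).
    nodes
        Optional full list of ``(node, modality)``; nodes without a
        surviving edge are retained as isolated nodes.  When omitted, the
        node set is taken from the edge list (all nodes appearing there,
        whether or not their edges survive).
    """
    seen = set()
    for a, b in zip(edges["node_a"], edges["node_b"]):
        key = frozenset((a, b))
        if key in seen:
            raise ValueError(f"duplicate unordered pair ({a!r}, {b!r}) in edge list")
        seen.add(key)

    graph = nx.Graph()
    if nodes is not None:
        for node, modality in nodes:
            graph.add_node(node, modality=modality)
    else:
        for _, row in edges.iterrows():
            graph.add_node(row["node_a"], modality=row["modality_a"])
            graph.add_node(row["node_b"], modality=row["modality_b"])
    surviving = edges[edges["log10_bf"] >= threshold]
    for _, row in surviving.iterrows():
        graph.add_edge(
            row["node_a"], row["node_b"],
            **{k: row[k] for k in EDGE_ATTRS if k in row},
        )
    return AssociationNetwork(graph, threshold)


def enumerate_tripartite_triangles(
    net: AssociationNetwork, pp_node: str
) -> list[TriangleMotif]:
    """All (taxon, module, pp_node) triangles, sorted by taxon then module.

    A triangle requires all three pairwise edges (taxon-module,
    taxon-symptom, module-symptom) to be present in the thresholded
    network.
    """
    g = net.graph
    if pp_node not in g:
        raise KeyError(f"psychopathology node {pp_node!r} not in network")
    if g.nodes[pp_node].get("modality") != "PP":
        raise ValueError(f"node {pp_node!r} does not have modality 'PP'")
    taxa = sorted(
        n for n in g.neighbors(pp_node) if g.nodes[n].get("modality") == "T"
    )
    modules = sorted(
        n for n in g.neighbors(pp_node) if g.nodes[n].get("modality") == "M"
    )
    motifs = []
    for t in taxa:
        for m in modules:
            if g.has_edge(t, m):
                motifs.append(
                    TriangleMotif(
                        taxon_node=t,
                        module_node=m,
                        pp_node=pp_node,
                        edge_tm=dict(g.edges[t, m]),
                        edge_tp=dict(g.edges[t, pp_node]),
                        edge_mp=dict(g.edges[m, pp_node]),
                    )
                )
    return motifs


def motif_table(motifs: list[TriangleMotif]) -> pd.DataFrame:
    """Report rows: three association rows per motif (T-M, T-PP, M-PP)."""
    rows = []
    for k, motif in enumerate(motifs):
        for (a, b), edge in zip(
            [
                (motif.taxon_node, motif.module_node),
                (motif.taxon_node, motif.pp_node),
                (motif.module_node, motif.pp_node),
            ],
            motif.edges,
        ):
            rows.append(
                {
                    "motif": k,
                    "node_a": a,
                    "node_b": b,
                    "log10_bf": edge["log10_bf"],
                    "rho": edge["rho"],
                }
            )
    return pd.DataFrame(rows, columns=["motif", "node_a", "node_b", "log10_bf", "rho"])


def summarize_motifs(motifs: list[TriangleMotif]) -> dict:
    """Counts of motifs and of the distinct taxa and modules involved."""
    return {
        "n_motifs": len(motifs),
        "n_taxa": len({m.taxon_node for m in motifs}),
        "n_modules": len({m.module_node for m in motifs}),
    }


class TripartiteMotifAnalysis:
    """Estimator-style wrapper: blocks in, thresholded network and motifs out.

    Follows the scikit-learn protocol (``fit`` / ``get_params`` /
    ``set_params``, fitted attributes with a trailing underscore) so the
    network stage composes with sklearn model-selection tooling.

    Parameters
    ----------
    threshold
        Inclusive log10 BF10 cut for an edge (default 0.5).
    rscale
        JZS prior width (default 0.354).
    method
        Bayes factor form, ``"regression"`` or ``"stretched-beta"``.

    Attributes
    ----------
    edges_ : DataFrame
        All pairwise associations (upper triangle of the joint matrix).
    network_ : AssociationNetwork
        The thresholded graph, isolated nodes retained.
    motifs_ : dict
        Triangle motifs per psychopathology node.
    summaries_ : dict
        Motif / distinct-taxon / distinct-module counts per PP node.
    """

    def __init__(self, threshold: float = 0.5, rscale: float = 0.354,
                 method: str = "regression"):
        self.threshold = threshold
        self.rscale = rscale
        self.method = method

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold, "rscale": self.rscale,
                "method": self.method}

    def set_params(self, **params) -> "TripartiteMotifAnalysis":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "TripartiteMotifAnalysis":
        """Fit on ``X``: a list of ``(samples x features frame, modality)``.

        Modalities must come from {"T", "M", "PP"}; triangles are
        enumerated for every PP column.
        """
        from .bayes import joint_edge_matrix

        self.edges_ = joint_edge_matrix(X, rscale=self.rscale, method=self.method)
        nodes = [
            (str(c), modality) for frame, modality in X for c in frame.columns
        ]
        self.network_ = build_network(self.edges_, self.threshold, nodes=nodes)
        self.motifs_ = {
            pp: enumerate_tripartite_triangles(self.network_, pp)
            for pp in self.network_.nodes_of_modality("PP")
        }
        self.summaries_ = {pp: summarize_motifs(m) for pp, m in self.motifs_.items()}
        return self


def write_network(net: AssociationNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Export the network as GraphML or as an edge-list TSV."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net.graph, path)
    elif fmt == "tsv":
        rows = [
            {"node_a": a, "node_b": b, **attrs}
            for a, b, attrs in net.graph.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        raise ValueError(f"unknown network format {fmt!r}")
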