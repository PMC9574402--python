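"""Filtered interaction network and replicate-level PCA.

Network nodes are the proteins that pass the triple filter — significantly
enriched, detected in all bait replicates, and mean SI_GI strictly greater
than a threshold (0.0005 by default). Edges come from a local
protein-protein interaction snapshot (no live database queries) restricted
to node pairs; each node carries its mean SI_GI (the presentation layer
scales node size from it) and, when available, its top GO Biological
Process term from a local annotation snapshot.

The PCA operates on replicate runs x selected protein features: each feature
column is z-transformed (centered, scaled by the n-1 sample standard
deviation; zero-variance features dropped with a warning; undetected entries
are 0 before the transform), and components come from the singular value
decomposition of the standardized matrix, i.e. the eigen-structure of the
feature correlation matrix. Component signs are fixed by making the
largest-magnitude loading of each component positive, so output is
deterministic across linear-algebra backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ApmsError
from .quantify import QuantMatrix

#: Default node threshold on mean SI_GI (strict inequality).
DEFAULT_NODE_THRESHOLD = 5e-4


def filter_network_nodes(
    records: pd.DataFrame, node_threshold: float = DEFAULT_NODE_THRESHOLD
) -> pd.DataFrame:
    """Triple filter: significant, detected in all replicates, mean SI_GI
    strictly above the threshold (a record at exactly the threshold is out)."""
    if node_threshold < 0:
        raise ApmsError(f"node_threshold must be >= 0, got {node_threshold}")
    keep = (
        records["significant"]
        & records["detected_in_all"]
        & (records["mean_si_gi"] > node_threshold)
    )
    return records[keep].reset_index(drop=True)


def build_network(
    nodes: pd.DataFrame,
    interactions: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
) -> nx.Graph:
    """Undirected network over filtered nodes.

    ``nodes`` is a filtered enrichment frame (protein, mean_si_gi, ...);
    ``interactions`` has columns protein_a, protein_b, score and is
    restricted to pairs whose endpoints are both nodes; self-edges are
    dropped and duplicate/reversed rows collapse to one edge (keeping the
    highest score). ``annotations`` (protein, go_term[, score]) attaches the
    top term per node.
    """
    graph = nx.Graph()
    go_terms: dict[str, str] = {}
    if annotations is not None and len(annotations):
        if "score" in annotations.columns:
            ann = annotations.sort_values("score", ascending=False, kind="stable")
        else:
            ann = annotations  # assumed best-first
        for rec in ann.itertuples(index=False):
            go_terms.setdefault(rec.protein, rec.go_term)
    for rec in nodes.itertuples(index=False):
        graph.add_node(
            rec.protein,
            mean_si_gi=float(rec.mean_si_gi),
            go_term=go_terms.get(rec.protein, ""),
        )
    if interactions is not None:
        for rec in interactions.itertuples(index=False):
            a, b = rec.protein_a, rec.protein_b
            if a == b or a not in graph or b not in graph:
                continue
            score = float(rec.score)
            if graph.has_edge(a, b):
                graph[a][b]["score"] = max(graph[a][b]["score"], score)
            else:
                graph.add_edge(a, b, score=score)
    return graph


def write_network(graph: nx.Graph, nodes_path, edges_path) -> None:
    node_rows = [
        {"protein": n, "mean_si_gi": d["mean_si_gi"], "go_term": d["go_term"]}
        for n, d in sorted(graph.nodes(data=True))
    ]
    pd.DataFrame(node_rows, columns=["protein", "mean_si_gi", "go_term"]).to_csv(
        nodes_path, sep="\t", index=False
    )
    edge_rows = [
        {"protein_a": min(a, b), "protein_b": max(a, b), "score": d["score"]}
        for a, b, d in graph.edges(data=True)
    ]
    edge_rows.sort(key=lambda r: (r["protein_a"], r["protein_b"]))
    pd.DataFrame(edge_rows, columns=["protein_a", "protein_b", "score"]).to_csv(
        edges_path, sep="\t", index=False
    )


@dataclass
class PcaResult:
    """Principal components of replicate runs in standardized feature space."""

    scores: pd.DataFrame  # runs x components (PC1, PC2, ...)
    loadings: pd.DataFrame  # features x components
    variance_fractions: np.ndarray  # non-increasing, sums to 1
    features: list[str]
    dropped_features: list[str] = field(default_factory=list)


def pca_replicates(
    matrix: QuantMatrix,
    features: list[str] | None = None,
    run_ids: list[str] | None = None,
) -> PcaResult:
    """PCA of bait replicates over selected protein features.

    ``features`` is typically the union of the significantly-enriched,
    all-replicate proteins of the purifications being compared; by default
    all proteins of the matrix are used. ``run_ids`` defaults to all bait
    runs. Requires >= 3 runs and >= 2 (non-constant) features.
    """
    if run_ids is None:
        run_ids = matrix.run_ids_where(condition="bait")
    if len(run_ids) < 3:
        raise ApmsError(f"PCA needs >= 3 runs, got {len(run_ids)}")
    if features is None:
        features = matrix.proteins
    if len(features) < 2:
        raise ApmsError(f"PCA needs >= 2 features, got {len(features)}")
    X = (
        matrix.values.reindex(index=features, columns=run_ids)
        .fillna(0.0)  # proteins never seen in these runs enter as 0
        .to_numpy(dtype=float)
        .T
    )  # runs x features
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [f for f, k in zip(features, keep) if not k]
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance feature(s) from PCA", stacklevel=2)
    kept = [f for f, k in zip(features, keep) if k]
    if not kept or len(kept) < 2:
        raise ApmsError("fewer than 2 features with non-zero variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    var = S**2
    fractions = var / var.sum()
    comp_names = [f"PC{k + 1}" for k in range(len(S))]
    scores = pd.DataFrame(U * S, index=pd.Index(run_ids, name="run_id"), columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=pd.Index(kept, name="protein"), columns=comp_names)
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_fractions=fractions,
        features=kept,
        dropped_features=dropped,
    )


def write_pca(result: PcaResult, scores_path, variance_path) -> None:
    result.scores.to_csv(scores_path, sep="\t")
    pd.DataFrame(
        {
            "component": [f"PC{k + 1}" for k in range(len(result.variance_fractions))],
            "variance_fraction": result.variance_fractions,
        }
    ).to_csv(variance_path, sep="\t", index=False)
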