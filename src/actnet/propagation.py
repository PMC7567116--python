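"""Node scoring, insulated heat diffusion, and consensus network extraction.

Each protein i gets a nonnegative score

    S_i = -sum_j log10 p_{j,TvsC}^{(i)},  j in {0, 1, 2},

when its longitudinal fit was significant (dynamic), and 0 otherwise; layer
scores are integrated by summation. Scores are spread over a protein
interaction network by an insulated-heat-diffusion random walk with restart:
with column-stochastic walk matrix W and restart probability beta,

    F = beta * (I - (1 - beta) W)^(-1),        E = F @ diag(scores),

so column j of the exchanged-heat matrix E redistributes node j's score over
the network (columns of F sum to one: heat is conserved). Thresholding the
off-diagonal entries of E at delta and taking strongly connected components
of the surviving directed graph yields a drug subnetwork; of four candidate
thresholds the minimal one is used. Subnetworks of the individual drugs are
merged into a consensus network keeping nodes and interactions that appear in
at least two of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .longitudinal import DynamicFit

logger = logging.getLogger(__name__)

DENSE_NODE_LIMIT = 2_000
DEFAULT_RESTART_PROB = 0.4
DEFAULT_DELTA_QUANTILES = (0.95, 0.99, 0.995, 0.999)
DEFAULT_MIN_COMPONENT_SIZE = 3
DEFAULT_MIN_OCCURRENCE = 2


@dataclass
class NodeScoreVector:
    """Per-protein nonnegative scores for one (drug, dose, layer) stratum."""

    scores: dict[str, float]
    stratum: tuple[str, str, str]  # (drug, dose, layer-or-"integrated")

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.scores.items() if v < 0}
        if bad:
            raise ValueError(f"negative scores: {bad}")


@dataclass
class PropagationConfig:
    restart_prob: float = DEFAULT_RESTART_PROB
    delta_quantiles: tuple[float, ...] = DEFAULT_DELTA_QUANTILES
    delta_candidates: tuple[float, ...] | None = None  # overrides quantiles
    min_component_size: int = DEFAULT_MIN_COMPONENT_SIZE

    def __post_init__(self) -> None:
        if not 0 < self.restart_prob < 1:
            raise ValueError("restart_prob must be in (0, 1)")
        if self.min_component_size < 2:
            raise ValueError("min_component_size must be >= 2")
        if self.delta_candidates is not None:
            cand = tuple(self.delta_candidates)
            if list(cand) != sorted(cand) or any(d <= 0 for d in cand):
                raise ValueError("delta_candidates must be positive and ascending")


@dataclass
class DrugSubnetwork:
    """Propagation-derived response subnetwork for one drug and dose."""

    drug: str
    dose: str
    nodes: set[str]
    edges: set[tuple[str, str]]  # directed (i, j) pairs with E[i, j] > delta
    chosen_delta: float
    delta_candidates: tuple[float, ...]
    node_ranking: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    nodes_per_delta: dict[float, int] = field(default_factory=dict)


@dataclass
class ConsensusNetwork:
    """Nodes/edges present in >= min_occurrence of the drug subnetworks."""

    node_occurrence: dict[str, int]
    edge_occurrence: dict[tuple[str, str], int]  # undirected, sorted pairs
    min_occurrence: int

    @property
    def nodes(self) -> set[str]:
        return set(self.node_occurrence)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.edge_occurrence)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score_nodes(
    fits: dict[str, DynamicFit], stratum: tuple[str, str, str]
) -> NodeScoreVector:
    """-log10 p-value sum over the three treatment-vs-control coefficients for
    dynamic features; zero for everything else."""
    scores: dict[str, float] = {}
    for feature, fit in fits.items():
        if fit.failed:
            continue
        if not fit.is_dynamic:
            scores[feature] = 0.0
            continue
        p = np.asarray(fit.p_TvsC, dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError(f"p-values outside (0, 1] for {feature}: {p}")
        scores[feature] = float(-np.log10(p).sum())
    return NodeScoreVector(scores=scores, stratum=stratum)


def integrate_scores(
    proteome: NodeScoreVector, transcriptome: NodeScoreVector
) -> NodeScoreVector:
    """Per-protein sum of layer scores; single-layer proteins keep their score."""
    if proteome.stratum[:2] != transcriptome.stratum[:2]:
        raise ValueError(
            f"stratum mismatch: {proteome.stratum} vs {transcriptome.stratum}"
        )
    merged = dict(proteome.scores)
    for k, v in transcriptome.scores.items():
        merged[k] = merged.get(k, 0.0) + v
    return NodeScoreVector(
        scores=merged, stratum=(*proteome.stratum[:2], "integrated")
    )


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def build_transition(graph: nx.Graph) -> tuple[sp.csc_matrix, list[str]]:
    """Column-normalized walk matrix of a simple undirected graph.

    W[i, j] = 1/degree(j) for each edge (i, j). Isolated nodes are dropped
    (logged) before normalization; a graph without edges is an error.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("graph has no edges; walk matrix undefined")
    isolated = list(nx.isolates(graph))
    if isolated:
        logger.warning("dropping %d isolated nodes from walk matrix", len(isolated))
        graph = graph.subgraph([n for n in graph if n not in set(isolated)])
    nodes = sorted(graph.nodes)
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, format="csc", dtype=float)
    deg = np.asarray(adj.sum(axis=0)).ravel()
    W = adj @ sp.diags(1.0 / deg)
    return sp.csc_matrix(W), nodes


def diffuse(
    W: sp.spmatrix,
    nodes: list[str],
    scores: NodeScoreVector,
    restart_prob: float = DEFAULT_RESTART_PROB,
    dense_limit: int = DENSE_NODE_LIMIT,
) -> np.ndarray:
    """Exchanged-heat matrix E = F diag(s), F = beta (I - (1-beta) W)^-1.

    Scores for proteins absent from the network are dropped with a logged
    count; network nodes without a score enter with score 0. Uses a dense
    solve up to ``dense_limit`` nodes and a sparse LU factorization above.
    """
    if not 0 < restart_prob < 1:
        raise ValueError("restart_prob must be in (0, 1)")
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    s = np.zeros(n)
    dropped = 0
    for k, v in scores.scores.items():
        i = idx.get(k)
        if i is None:
            dropped += 1
        else:
            s[i] = v
    if dropped:
        logger.info("%d scored proteins absent from the network (dropped)", dropped)

    beta = restart_prob
    A = sp.identity(n, format="csc") - (1.0 - beta) * sp.csc_matrix(W)
    if n <= dense_limit:
        F = beta * np.linalg.solve(A.toarray(), np.eye(n))
    else:
        lu = spla.splu(A)
        F = beta * lu.solve(np.eye(n))
    E = F * s[np.newaxis, :]  # scale column j by score_j
    if E.min() < -1e-12:
        raise ValueError("negative exchanged heat; walk matrix not stochastic?")
    return E


def derive_delta_candidates(
    E: np.ndarray, quantiles: tuple[float, ...] = DEFAULT_DELTA_QUANTILES
) -> tuple[float, ...]:
    """Quantiles of the positive off-diagonal exchanged heat."""
    off = E[~np.eye(E.shape[0], dtype=bool)]
    pos = off[off > 0]
    if pos.size == 0:
        raise ValueError("no positive off-diagonal heat; all scores zero?")
    return tuple(float(np.quantile(pos, q)) for q in sorted(quantiles))


def extract_subnetworks(
    E: np.ndarray,
    nodes: list[str],
    config: PropagationConfig | None = None,
    drug: str = "",
    dose: str = "",
) -> DrugSubnetwork:
    """Threshold exchanged heat at four deltas; keep strongly connected
    components of size >= min_component_size; return the subnetwork at the
    minimal delta, with the node ranking by final score."""
    config = config or PropagationConfig()
    if config.delta_candidates:
        deltas = config.delta_candidates
    elif np.any(E[~np.eye(E.shape[0], dtype=bool)] > 0):
        deltas = derive_delta_candidates(E, config.delta_quantiles)
    else:
        logger.warning("no positive exchanged heat (%s %s): empty subnetwork", drug, dose)
        return DrugSubnetwork(
            drug=drug, dose=dose, nodes=set(), edges=set(),
            chosen_delta=float("nan"), delta_candidates=(),
            node_ranking=pd.Series(0.0, index=nodes),
        )
    n = len(nodes)
    results: dict[float, tuple[set[str], set[tuple[str, str]]]] = {}
    for delta in deltas:
        mask = E > delta
        np.fill_diagonal(mask, False)
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        rows, cols = np.nonzero(mask)
        # E[i, j] is heat received by i from source j: edge j -> i
        g.add_edges_from(zip(cols, rows))
        kept_nodes: set[str] = set()
        kept_edges: set[tuple[str, str]] = set()
        for comp in nx.strongly_connected_components(g):
            if len(comp) < config.min_component_size:
                continue
            kept_nodes |= {nodes[i] for i in comp}
            for j, i in g.edges(comp):
                if i in comp and j in comp:
                    kept_edges.add((nodes[j], nodes[i]))
        results[delta] = (kept_nodes, kept_edges)

    if all(len(v[0]) == 0 for v in results.values()):
        logger.warning("all delta candidates give empty subnetworks (%s %s)", drug, dose)
    chosen = min(deltas)
    kept_nodes, kept_edges = results[chosen]
    kept_idx = [i for i, v in enumerate(nodes) if v in kept_nodes]
    final = E[kept_idx, :].sum(axis=0) if kept_idx else np.zeros(n)
    ranking = pd.Series(final, index=nodes).sort_values(ascending=False)
    return DrugSubnetwork(
        drug=drug,
        dose=dose,
        nodes=kept_nodes,
        edges=kept_edges,
        chosen_delta=chosen,
        delta_candidates=tuple(deltas),
        node_ranking=ranking,
        nodes_per_delta={d: len(v[0]) for d, v in results.items()},
    )


def subnetworks_at_all_deltas(
    E: np.ndarray, nodes: list[str], config: PropagationConfig | None = None
) -> dict[float, set[str]]:
    """Node sets for every delta candidate (used for monotonicity checks)."""
    config = config or PropagationConfig()
    deltas = config.delta_candidates or derive_delta_candidates(
        E, config.delta_quantiles
    )
    out = {}
    for delta in deltas:
        sub = extract_subnetworks(
            E, nodes, PropagationConfig(
                restart_prob=config.restart_prob,
                delta_candidates=(delta,),
                min_component_size=config.min_component_size,
            ),
        )
        out[delta] = sub.nodes
    return out


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def build_consensus(
    subnetworks: list[DrugSubnetwork],
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
) -> ConsensusNetwork:
    """Keep nodes and undirected interactions appearing in >= min_occurrence
    of the per-drug subnetworks (edges additionally need both endpoints kept)."""
    if len(subnetworks) < min_occurrence:
        raise ValueError(
            f"need >= {min_occurrence} subnetworks, got {len(subnetworks)}"
        )
    node_counts: dict[str, int] = {}
    edge_counts: dict[tuple[str, str], int] = {}
    for sub in subnetworks:
        for v in sub.nodes:
            node_counts[v] = node_counts.get(v, 0) + 1
        undirected = {tuple(sorted(e)) for e in sub.edges}
        for e in undirected:
            edge_counts[e] = edge_counts.get(e, 0) + 1
    kept_nodes = {v: c for v, c in node_counts.items() if c >= min_occurrence}
    kept_edges = {
        e: c
        for e, c in edge_counts.items()
        if c >= min_occurrence and e[0] in kept_nodes and e[1] in kept_nodes
    }
    return ConsensusNetwork(
        node_occurrence=kept_nodes,
        edge_occurrence=kept_edges,
        min_occurrence=min_occurrence,
    )


def consensus_to_frames(c: ConsensusNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = pd.DataFrame(
        sorted(c.node_occurrence.items()), columns=["node", "occurrence"]
    )
    edges = pd.DataFrame(
        [(a, b, occ) for (a, b), occ in sorted(c.edge_occurrence.items())],
        columns=["node_a", "node_b", "occurrence"],
    )
    return nodes, edges
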