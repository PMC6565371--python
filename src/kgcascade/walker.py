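"""Biased second-order random walks and skip-gram node embeddings.

The multi-relational graph is first homogenized — collapsed to an undirected,
unlabeled adjacency (linked or not linked) — then explored with node2vec-style
walks. A walk at node ``cur`` having arrived from ``prev`` steps to a neighbor
``x`` with unnormalized weight 1/p if x == prev (return), 1 if x is adjacent
to prev (breadth-first move), and 1/q otherwise (depth-first move). p and q
therefore trade off local versus global exploration; p = q = 1 recovers a
uniform random walk.

Walk corpora are fed to a skip-gram model with negative sampling trained by
plain numpy SGD: for each (center, context) co-occurrence within a window the
model maximizes log σ(u_ctx · v_cen) and pushes down a handful of noise nodes
drawn from the unigram^0.75 distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .kgdata import KnowledgeGraph


@dataclass
class WalkConfig:
    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    walks_per_node: int = 3
    context_size: int = 10
    dim: int = 128
    negatives_per_sample: int = 5
    epochs: int = 5
    learn_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.context_size > self.walk_length:
            raise ValueError("context_size must not exceed walk_length")


@dataclass
class WalkCorpus:
    walks: list[list[int]]

    def __len__(self) -> int:
        return len(self.walks)


@dataclass
class NodeEmbedding:
    vectors: np.ndarray  # |V| x d
    loss_history: list[float] = field(default_factory=list)

    def __getitem__(self, node: int) -> np.ndarray:
        return self.vectors[node]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


class Adjacency:
    """Undirected unlabeled adjacency with sorted neighbor arrays."""

    def __init__(self, n_nodes: int, edges: set[tuple[int, int]]) -> None:
        self.n_nodes = n_nodes
        self.edges = edges  # canonical (min, max) pairs; (v, v) for self-loops
        nbrs: list[set[int]] = [set() for _ in range(n_nodes)]
        for u, v in edges:
            nbrs[u].add(v)
            nbrs[v].add(u)
        self.neighbors = [np.array(sorted(s), dtype=np.int64) for s in nbrs]

    def has_edge(self, u: int, v: int) -> bool:
        return (min(u, v), max(u, v)) in self.edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def homogenize(graph: KnowledgeGraph) -> Adjacency:
    """Collapse direction and relation labels: one edge per linked entity pair."""
    edges = {(min(h, t), max(h, t)) for h, _, t in graph.triplets}
    return Adjacency(graph.n_entities, edges)


def transition_weights(
    adj: Adjacency, prev: int | None, cur: int, p: float, q: float
) -> tuple[np.ndarray, np.ndarray]:
    """Second-order step distribution over neighbors of ``cur``.

    Returns (neighbor ids, probabilities summing to 1). The first step of a
    walk (prev is None) is uniform. A node with no neighbors yields empty
    arrays and the walk terminates.
    """
    nbrs = adj.neighbors[cur]
    if nbrs.size == 0:
        return nbrs, np.empty(0)
    if prev is None:
        return nbrs, np.full(nbrs.size, 1.0 / nbrs.size)
    w = np.empty(nbrs.size)
    for i, x in enumerate(nbrs):
        if x == prev:
            w[i] = 1.0 / p
        elif adj.has_edge(int(x), prev):
            w[i] = 1.0
        else:
            w[i] = 1.0 / q
    return nbrs, w / w.sum()


def generate_walks(adj: Adjacency, config: WalkConfig) -> WalkCorpus:
    """``walks_per_node`` biased walks from every node, seeded and reproducible.

    Step distributions are memoized per (prev, cur) state, which plays the
    role of a precomputed alias table without materializing every edge state
    up front.
    """
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple[int | None, int], tuple[np.ndarray, np.ndarray]] = {}

    def step_dist(prev: int | None, cur: int):
        key = (prev, cur)
        if key not in cache:
            cache[key] = transition_weights(adj, prev, cur, config.p, config.q)
        return cache[key]

    walks: list[list[int]] = []
    for _ in range(config.walks_per_node):
        for start in range(adj.n_nodes):
            walk = [start]
            prev: int | None = None
            while len(walk) < config.walk_length:
                cur = walk[-1]
                nbrs, probs = step_dist(prev, cur)
                if nbrs.size == 0:
                    break
                nxt = int(nbrs[rng.choice(nbrs.size, p=probs)])
                walk.append(nxt)
                prev = cur
            walks.append(walk)
    return WalkCorpus(walks)


def _skipgram_pairs(corpus: WalkCorpus, window: int) -> np.ndarray:
    """All (center, context) pairs within the window, as an (n, 2) array."""
    pairs = []
    for walk in corpus.walks:
        L = len(walk)
        for i, center in enumerate(walk):
            lo = max(0, i - window)
            hi = min(L, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    pairs.append((center, walk[j]))
    if not pairs:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(pairs, dtype=np.int64)


def train_node_embedding(
    corpus: WalkCorpus,
    config: WalkConfig,
    n_nodes: int | None = None,
    *,
    batch_size: int = 4096,
) -> NodeEmbedding:
    """Skip-gram with negative sampling over the walk corpus (numpy SGD).

    Noise nodes are drawn from the corpus unigram distribution raised to 0.75.
    The learning rate decays linearly across epochs. Fixed seed implies a
    reproducible embedding. Every node of the graph receives a vector; nodes
    absent from the corpus keep their random initialization.
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    max_node = max(max(w) for w in corpus.walks)
    if n_nodes is None:
        n_nodes = max_node + 1
    elif max_node >= n_nodes:
        raise ValueError(
            f"corpus mentions node {max_node} but n_nodes is {n_nodes}"
        )
    rng = np.random.default_rng(config.seed)
    d = config.dim
    V = n_nodes
    vec_in = (rng.random((V, d)) - 0.5) / d  # center ("input") vectors
    vec_out = np.zeros((V, d))  # context ("output") vectors

    counts = np.bincount(
        np.concatenate([np.asarray(w) for w in corpus.walks]), minlength=V
    ).astype(float)
    noise = counts**0.75
    noise /= noise.sum()

    pairs = _skipgram_pairs(corpus, config.context_size)
    if pairs.shape[0] == 0:
        return NodeEmbedding(vectors=vec_in)
    n_pairs = pairs.shape[0]
    # gradients are scatter-summed per batch: a node recurring many times in
    # one batch takes the summed step, so the batch must stay small relative
    # to the vocabulary or training diverges on small graphs
    batch_size = int(max(32, min(batch_size, V)))
    K = config.negatives_per_sample
    lr0, lr_min = config.learn_rate, 1e-4
    history: list[float] = []
    total_steps = config.epochs * n_pairs
    done = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n_pairs)
        epoch_loss = 0.0
        for start in range(0, n_pairs, batch_size):
            idx = order[start : start + batch_size]
            centers = pairs[idx, 0]
            contexts = pairs[idx, 1]
            b = idx.size
            negs = rng.choice(V, size=(b, K), p=noise)
            lr = max(lr_min, lr0 * (1.0 - done / total_steps))
            done += b

            v = vec_in[centers]  # b x d
            u_pos = vec_out[contexts]  # b x d
            u_neg = vec_out[negs]  # b x K x d

            s_pos = expit(np.einsum("bd,bd->b", v, u_pos))
            s_neg = expit(np.einsum("bkd,bd->bk", u_neg, v))
            with np.errstate(divide="ignore"):
                epoch_loss += float(
                    -np.log(np.clip(s_pos, 1e-12, None)).sum()
                    - np.log(np.clip(1.0 - s_neg, 1e-12, None)).sum()
                )

            g_pos = s_pos - 1.0  # b
            grad_v = g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", s_neg, u_neg)
            grad_u_pos = g_pos[:, None] * v
            grad_u_neg = s_neg[:, :, None] * v[:, None, :]

            np.add.at(vec_in, centers, -lr * grad_v)
            np.add.at(vec_out, contexts, -lr * grad_u_pos)
            np.add.at(vec_out, negs.ravel(), -lr * grad_u_neg.reshape(-1, d))
        history.append(epoch_loss / n_pairs)
    return NodeEmbedding(vectors=vec_in, loss_history=history)


EDGE_OPERATORS = ("hadamard", "average", "l1", "l2")


def edge_feature(u_vec: np.ndarray, v_vec: np.ndarray, operator: str = "hadamard") -> np.ndarray:
    """Binary edge operator g(u, v) on two node vectors.

    hadamard: elementwise product (the cascade's default G feature);
    average: elementwise mean; l1: |u - v|; l2: (u - v)^2.
    """
    u_vec = np.asarray(u_vec, dtype=float)
    v_vec = np.asarray(v_vec, dtype=float)
    if u_vec.shape != v_vec.shape:
        raise ValueError(f"dimension mismatch: {u_vec.shape} vs {v_vec.shape}")
    if operator == "hadamard":
        return u_vec * v_vec
    if operator == "average":
        return (u_vec + v_vec) / 2.0
    if operator == "l1":
        return np.abs(u_vec - v_vec)
    if operator == "l2":
        return (u_vec - v_vec) ** 2
    raise ValueError(f"unknown operator {operator!r}; expected one of {EDGE_OPERATORS}")
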