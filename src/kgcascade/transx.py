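"""Translation-based knowledge embedding: TransE and TranSparse.

Both models embed entities and relations so that a true fact (h, r, t)
satisfies h + r ≈ t in the embedding space; a triplet's dissimilarity is
d(h, r, t) = ||h_p + r - t_p|| under the L1 or L2 norm, where h_p, t_p are
the head/tail images. TransE uses the raw entity vectors; TranSparse first
projects them through per-relation sparse matrices M_rh, M_rt whose sparse
degree (fraction of structurally zero entries) adapts to how many entities
the relation links — relations touching few entities get sparser, hence
lower-capacity, projections.

Training minimizes the margin ranking loss
    sum over positives and their corruptions of [γ + d(pos) - d(neg)]_+
by minibatch SGD with one corrupted triplet per positive per step.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np

from .kgdata import KnowledgeGraph, Side, Triplet, corrupt_triplet


@dataclass
class TransXConfig:
    model: str = "transparse"  # "transe" | "transparse"
    dim_entity: int = 100
    dim_relation: int = 100
    margin: float = 1.5
    learn_rate: float = 0.001
    epochs: int = 1000
    norm: str = "L1"  # "L1" | "L2"
    theta_min: float = 0.0
    batch_size: int = 512
    # optional final learning rate for a linear per-epoch decay schedule
    lr_final: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("transe", "transparse"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == "transe" and self.dim_entity != self.dim_relation:
            raise ValueError("transe requires dim_entity == dim_relation")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.norm not in ("L1", "L2"):
            raise ValueError(f"norm must be 'L1' or 'L2', got {self.norm!r}")
        if not 0.0 <= self.theta_min <= 1.0:
            raise ValueError("theta_min must lie in [0, 1]")


@dataclass
class TransXModel:
    config: TransXConfig
    entity_vecs: np.ndarray  # |E| x n
    relation_vecs: np.ndarray  # |R| x m
    # TranSparse only; None for TransE
    proj_head: np.ndarray | None = None  # |R| x m x n
    proj_tail: np.ndarray | None = None
    mask_head: np.ndarray | None = None  # boolean zero-pattern masks
    mask_tail: np.ndarray | None = None
    theta_head: np.ndarray | None = None  # declared sparse degrees per relation
    theta_tail: np.ndarray | None = None

    @property
    def is_sparse(self) -> bool:
        return self.config.model == "transparse"

    def copy(self) -> "TransXModel":
        return TransXModel(
            config=self.config,
            entity_vecs=self.entity_vecs.copy(),
            relation_vecs=self.relation_vecs.copy(),
            proj_head=None if self.proj_head is None else self.proj_head.copy(),
            proj_tail=None if self.proj_tail is None else self.proj_tail.copy(),
            mask_head=None if self.mask_head is None else self.mask_head.copy(),
            mask_tail=None if self.mask_tail is None else self.mask_tail.copy(),
            theta_head=None if self.theta_head is None else self.theta_head.copy(),
            theta_tail=None if self.theta_tail is None else self.theta_tail.copy(),
        )

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        np.save(os.path.join(directory, "entity_vecs.npy"), self.entity_vecs)
        np.save(os.path.join(directory, "relation_vecs.npy"), self.relation_vecs)
        manifest = {"config": asdict(self.config)}
        if self.is_sparse:
            np.save(os.path.join(directory, "proj_head.npy"), self.proj_head)
            np.save(os.path.join(directory, "proj_tail.npy"), self.proj_tail)
            np.save(os.path.join(directory, "mask_head.npy"), self.mask_head)
            np.save(os.path.join(directory, "mask_tail.npy"), self.mask_tail)
            manifest["theta_head"] = self.theta_head.tolist()
            manifest["theta_tail"] = self.theta_tail.tolist()
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory: str) -> "TransXModel":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        config = TransXConfig(**manifest["config"])
        kwargs = dict(
            config=config,
            entity_vecs=np.load(os.path.join(directory, "entity_vecs.npy")),
            relation_vecs=np.load(os.path.join(directory, "relation_vecs.npy")),
        )
        if config.model == "transparse":
            kwargs.update(
                proj_head=np.load(os.path.join(directory, "proj_head.npy")),
                proj_tail=np.load(os.path.join(directory, "proj_tail.npy")),
                mask_head=np.load(os.path.join(directory, "mask_head.npy")),
                mask_tail=np.load(os.path.join(directory, "mask_tail.npy")),
                theta_head=np.array(manifest["theta_head"]),
                theta_tail=np.array(manifest["theta_tail"]),
            )
        return cls(**kwargs)


def _sparse_mask(m: int, n: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with round((1-theta)*m*n) structurally nonzero entries.

    Diagonal entries are kept nonzero first (the projection starts near the
    identity), then off-diagonal positions are filled at random.
    """
    nnz = int(round((1.0 - theta) * m * n))
    mask = np.zeros((m, n), dtype=bool)
    diag = min(m, n)
    if nnz >= diag:
        mask[np.arange(diag), np.arange(diag)] = True
        remaining = nnz - diag
        off = [(i, j) for i in range(m) for j in range(n) if i != j]
        if remaining > 0:
            pick = rng.choice(len(off), size=remaining, replace=False)
            for k in pick:
                mask[off[k]] = True
    elif nnz > 0:
        pick = rng.choice(diag, size=nnz, replace=False)
        mask[pick, pick] = True
    return mask


def sparse_degrees(graph: KnowledgeGraph, theta_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-relation sparse degrees θ_rh, θ_rt from observed fan-out.

    θ = 1 - (1 - θ_min) · N / N_max where N counts the distinct head (resp.
    tail) entities a relation links and N_max the maximum over relations.
    The busiest relation gets the densest projection (θ = θ_min).
    """
    n_rel = graph.n_relations
    n_heads = np.zeros(n_rel)
    n_tails = np.zeros(n_rel)
    heads: dict[int, set] = {r: set() for r in range(n_rel)}
    tails: dict[int, set] = {r: set() for r in range(n_rel)}
    for h, r, t in graph.triplets:
        heads[r].add(h)
        tails[r].add(t)
    for r in range(n_rel):
        n_heads[r] = len(heads[r])
        n_tails[r] = len(tails[r])
    hmax = n_heads.max() if n_rel and n_heads.max() > 0 else 1.0
    tmax = n_tails.max() if n_rel and n_tails.max() > 0 else 1.0
    theta_h = 1.0 - (1.0 - theta_min) * n_heads / hmax
    theta_t = 1.0 - (1.0 - theta_min) * n_tails / tmax
    return theta_h, theta_t


def init_transx(graph: KnowledgeGraph, config: TransXConfig) -> TransXModel:
    """Initialize embeddings uniform in [-6/√n, 6/√n]; fix sparse patterns."""
    if graph.n_triplets == 0:
        raise ValueError("cannot initialize on an empty graph")
    rng = np.random.default_rng(config.seed)
    n, m = config.dim_entity, config.dim_relation
    bound_e = 6.0 / np.sqrt(n)
    bound_r = 6.0 / np.sqrt(m)
    entity_vecs = rng.uniform(-bound_e, bound_e, size=(graph.n_entities, n))
    relation_vecs = rng.uniform(-bound_r, bound_r, size=(graph.n_relations, m))
    if config.model == "transe":
        return TransXModel(config, entity_vecs, relation_vecs)
    theta_h, theta_t = sparse_degrees(graph, config.theta_min)
    mask_h = np.stack([_sparse_mask(m, n, th, rng) for th in theta_h])
    mask_t = np.stack([_sparse_mask(m, n, th, rng) for th in theta_t])
    eye = np.zeros((m, n))
    eye[np.arange(min(m, n)), np.arange(min(m, n))] = 1.0
    proj_h = (eye[None, :, :] * mask_h).astype(float)
    proj_t = (eye[None, :, :] * mask_t).astype(float)
    return TransXModel(
        config,
        entity_vecs,
        relation_vecs,
        proj_head=proj_h,
        proj_tail=proj_t,
        mask_head=mask_h,
        mask_tail=mask_t,
        theta_head=theta_h,
        theta_tail=theta_t,
    )


def project_entity(model: TransXModel, entity: int, relation: int, side: Side) -> np.ndarray:
    """Image of an entity in relation space: M·v for TranSparse, v for TransE."""
    v = model.entity_vecs[entity]
    if not model.is_sparse:
        return v.copy()
    M = model.proj_head[relation] if side is Side.HEAD else model.proj_tail[relation]
    return M @ v


def residual(model: TransXModel, t: Triplet) -> np.ndarray:
    """The translation residual h_p + r - t_p for one triplet."""
    t = Triplet(*t)
    hp = project_entity(model, t.head, t.relation, Side.HEAD)
    tp = project_entity(model, t.tail, t.relation, Side.TAIL)
    return hp + model.relation_vecs[t.relation] - tp


def score_triplet(model: TransXModel, t: Triplet) -> float:
    """Dissimilarity d(h, r, t) = ||h_p + r - t_p||; lower is more plausible."""
    res = residual(model, t)
    if model.config.norm == "L1":
        return float(np.abs(res).sum())
    return float(np.linalg.norm(res))


def score_batch(model: TransXModel, triplets: np.ndarray) -> np.ndarray:
    """Vectorized dissimilarities for an (n, 3) array of triplets."""
    H, R, T = triplets[:, 0], triplets[:, 1], triplets[:, 2]
    h = model.entity_vecs[H]
    t = model.entity_vecs[T]
    r = model.relation_vecs[R]
    if model.is_sparse:
        hp = np.einsum("kmn,kn->km", model.proj_head[R], h)
        tp = np.einsum("kmn,kn->km", model.proj_tail[R], t)
    else:
        hp, tp = h, t
    res = hp + r - tp
    if model.config.norm == "L1":
        return np.abs(res).sum(axis=1)
    return np.linalg.norm(res, axis=1)


def margin_loss(d_pos: float, d_neg: float, margin: float) -> float:
    """Hinge contribution max(0, margin + d_pos - d_neg)."""
    if margin <= 0:
        raise ValueError("margin must be positive")
    return max(0.0, margin + d_pos - d_neg)


def _norm_grad(res: np.ndarray, norm: str) -> np.ndarray:
    """∂||res||/∂res; L1 subgradient at 0 taken as 0."""
    if norm == "L1":
        return np.sign(res)
    nrm = np.linalg.norm(res)
    if nrm == 0.0:
        return np.zeros_like(res)
    return res / nrm


def pair_gradients(
    model: TransXModel, pos: Triplet, neg: Triplet, margin: float
) -> tuple[float, dict]:
    """Hinge loss for one (positive, corruption) pair and its gradients.

    Returns (loss, grads) where grads maps parameter slots —
    ``("entity", i)``, ``("relation", r)``, ``("proj_head", r)``,
    ``("proj_tail", r)`` — to dense gradient arrays. Gradients of the sparse
    projection matrices are masked so structural zeros stay zero.
    """
    d_pos = score_triplet(model, pos)
    d_neg = score_triplet(model, neg)
    loss = margin_loss(d_pos, d_neg, margin)
    grads: dict = {}
    if loss == 0.0:
        return loss, grads

    def accumulate(t: Triplet, sign: float) -> None:
        res = residual(model, t)
        g = sign * _norm_grad(res, model.config.norm)
        h_vec = model.entity_vecs[t.head]
        t_vec = model.entity_vecs[t.tail]
        if model.is_sparse:
            Mh = model.proj_head[t.relation]
            Mt = model.proj_tail[t.relation]
            _add(grads, ("entity", t.head), Mh.T @ g)
            _add(grads, ("entity", t.tail), -(Mt.T @ g))
            _add(grads, ("proj_head", t.relation),
                 np.outer(g, h_vec) * model.mask_head[t.relation])
            _add(grads, ("proj_tail", t.relation),
                 -np.outer(g, t_vec) * model.mask_tail[t.relation])
        else:
            _add(grads, ("entity", t.head), g)
            _add(grads, ("entity", t.tail), -g)
        _add(grads, ("relation", t.relation), g)

    accumulate(pos, +1.0)
    accumulate(neg, -1.0)
    return loss, grads


def _add(grads: dict, key: tuple, value: np.ndarray) -> None:
    if key in grads:
        grads[key] = grads[key] + value
    else:
        grads[key] = value


def _apply_grads(model: TransXModel, grads: dict, lr: float) -> None:
    for (kind, idx), g in grads.items():
        if kind == "entity":
            model.entity_vecs[idx] -= lr * g
        elif kind == "relation":
            model.relation_vecs[idx] -= lr * g
        elif kind == "proj_head":
            model.proj_head[idx] -= lr * g
        elif kind == "proj_tail":
            model.proj_tail[idx] -= lr * g


def _renormalize_entities(model: TransXModel) -> None:
    norms = np.linalg.norm(model.entity_vecs, axis=1)
    over = norms > 1.0
    if over.any():
        model.entity_vecs[over] /= norms[over, None]


def train_transx(
    graph: KnowledgeGraph,
    config: TransXConfig,
    *,
    epoch_callback: Callable[[int, float], None] | None = None,
) -> TransXModel:
    """Minibatch SGD on the margin ranking loss with one corruption per positive.

    Entity vectors are renormalized to the unit ball after every epoch. The
    whole trajectory is a pure function of ``config.seed``. Raises on a
    non-finite loss.
    """
    if graph.n_entities < 2:
        raise ValueError("training needs at least 2 entities")
    model = init_transx(graph, config)
    if config.epochs == 0:
        return model
    rng = np.random.default_rng(config.seed + 1)
    triplets = [Triplet(*row) for row in graph.triplet_array()]
    n = len(triplets)
    for epoch in range(config.epochs):
        if config.lr_final is not None and config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            lr = config.learn_rate + frac * (config.lr_final - config.learn_rate)
        else:
            lr = config.learn_rate
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            batch_grads: dict = {}
            for j in order[start : start + config.batch_size]:
                pos = triplets[j]
                neg = corrupt_triplet(pos, graph, rng).triplet
                loss, grads = pair_gradients(model, pos, neg, config.margin)
                total += loss
                for key, g in grads.items():
                    _add(batch_grads, key, g)
            _apply_grads(model, batch_grads, lr)
        _renormalize_entities(model)
        if not np.isfinite(total):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {total}"
            )
        if epoch_callback is not None:
            epoch_callback(epoch, total / n)
    return model


def export_word2vec(names, vectors: np.ndarray, path: str) -> None:
    """Write embeddings in word2vec text format: count dim header, then rows."""
    n, d = vectors.shape
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{n} {d}\n")
        for name, row in zip(names, vectors):
            fh.write(name + " " + " ".join(f"{x:.6g}" for x in row) + "\n")
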