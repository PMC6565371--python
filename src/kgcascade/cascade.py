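"""Feature construction and the two-stage logistic cascade.

For a triplet (h, r, t) two complementary feature blocks are built:

* semantic feature ``F(h, t) = |h_r + r - t_r|`` — the elementwise absolute
  translation residual in relation space, from the knowledge embedding;
* graph feature ``G(h, t) = u(h) * u(t)`` — the hadamard product of the two
  node embeddings, from the random-walk model.

The cascade is an ordered sequence of logistic classifiers. In the default
two-stage plan, the graph features pass through stage one alone; stage two
consumes the semantic features concatenated with stage one's predicted
probability, so the topological evidence is refined before fusion. Each stage
minimizes the L2-penalized negative log-likelihood

    L(θ) = -Σ [y_i log p_i + (1 - y_i) log(1 - p_i)] + α ||θ||²

with the bias unpenalized. Single-stage plans on F alone, G alone, or the
plain concatenation [F ∥ G] are available for ablations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .kgdata import KnowledgeGraph, Triplet, corrupt_triplet
from .transx import TransXModel, residual
from .walker import NodeEmbedding, edge_feature

FEATURE_PLANS = ("two-stage", "sg", "s", "g")


@dataclass
class FeatureSet:
    """Labeled feature rows: one per (triplet, label) pair."""

    F: np.ndarray  # n x m semantic residuals, elementwise >= 0
    G: np.ndarray  # n x d hadamard graph features
    y: np.ndarray  # n, in {0, 1}
    triplets: list[Triplet] = field(default_factory=list)

    def __len__(self) -> int:
        return self.y.shape[0]


@dataclass
class Stage:
    weights: np.ndarray
    bias: float


@dataclass
class CascadeModel:
    stages: list[Stage]
    feature_plan: str
    alpha_reg: float

    def save(self, path: str) -> None:
        payload = {
            "feature_plan": self.feature_plan,
            "alpha_reg": self.alpha_reg,
            "stages": [
                {"weights": s.weights.tolist(), "bias": s.bias} for s in self.stages
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "CascadeModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            stages=[
                Stage(np.asarray(s["weights"], dtype=float), float(s["bias"]))
                for s in payload["stages"]
            ],
            feature_plan=payload["feature_plan"],
            alpha_reg=payload["alpha_reg"],
        )


def semantic_feature(model: TransXModel, t: Triplet) -> np.ndarray:
    """F(h, t) = |h_r + r - t_r|, the absolute residual in relation space."""
    return np.abs(residual(model, t))


def graph_feature(nemb: NodeEmbedding, t: Triplet) -> np.ndarray:
    """G(h, t) = u(h) * u(t), the hadamard edge feature."""
    t = Triplet(*t)
    return edge_feature(nemb[t.head], nemb[t.tail], "hadamard")


def build_feature_set(
    kmodel: TransXModel,
    nemb: NodeEmbedding,
    positives: list[Triplet],
    graph: KnowledgeGraph,
    neg_ratio: float,
    rng: np.random.Generator,
) -> FeatureSet:
    """[F, G] rows for each positive (y=1) plus ``neg_ratio`` corruptions each.

    Negatives are drawn by the head/tail replacement protocol, filtered
    against the graph's positive set. Deterministic under a seeded rng.
    """
    n_ent = kmodel.entity_vecs.shape[0]
    if nemb.vectors.shape[0] < graph.n_entities or n_ent < graph.n_entities:
        raise ValueError(
            f"embeddings cover {min(nemb.vectors.shape[0], n_ent)} entities "
            f"but the graph has {graph.n_entities}"
        )
    rows: list[Triplet] = []
    labels: list[int] = []
    for pos in positives:
        pos = Triplet(*pos)
        if pos.head >= n_ent or pos.tail >= n_ent:
            raise ValueError(f"entity missing an embedding in {pos}")
        rows.append(pos)
        labels.append(1)
    n_neg_total = int(round(neg_ratio * len(positives)))
    for k in range(n_neg_total):
        src = Triplet(*positives[k % len(positives)])
        neg = corrupt_triplet(src, graph, rng).triplet
        rows.append(neg)
        labels.append(0)
    F = np.stack([semantic_feature(kmodel, t) for t in rows])
    G = np.stack([graph_feature(nemb, t) for t in rows])
    return FeatureSet(F=F, G=G, y=np.asarray(labels), triplets=rows)


def stage_forward(theta: np.ndarray, bias: float, x: np.ndarray) -> np.ndarray:
    """σ(θᵀx + bias); accepts a single vector or an (n, k) matrix of rows."""
    x = np.asarray(x, dtype=float)
    z = x @ np.asarray(theta, dtype=float) + bias
    return expit(z)


def _fit_logistic(X: np.ndarray, y: np.ndarray, alpha_reg: float) -> Stage:
    """One L2-penalized logistic stage via a deterministic quasi-Newton fit.

    α Σθ² corresponds to C = 1/(2α) in scikit-learn's objective; the
    intercept is unpenalized.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("stage training requires both labels present")
    C = 1.0 / (2.0 * alpha_reg) if alpha_reg > 0 else 1e12
    clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-6, max_iter=2000)
    clf.fit(X, y)
    return Stage(weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]))


def _stage_inputs(plan: str, F: np.ndarray, G: np.ndarray, p1: np.ndarray | None):
    if plan == "s":
        return F
    if plan == "g":
        return G
    if plan == "sg":
        return np.hstack([F, G])
    if plan == "two-stage":
        return np.hstack([F, p1[:, None]])
    raise ValueError(f"unknown feature plan {plan!r}; expected one of {FEATURE_PLANS}")


def train_cascade(
    features: FeatureSet, alpha_reg: float = 1.0, plan: str = "two-stage"
) -> CascadeModel:
    """Fit the cascade stages on a labeled feature set.

    two-stage: stage 1 on G alone, stage 2 on [F ∥ p1] where p1 is stage 1's
    predicted probability. "s"/"g"/"sg" fit a single logistic stage on F, G,
    or [F ∥ G] respectively.
    """
    if plan not in FEATURE_PLANS:
        raise ValueError(f"unknown feature plan {plan!r}; expected one of {FEATURE_PLANS}")
    F, G, y = features.F, features.G, features.y
    stages: list[Stage] = []
    if plan == "two-stage":
        s1 = _fit_logistic(G, y, alpha_reg)
        p1 = stage_forward(s1.weights, s1.bias, G)
        s2 = _fit_logistic(_stage_inputs(plan, F, G, p1), y, alpha_reg)
        stages = [s1, s2]
    else:
        stages = [_fit_logistic(_stage_inputs(plan, F, G, None), y, alpha_reg)]
    return CascadeModel(stages=stages, feature_plan=plan, alpha_reg=alpha_reg)


def predict_proba(model: CascadeModel, F: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Final-stage probability for rows of [F, G] features."""
    if not model.stages:
        raise ValueError("cascade model has no trained stages")
    F = np.atleast_2d(np.asarray(F, dtype=float))
    G = np.atleast_2d(np.asarray(G, dtype=float))
    plan = model.feature_plan
    if plan == "two-stage":
        s1, s2 = model.stages
        p1 = stage_forward(s1.weights, s1.bias, G)
        out = stage_forward(s2.weights, s2.bias, _stage_inputs(plan, F, G, p1))
    else:
        (s1,) = model.stages
        out = stage_forward(s1.weights, s1.bias, _stage_inputs(plan, F, G, None))
    return out if out.shape[0] > 1 else out.reshape(-1)


def triplet_scorer(kmodel: TransXModel, nemb: NodeEmbedding, model: CascadeModel):
    """A triplet -> probability callable over the trained cascade (vectorized
    over lists of triplets)."""

    def score(triplets) -> np.ndarray:
        single = isinstance(triplets, tuple) or (
            hasattr(triplets, "head") and not isinstance(triplets, list)
        )
        ts = [Triplet(*triplets)] if single else [Triplet(*t) for t in triplets]
        F = np.stack([semantic_feature(kmodel, t) for t in ts])
        G = np.stack([graph_feature(nemb, t) for t in ts])
        p = np.atleast_1d(predict_proba(model, F, G))
        return float(p[0]) if single else p

    return score
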