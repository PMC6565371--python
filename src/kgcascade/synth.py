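"""Deterministic synthetic generators for knowledge graphs and classifier data.

Three generators cover the statistical structure of real biochemical triplet
stores without any of their semantics:

* ``make_translation_kg`` plants an exact translation geometry — latent
  entity points and per-relation offsets in R^k; the facts of each relation
  are the entity pairs whose latent residual ``||h* + r* - t*||`` (plus
  optional noise) is smallest, emitted by quantile so the per-relation triplet
  count is exact. Recovery of this structure by a trained embedding is the
  package's main end-to-end check.
* ``make_imbalanced_kg`` emulates extreme 1-to-many fan-out (a relation whose
  tails each collect many heads, like compound–gene binding) and the
  long-tailed degree profile where most entities occur exactly once.
* ``make_cascade_fixture`` draws logistic-regression data with known weights
  for parameter-recovery tests of the cascade stages.

All generators are pure functions of their spec, seed included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import FeatureSet
from .kgdata import KnowledgeGraph, Triplet


@dataclass
class PlantedKGSpec:
    n_entities: int = 50
    n_relations: int = 2
    latent_dim: int = 4
    noise_sd: float = 0.0
    triplets_per_relation: int = 100
    fanout: tuple[float, float] | None = None  # (heads_per_tail, tails_per_head)
    # latent community structure: entities drawn around n_clusters centers.
    # With clusters, close pairs are mostly intra-community, so the emitted
    # graph carries topological (modular) signal alongside the translation
    # geometry. n_clusters=1 recovers a single isotropic cloud.
    n_clusters: int = 1
    cluster_spread: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_entities, self.n_relations, self.latent_dim, self.triplets_per_relation) < 1:
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def make_translation_kg(spec: PlantedKGSpec) -> tuple[KnowledgeGraph, dict]:
    """Plant h* + r* ≈ t* structure; returns the graph and ground truth.

    For each relation the ``triplets_per_relation`` ordered entity pairs with
    the smallest noisy latent residual are emitted (self-pairs excluded).
    Ground truth holds the latent entity matrix and relation offsets.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.n_clusters > 1:
        centers = rng.standard_normal((spec.n_clusters, spec.latent_dim))
        assign = rng.integers(spec.n_clusters, size=spec.n_entities)
        E = centers[assign] + spec.cluster_spread * rng.standard_normal(
            (spec.n_entities, spec.latent_dim)
        )
        R = spec.cluster_spread * rng.standard_normal(
            (spec.n_relations, spec.latent_dim)
        )
    else:
        E = rng.standard_normal((spec.n_entities, spec.latent_dim))
        R = rng.standard_normal((spec.n_relations, spec.latent_dim))
    n = spec.n_entities
    max_pairs = n * (n - 1)
    if spec.triplets_per_relation > max_pairs:
        raise ValueError(
            f"cannot emit {spec.triplets_per_relation} triplets from {max_pairs} ordered pairs"
        )
    triplets: list[Triplet] = []
    for r in range(spec.n_relations):
        # residual of every ordered pair (h, t), h != t
        diff = E[:, None, :] + R[r][None, None, :] - E[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dist, np.inf)
        if spec.noise_sd > 0:
            dist = dist + spec.noise_sd * rng.standard_normal(dist.shape)
            np.fill_diagonal(dist, np.inf)
        flat = dist.ravel()
        cut_idx = np.argsort(flat, kind="stable")[: spec.triplets_per_relation]
        for idx in cut_idx:
            h, t = divmod(int(idx), n)
            triplets.append(Triplet(h, r, t))
    graph = KnowledgeGraph(
        [f"e{i}" for i in range(n)],
        [f"r{j}" for j in range(spec.n_relations)],
        triplets,
    )
    return graph, {"entities": E, "relations": R}


def _preferential_fill(pool: int, total: int, rng: np.random.Generator) -> np.ndarray:
    """``total`` draws from ``pool`` ids, each id at least once, rich get richer."""
    counts = np.ones(pool, dtype=np.int64)
    for _ in range(total - pool):
        probs = counts / counts.sum()
        counts[rng.choice(pool, p=probs)] += 1
    out = np.repeat(np.arange(pool), counts)
    rng.shuffle(out)
    return out


def make_imbalanced_kg(spec: PlantedKGSpec) -> KnowledgeGraph:
    """Fan-out-controlled bipartite relation(s) with a long-tailed degree profile.

    ``spec.fanout = (H, T)`` targets a mean of H distinct heads per tail and T
    distinct tails per head. Distinct-entity pool sizes are set to
    round(count/H) and round(count/T), and every pool member is used at least
    once, so the realized means land within 10% of the targets. Head and tail
    pools are disjoint, mimicking typed bipartite relations.
    """
    if spec.fanout is None:
        raise ValueError("make_imbalanced_kg requires fanout targets")
    H, T = spec.fanout
    if H < 1 or T < 1:
        raise ValueError("fanout targets must be >= 1")
    rng = np.random.default_rng(spec.seed)
    count = spec.triplets_per_relation
    triplets: list[Triplet] = []
    entity_names: list[str] = []
    for r in range(spec.n_relations):
        n_tails = max(1, int(round(count / H)))
        n_heads = max(1, int(round(count / T)))
        if n_heads * n_tails < count:
            raise ValueError(
                f"fanout targets ({H}, {T}) infeasible: only {n_heads * n_tails} "
                f"distinct pairs for {count} triplets"
            )
        h_off = len(entity_names)
        entity_names.extend(f"h{r}_{i}" for i in range(n_heads))
        t_off = len(entity_names)
        entity_names.extend(f"t{r}_{i}" for i in range(n_tails))
        heads = _preferential_fill(n_heads, count, rng)
        tails = _preferential_fill(n_tails, count, rng)
        seen: set[tuple[int, int]] = set()
        for h, t in zip(heads, tails):
            pair = (int(h), int(t))
            tries = 0
            while pair in seen:
                pair = (int(rng.integers(n_heads)), int(rng.integers(n_tails)))
                tries += 1
                if tries > 10000:
                    raise ValueError("could not realize unique pairs for fanout spec")
            seen.add(pair)
            triplets.append(Triplet(h_off + pair[0], r, t_off + pair[1]))
    if len(entity_names) > spec.n_entities and spec.n_entities != PlantedKGSpec.n_entities:
        raise ValueError(
            f"fanout spec requires {len(entity_names)} entities, cap is {spec.n_entities}"
        )
    return KnowledgeGraph(entity_names, [f"r{j}" for j in range(spec.n_relations)], triplets)


@dataclass
class CascadeFixture:
    """Synthetic logistic data with known generating weights.

    X's first ``dim_F`` columns play the semantic block and the rest the graph
    block; all columns are standard normal (the nonnegativity of real semantic
    residuals is deliberately not emulated — the fixture tests the optimizer,
    not the feature semantics).
    """

    X: np.ndarray
    y: np.ndarray
    theta_true: np.ndarray
    dim_F: int
    dim_G: int

    def feature_set(self) -> FeatureSet:
        return FeatureSet(F=self.X[:, : self.dim_F], G=self.X[:, self.dim_F :], y=self.y)


def make_cascade_fixture(
    n: int,
    dim_F: int,
    dim_G: int,
    theta_true: np.ndarray | None = None,
    seed: int = 0,
) -> CascadeFixture:
    """Draw n logistic samples: X ~ N(0,1), y ~ Bernoulli(σ(θ_trueᵀx))."""
    if n < 10:
        raise ValueError("n must be at least 10")
    rng = np.random.default_rng(seed)
    d = dim_F + dim_G
    if theta_true is None:
        theta_true = rng.standard_normal(d)
    theta_true = np.asarray(theta_true, dtype=float)
    if theta_true.shape != (d,):
        raise ValueError(f"theta_true must have shape ({d},)")
    X = rng.standard_normal((n, d))
    p = 1.0 / (1.0 + np.exp(-(X @ theta_true)))
    y = (rng.random(n) < p).astype(int)
    return CascadeFixture(X=X, y=y, theta_true=theta_true, dim_F=dim_F, dim_G=dim_G)
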