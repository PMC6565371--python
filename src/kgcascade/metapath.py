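"""Greedy meta-path instantiation and path-reliability ranking.

A meta-path is an ordered list of relations (e.g. compound —treated-by⁻¹→
disease —caused-by→ gene). Concrete paths are instantiated by a greedy beam:
at each step the scorer ranks all admissible next entities and the top k are
kept as heads for the following relation. A path's reliability is the product
of its per-step link probabilities and the closing head–tail probability
P(path) = p_R1 · p_R2 · … · p_Rn · p_ht, so extending a path can never make
it more reliable.

Step candidate sets are the entities observed as tails (or heads, when the
step is traversed against its stored direction) of the step's relation
anywhere in the fact set — type compatibility by observed usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kgdata import KnowledgeGraph, Triplet


@dataclass
class MetaPath:
    relations: list[int]
    k: int = 10
    closing_relation: int | None = None
    # per-step flag: traverse the relation from tail to head instead
    inverted: list[bool] | None = None

    def __post_init__(self) -> None:
        if len(self.relations) < 1:
            raise ValueError("meta-path needs at least one relation")
        if self.k < 1:
            raise ValueError("expansion width k must be >= 1")
        if self.inverted is None:
            self.inverted = [False] * len(self.relations)
        if len(self.inverted) != len(self.relations):
            raise ValueError("inverted flags must match the relation list length")


@dataclass
class PathResult:
    entities: list[int]  # h, m_1 … m_{n-1}, t
    step_probs: list[float]
    closing_prob: float
    reliability: float
    novel: bool = True  # False when every constituent triplet is a known fact


def path_probability(step_probs: list[float], closing_prob: float = 1.0) -> float:
    """P(path): product of step link probabilities and the closing probability."""
    vals = list(step_probs) + [closing_prob]
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability {v} outside [0, 1]")
    return float(np.prod(vals))


def _step_triplet(cur: int, relation: int, cand: int, inverted: bool) -> Triplet:
    return Triplet(cand, relation, cur) if inverted else Triplet(cur, relation, cand)


def expand_step(
    scorer,
    heads: list[int],
    relation: int,
    k: int,
    candidates: list[int],
    inverted: bool = False,
) -> dict[int, list[tuple[int, int, float]]]:
    """Top-k (head, tail, probability) continuations per head.

    Ties are broken by candidate entity id ascending; each head's list is
    sorted by probability descending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not candidates:
        raise ValueError("candidate set is empty")
    out: dict[int, list[tuple[int, int, float]]] = {}
    for h in heads:
        triplets = [_step_triplet(h, relation, c, inverted) for c in candidates]
        probs = np.asarray(scorer(triplets), dtype=float)
        order = sorted(range(len(candidates)), key=lambda i: (-probs[i], candidates[i]))
        out[h] = [(h, candidates[i], float(probs[i])) for i in order[:k]]
    return out


def _step_candidates(graph: KnowledgeGraph, relation: int, inverted: bool) -> list[int]:
    ents = set()
    for h, r, t in graph.triplets:
        if r == relation:
            ents.add(h if inverted else t)
    return sorted(ents)


def predict_paths(
    scorer,
    metapath: MetaPath,
    head: int,
    graph: KnowledgeGraph,
    tail: int | None = None,
    top_n: int = 100,
    include_known: bool = False,
) -> list[PathResult]:
    """Greedy beam instantiation of a meta-path from ``head``.

    At each step the top ``metapath.k`` continuations per frontier path are
    kept. When ``tail`` is fixed, the final step is constrained to it. The
    closing probability p_ht scores the direct head-tail link under
    ``metapath.closing_relation`` (1.0 when no closing relation is set).
    Paths whose every constituent triplet — including the closing link — is
    already a known fact are removed unless ``include_known`` is set. Results
    are sorted by reliability descending and truncated to ``top_n``.
    """
    frontier: list[tuple[list[int], list[float]]] = [([head], [])]
    n_steps = len(metapath.relations)
    for i, rel in enumerate(metapath.relations):
        inverted = metapath.inverted[i]
        last_step = i == n_steps - 1
        if last_step and tail is not None:
            candidates = [tail]
        else:
            candidates = _step_candidates(graph, rel, inverted)
        if not candidates:
            return []
        new_frontier: list[tuple[list[int], list[float]]] = []
        heads = sorted({path[-1] for path, _ in frontier})
        expanded = expand_step(scorer, heads, rel, metapath.k, candidates, inverted)
        for path, probs in frontier:
            for _, cand, p in expanded[path[-1]]:
                if cand in path:  # no revisits: simple paths only
                    continue
                new_frontier.append((path + [cand], probs + [p]))
        frontier = new_frontier
        if not frontier:
            return []
    results: list[PathResult] = []
    for path, probs in frontier:
        end = path[-1]
        if metapath.closing_relation is not None:
            closing_t = Triplet(head, metapath.closing_relation, end)
            closing_p = float(np.asarray(scorer([closing_t]), dtype=float)[0])
            closing_known = closing_t in graph.triplets
        else:
            closing_p, closing_known = 1.0, True
        known = closing_known
        for i, rel in enumerate(metapath.relations):
            t = _step_triplet(path[i], rel, path[i + 1], metapath.inverted[i])
            known = known and (t in graph.triplets)
        if known and not include_known:
            continue
        results.append(
            PathResult(
                entities=path,
                step_probs=probs,
                closing_prob=closing_p,
                reliability=path_probability(probs, closing_p),
                novel=not known,
            )
        )
    results.sort(key=lambda r: (-r.reliability, r.entities))
    return results[:top_n]


def write_paths_tsv(results: list[PathResult], graph: KnowledgeGraph, path: str) -> None:
    """One path per row: entities, per-step probabilities, closing prob, reliability."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entities\tstep_probs\tclosing_prob\treliability\n")
        for r in results:
            names = "/".join(graph.entity_names[e] for e in r.entities)
            probs = ",".join(f"{p:.6g}" for p in r.step_probs)
            fh.write(f"{names}\t{probs}\t{r.closing_prob:.6g}\t{r.reliability:.6g}\n")
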