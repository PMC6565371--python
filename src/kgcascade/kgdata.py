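"""Multi-relational triplet data: parsing, indexing, splitting, corruption, statistics.

A knowledge graph here is a directed set of facts ``(head, relation, tail)``
over dense integer ids. Duplicate facts are collapsed on load: the graph is a
set, which is what the negative-sampling filter (membership of a candidate
corruption in the positive set) requires.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import numpy as np


class Triplet(NamedTuple):
    """A directed fact: head entity, relation, tail entity (dense 0-based ids)."""

    head: int
    relation: int
    tail: int


class Side(str, Enum):
    HEAD = "head"
    TAIL = "tail"


@dataclass
class NegativeSample:
    """A corrupted triplet: the source fact with one entity slot replaced."""

    triplet: Triplet
    corrupted_side: Side
    source: Triplet


@dataclass
class ImbalanceLabel:
    """Per-relation fan-out summary and its 1-1 / 1-N / N-1 / N-N class.

    ``n_head`` is the mean number of distinct heads per (relation, tail) pair;
    ``n_tail`` the mean distinct tails per (head, relation) pair. A side is
    labelled N (many) when its mean exceeds 1.5.
    """

    relation: int
    n_head: float
    n_tail: float
    klass: str


IMBALANCE_THRESHOLD = 1.5


class KnowledgeGraph:
    """Directed multi-relational fact set with dictionaries and fan-out indexes."""

    def __init__(
        self,
        entity_names: Sequence[str],
        relation_names: Sequence[str],
        triplets: Iterable[Triplet],
    ) -> None:
        self.entity_names = list(entity_names)
        self.relation_names = list(relation_names)
        self.triplets: set[Triplet] = set(Triplet(*t) for t in triplets)
        for t in self.triplets:
            if not (0 <= t.head < len(self.entity_names)):
                raise ValueError(f"head id {t.head} out of range")
            if not (0 <= t.tail < len(self.entity_names)):
                raise ValueError(f"tail id {t.tail} out of range")
            if not (0 <= t.relation < len(self.relation_names)):
                raise ValueError(f"relation id {t.relation} out of range")
        self._build_indexes()

    def _build_indexes(self) -> None:
        self.index_by_rt: dict[tuple[int, int], set[int]] = defaultdict(set)
        self.index_by_hr: dict[tuple[int, int], set[int]] = defaultdict(set)
        self.degree: Counter[int] = Counter()
        for h, r, t in self.triplets:
            self.index_by_rt[(r, t)].add(h)
            self.index_by_hr[(h, r)].add(t)
            self.degree[h] += 1
            self.degree[t] += 1

    @property
    def n_entities(self) -> int:
        return len(self.entity_names)

    @property
    def n_relations(self) -> int:
        return len(self.relation_names)

    @property
    def n_triplets(self) -> int:
        return len(self.triplets)

    def __contains__(self, t: Triplet) -> bool:
        return Triplet(*t) in self.triplets

    def triplet_array(self) -> np.ndarray:
        """All triplets as an (n, 3) int array in a stable sorted order."""
        if not self.triplets:
            return np.empty((0, 3), dtype=np.int64)
        return np.array(sorted(self.triplets), dtype=np.int64)


def load_triplets(path, *, sep: str = "\t") -> KnowledgeGraph:
    """Parse a ``head<TAB>relation<TAB>tail`` file into a KnowledgeGraph.

    Entity and relation ids are assigned in first-appearance order; duplicate
    lines are dropped. An empty file yields an empty graph. A line without
    exactly three fields raises ``ValueError`` naming the line number.
    """
    entities: dict[str, int] = {}
    relations: dict[str, int] = {}
    triplets: list[Triplet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 fields separated by {sep!r}, "
                    f"got {len(parts)}"
                )
            h, r, t = parts
            hid = entities.setdefault(h, len(entities))
            rid = relations.setdefault(r, len(relations))
            tid = entities.setdefault(t, len(entities))
            triplets.append(Triplet(hid, rid, tid))
    return KnowledgeGraph(list(entities), list(relations), triplets)


def write_triplets(graph: KnowledgeGraph, path, *, sep: str = "\t") -> None:
    """Write the graph back out in the same TSV dialect (sorted id order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h, r, t in sorted(graph.triplets):
            fh.write(
                f"{graph.entity_names[h]}{sep}"
                f"{graph.relation_names[r]}{sep}"
                f"{graph.entity_names[t]}\n"
            )


def write_dictionary(names: Sequence[str], path) -> None:
    """Persist an id -> name dictionary as 2-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, name in enumerate(names):
            fh.write(f"{i}\t{name}\n")


def split_train_test(
    graph: KnowledgeGraph,
    test_size: int,
    seed: int,
    *,
    stratify_by_relation: bool = False,
) -> tuple[KnowledgeGraph, list[Triplet]]:
    """Partition the fact set into a training graph and held-out test triplets.

    With ``stratify_by_relation`` the test set is allocated proportionally to
    per-relation triplet counts (every relation with enough facts is covered);
    otherwise sampling is uniform over the whole fact set.
    """
    if not 0 <= test_size <= graph.n_triplets:
        raise ValueError(
            f"test_size {test_size} out of range [0, {graph.n_triplets}]"
        )
    rng = np.random.default_rng(seed)
    all_triplets = [Triplet(*row) for row in graph.triplet_array()]
    if stratify_by_relation and test_size > 0:
        by_rel: dict[int, list[Triplet]] = defaultdict(list)
        for t in all_triplets:
            by_rel[t.relation].append(t)
        counts = {r: len(ts) for r, ts in by_rel.items()}
        total = graph.n_triplets
        quota = {r: int(round(test_size * c / total)) for r, c in counts.items()}
        # ensure at least one test triplet per relation when affordable
        for r in quota:
            if quota[r] == 0 and counts[r] > 1 and test_size >= len(quota):
                quota[r] = 1
        # fix rounding drift
        drift = test_size - sum(quota.values())
        rel_order = sorted(quota, key=lambda r: -counts[r])
        i = 0
        while drift != 0 and rel_order:
            r = rel_order[i % len(rel_order)]
            step = 1 if drift > 0 else -1
            if 0 <= quota[r] + step <= counts[r]:
                quota[r] += step
                drift -= step
            i += 1
        test: list[Triplet] = []
        for r in sorted(by_rel):
            idx = rng.choice(counts[r], size=quota[r], replace=False)
            test.extend(by_rel[r][j] for j in sorted(idx))
    else:
        idx = rng.choice(graph.n_triplets, size=test_size, replace=False)
        chosen = set(int(j) for j in idx)
        test = [t for j, t in enumerate(all_triplets) if j in chosen]
    test_set = set(test)
    train = [t for t in all_triplets if t not in test_set]
    train_graph = KnowledgeGraph(graph.entity_names, graph.relation_names, train)
    return train_graph, test


def corrupt_triplet(
    t: Triplet,
    graph: KnowledgeGraph,
    rng: np.random.Generator,
    side: Side | None = None,
    *,
    max_tries: int = 1000,
) -> NegativeSample:
    """Corrupt one side of a positive triplet into a presumed-false one.

    Replaces the head or the tail (chosen uniformly when ``side`` is None) with
    a random entity, rejecting candidates that are known positives, until a
    valid corruption is found. Raises ``RuntimeError`` when every candidate on
    the chosen side is a known positive (or the entity set is trivially small).
    """
    t = Triplet(*t)
    n = graph.n_entities
    if n < 2:
        raise RuntimeError("cannot corrupt: fewer than 2 entities")
    chosen = side if side is not None else (Side.HEAD if rng.random() < 0.5 else Side.TAIL)
    for _ in range(max_tries):
        e = int(rng.integers(n))
        if chosen is Side.HEAD:
            cand = Triplet(e, t.relation, t.tail)
            if e != t.head and cand not in graph.triplets:
                return NegativeSample(cand, chosen, t)
        else:
            cand = Triplet(t.head, t.relation, e)
            if e != t.tail and cand not in graph.triplets:
                return NegativeSample(cand, chosen, t)
    # rejection sampling exhausted: fall back to exhaustive scan
    for e in range(n):
        if chosen is Side.HEAD:
            cand = Triplet(e, t.relation, t.tail)
            if e != t.head and cand not in graph.triplets:
                return NegativeSample(cand, chosen, t)
        else:
            cand = Triplet(t.head, t.relation, e)
            if e != t.tail and cand not in graph.triplets:
                return NegativeSample(cand, chosen, t)
    raise RuntimeError(
        f"corruption exhausted: every {chosen.value} replacement of {t} is a known positive"
    )


def relation_stats(graph: KnowledgeGraph) -> dict[int, dict]:
    """Per-relation triplet counts and distinct head/tail entity counts."""
    stats: dict[int, dict] = {
        r: {"name": graph.relation_names[r], "n_triplets": 0, "heads": set(), "tails": set()}
        for r in range(graph.n_relations)
    }
    for h, r, t in graph.triplets:
        stats[r]["n_triplets"] += 1
        stats[r]["heads"].add(h)
        stats[r]["tails"].add(t)
    for r in stats:
        stats[r]["n_heads"] = len(stats[r].pop("heads"))
        stats[r]["n_tails"] = len(stats[r].pop("tails"))
    return stats


def degree_distribution(graph: KnowledgeGraph) -> tuple[dict[int, int], float]:
    """Histogram of total node degree (in + out) and the mean degree 2|Δ|/|V|."""
    hist = Counter(graph.degree[e] for e in range(graph.n_entities))
    mean = 2 * graph.n_triplets / graph.n_entities if graph.n_entities else 0.0
    return dict(hist), mean


def imbalance_labels(graph: KnowledgeGraph) -> list[ImbalanceLabel]:
    """Classify each relation as 1-1 / 1-N / N-1 / N-N by mean fan-out.

    ``n_head(r) = |Δ_r| / #distinct tails`` and symmetrically for tails;
    a side is N when its mean exceeds 1.5, following the translation-model
    convention for diagnosing relation imbalance.
    """
    stats = relation_stats(graph)
    labels = []
    for r in sorted(stats):
        s = stats[r]
        if s["n_triplets"] == 0:
            continue
        n_head = s["n_triplets"] / s["n_tails"]
        n_tail = s["n_triplets"] / s["n_heads"]
        head_k = "N" if n_head > IMBALANCE_THRESHOLD else "1"
        tail_k = "N" if n_tail > IMBALANCE_THRESHOLD else "1"
        labels.append(
            ImbalanceLabel(relation=r, n_head=n_head, n_tail=n_tail, klass=f"{head_k}-{tail_k}")
        )
    return labels
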