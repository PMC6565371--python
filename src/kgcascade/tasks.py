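"""Evaluation tasks: link classification, filtered entity ranking, ROC.

Link classification follows the per-relation threshold protocol: a decision
cut δ_r is fitted for every relation by maximizing 0/1 accuracy on training
scores, then applied to held-out positives and an equal number of sampled
corruptions. Entity ranking replaces the head (or tail) of a query triplet
with every entity, scores all candidates, and reports the rank of the true
entity; in the *filtered* setting candidates that form other known-true
triplets are removed first so they cannot unfairly outrank the query.

Scorers are callables mapping a list of triplets to scores. Both score
orientations flow through the same machinery: "higher" for probabilities
(cascade output) and "lower" for translation distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skmetrics

from .kgdata import KnowledgeGraph, Side, Triplet, corrupt_triplet

ORIENTATIONS = ("higher", "lower")


@dataclass
class RelationThresholds:
    delta: dict[int, float]
    orientation: str  # "higher": score > δ is positive; "lower": score < δ
    train_accuracy: dict[int, float] = field(default_factory=dict)


@dataclass
class RankingResult:
    ranks: list[int]
    mean_rank: float
    hits_at_10: float
    per_relation: dict[int, dict] = field(default_factory=dict)
    filtered: bool = True


def _classify(scores: np.ndarray, delta: float, orientation: str) -> np.ndarray:
    if orientation == "higher":
        return (scores > delta).astype(int)
    return (scores < delta).astype(int)


def fit_relation_thresholds(
    scores: np.ndarray,
    labels: np.ndarray,
    relations: np.ndarray,
    orientation: str = "higher",
) -> RelationThresholds:
    """Per-relation accuracy-maximizing cut points.

    Candidate cuts are the midpoints of adjacent sorted unique scores plus
    ±inf; ties are broken toward the smaller threshold. A relation with only
    one label present gets an all-accepting/all-rejecting cut at ±inf with a
    warning.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    relations = np.asarray(relations, dtype=int)
    delta: dict[int, float] = {}
    train_acc: dict[int, float] = {}
    for r in sorted(set(relations.tolist())):
        sel = relations == r
        s, y = scores[sel], labels[sel]
        if len(np.unique(y)) < 2:
            warnings.warn(
                f"relation {r} has a single class; threshold set at ±inf",
                stacklevel=2,
            )
            if y[0] == 1:
                delta[r] = -np.inf if orientation == "higher" else np.inf
            else:
                delta[r] = np.inf if orientation == "higher" else -np.inf
            train_acc[r] = 1.0
            continue
        uniq = np.unique(s)
        cands = np.concatenate(
            [[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]]
        )
        best_acc, best_cut = -1.0, None
        for cut in cands:  # ascending, so first max is the smallest cut
            acc = float((_classify(s, cut, orientation) == y).mean())
            if acc > best_acc:
                best_acc, best_cut = acc, cut
        delta[r] = float(best_cut)
        train_acc[r] = best_acc
    return RelationThresholds(delta=delta, orientation=orientation, train_accuracy=train_acc)


def evaluate_link_accuracy(
    scorer,
    test_pos: list[Triplet],
    graph: KnowledgeGraph,
    thresholds: RelationThresholds,
    rng: np.random.Generator,
) -> dict:
    """Binary triplet classification on held-out positives plus corruptions.

    One negative per positive, generated by head/tail replacement filtered
    against the graph's known positives. Returns per-relation accuracy and the
    macro average over relations present in the test set.
    """
    triplets: list[Triplet] = []
    labels: list[int] = []
    for pos in test_pos:
        pos = Triplet(*pos)
        if pos.relation not in thresholds.delta:
            raise KeyError(f"relation {pos.relation} missing from thresholds")
        triplets.append(pos)
        labels.append(1)
        triplets.append(corrupt_triplet(pos, graph, rng).triplet)
        labels.append(0)
    scores = np.asarray(scorer(triplets), dtype=float)
    labels_arr = np.asarray(labels)
    rels = np.array([t.relation for t in triplets])
    per_relation: dict[int, dict] = {}
    for r in sorted(set(rels.tolist())):
        sel = rels == r
        pred = _classify(scores[sel], thresholds.delta[r], thresholds.orientation)
        per_relation[r] = {
            "accuracy": float((pred == labels_arr[sel]).mean()),
            "n": int(sel.sum()),
        }
    macro = float(np.mean([v["accuracy"] for v in per_relation.values()]))
    micro_correct = sum(
        v["accuracy"] * v["n"] for v in per_relation.values()
    )
    return {
        "per_relation": per_relation,
        "macro_accuracy": macro,
        "micro_accuracy": float(micro_correct / len(triplets)),
        "n_examples": len(triplets),
    }


def rank_candidates(
    scorer,
    query: Triplet,
    side: Side,
    graph_all: KnowledgeGraph,
    filtered: bool = True,
    orientation: str = "higher",
) -> int:
    """Rank of the true entity when the query's head/tail is replaced by all.

    rank = 1 + number of candidates scoring strictly better than the query
    (optimistic tie handling). With ``filtered`` set, candidates forming known
    positives other than the query are removed; the true candidate itself is
    always retained.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    query = Triplet(*query)
    cands: list[Triplet] = []
    for e in range(graph_all.n_entities):
        if side is Side.HEAD:
            c = Triplet(e, query.relation, query.tail)
        else:
            c = Triplet(query.head, query.relation, e)
        if c == query:
            cands.append(c)
        elif filtered and c in graph_all.triplets:
            continue
        else:
            cands.append(c)
    scores = np.asarray(scorer(cands), dtype=float)
    q_idx = cands.index(query)
    q_score = scores[q_idx]
    if orientation == "higher":
        better = int((scores > q_score).sum())
    else:
        better = int((scores < q_score).sum())
    return 1 + better


def ranking_metrics(
    ranks: list[int], relations: list[int] | None = None, filtered: bool = True
) -> RankingResult:
    """Mean rank and hits@10 over a list of query ranks."""
    if not ranks:
        raise ValueError("ranking_metrics requires at least one rank")
    arr = np.asarray(ranks, dtype=float)
    if (arr < 1).any():
        raise ValueError("ranks must be >= 1")
    per_relation: dict[int, dict] = {}
    if relations is not None:
        rels = np.asarray(relations)
        for r in sorted(set(rels.tolist())):
            sel = rels == r
            per_relation[int(r)] = {
                "mean_rank": float(arr[sel].mean()),
                "hits_at_10": float((arr[sel] <= 10).mean()),
                "n": int(sel.sum()),
            }
    return RankingResult(
        ranks=list(int(x) for x in ranks),
        mean_rank=float(arr.mean()),
        hits_at_10=float((arr <= 10).mean()),
        per_relation=per_relation,
        filtered=filtered,
    )


def crossfit_calibrated_scorer(
    train_graph: KnowledgeGraph,
    scorer_factory,
    n_folds: int,
    seed: int,
    orientation: str = "lower",
    neg_per_pos: int = 3,
    corrupt_filter_graph: KnowledgeGraph | None = None,
):
    """Cross-fitted threshold calibration for embedding-based link classifiers.

    An embedding trained on a small fact set memorizes it: its own training
    triplets score far better than held-out true triplets, so a decision
    threshold maximized on in-sample scores does not transfer. This helper
    splits the training facts into ``n_folds`` folds, trains one scorer per
    fold on the complement (``scorer_factory(fold_graph)`` → triplet scorer),
    scores each fold's positives and corruptions *out of fold*, fits the
    per-relation thresholds on those unbiased scores, and returns the
    fold-ensemble scorer (mean of fold scores) together with the thresholds.

    At full data scale in-sample fitting is unproblematic and cheaper; this
    protocol exists for small-sample regimes.
    """
    rng = np.random.default_rng(seed)
    all_train = [Triplet(*row) for row in train_graph.triplet_array()]
    folds = np.array_split(rng.permutation(len(all_train)), n_folds)
    filt = corrupt_filter_graph if corrupt_filter_graph is not None else train_graph
    scorers = []
    oof_triplets: list[Triplet] = []
    oof_labels: list[int] = []
    oof_scores: list[np.ndarray] = []
    for fold_idx in folds:
        held = set(int(i) for i in fold_idx)
        hold = [all_train[i] for i in sorted(held)]
        keep = [t for i, t in enumerate(all_train) if i not in held]
        fold_graph = KnowledgeGraph(
            train_graph.entity_names, train_graph.relation_names, keep
        )
        sc = scorer_factory(fold_graph)
        scorers.append(sc)
        # replicate positives to keep the fitting set balanced at 1:1
        pos = [t for t in hold for _ in range(neg_per_pos)]
        neg = [corrupt_triplet(t, filt, rng).triplet for t in pos]
        ts = pos + neg
        oof_triplets += ts
        oof_labels += [1] * len(pos) + [0] * len(neg)
        oof_scores.append(np.asarray(sc(ts), dtype=float))
    thresholds = fit_relation_thresholds(
        np.concatenate(oof_scores),
        np.asarray(oof_labels),
        np.array([t.relation for t in oof_triplets]),
        orientation=orientation,
    )

    def ensemble(triplets) -> np.ndarray:
        return np.mean([np.asarray(s(triplets), dtype=float) for s in scorers], axis=0)

    return ensemble, thresholds


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-sweep ROC points and trapezoidal AUC (higher = positive)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC undefined: only one class present")
    fpr, tpr, _ = _skmetrics.roc_curve(labels, np.asarray(scores, dtype=float))
    return fpr, tpr, float(_skmetrics.auc(fpr, tpr))
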