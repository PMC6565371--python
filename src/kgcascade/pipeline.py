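"""End-to-end orchestration: data → embeddings → cascade → evaluation.

``run_pipeline`` wires the stages together: split the fact set, train the
translation embedding and the walk embedding on the training graph, build
[F, G] features with sampled corruptions, fit the logistic cascade, fit
per-relation decision thresholds on the training scores, then evaluate link
classification and filtered entity ranking on the held-out triplets. A single
global seed fans out to per-stage seeds through a fixed derivation so any
stage can be rerun in isolation and the whole report is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import tasks
from .cascade import build_feature_set, predict_proba, train_cascade, triplet_scorer
from .kgdata import (
    KnowledgeGraph,
    Side,
    Triplet,
    corrupt_triplet,
    load_triplets,
    split_train_test,
)
from .transx import TransXConfig, train_transx
from .walker import WalkConfig, generate_walks, homogenize, train_node_embedding


def crossfit_cascade_scorers(
    graph: KnowledgeGraph,
    train_graph: KnowledgeGraph,
    transx_cfg: TransXConfig,
    walk_cfg: WalkConfig,
    plans: tuple[str, ...] = ("two-stage",),
    n_folds: int = 5,
    seed: int = 0,
    alpha_reg: float = 1.0,
    neg_ratio: float = 1.0,
    neg_per_pos: int = 3,
) -> dict[str, tuple]:
    """Cross-fitted cascade scorers and thresholds for one or more feature plans.

    Embeddings trained on few facts memorize them, so probabilities and
    thresholds fitted in-sample do not transfer to held-out triplets. This
    helper trains the whole stack (translation embedding, walk embedding,
    cascade) on each of ``n_folds`` fold complements, scores each fold's
    positives and corruptions out of fold, fits per-relation thresholds on
    those unbiased scores, and returns per plan the fold-ensemble scorer
    (mean probability) with its thresholds. Fold models are shared across
    plans so ablations compare classifiers, not embeddings.
    """
    all_train = [Triplet(*row) for row in train_graph.triplet_array()]
    folds = np.array_split(
        np.random.default_rng(seed + 200).permutation(len(all_train)), n_folds
    )
    rng = np.random.default_rng(seed + 300)
    plan_scorers: dict[str, list] = {p: [] for p in plans}
    oof: dict[str, tuple[list, list, list]] = {p: ([], [], []) for p in plans}
    for k, fidx in enumerate(folds):
        held = set(int(i) for i in fidx)
        hold = [all_train[i] for i in sorted(held)]
        keep = [t for i, t in enumerate(all_train) if i not in held]
        fold_graph = KnowledgeGraph(
            graph.entity_names, graph.relation_names, keep
        )
        kcfg = dataclasses.replace(transx_cfg, seed=transx_cfg.seed + 50 * k)
        km = train_transx(fold_graph, kcfg)
        wcfg = dataclasses.replace(walk_cfg, seed=walk_cfg.seed + 50 * k)
        nemb = train_node_embedding(
            generate_walks(homogenize(fold_graph), wcfg), wcfg,
            n_nodes=graph.n_entities,
        )
        feats = build_feature_set(
            km, nemb, keep, fold_graph, neg_ratio, np.random.default_rng(seed + 2 + k)
        )
        pos = [t for t in hold for _ in range(neg_per_pos)]
        neg = [corrupt_triplet(t, train_graph, rng).triplet for t in pos]
        ts = pos + neg
        ys = [1] * len(pos) + [0] * len(neg)
        for plan in plans:
            cm = train_cascade(feats, alpha_reg=alpha_reg, plan=plan)
            sc = triplet_scorer(km, nemb, cm)
            plan_scorers[plan].append(sc)
            o = oof[plan]
            o[0].extend(ts)
            o[1].extend(ys)
            o[2].append(np.asarray(sc(ts), dtype=float))
    out: dict[str, tuple] = {}
    for plan in plans:
        ts, ys, ss = oof[plan]
        th = tasks.fit_relation_thresholds(
            np.concatenate(ss), np.asarray(ys),
            np.array([t.relation for t in ts]), orientation="higher",
        )

        def ensemble(triplets, _p=plan):
            return np.mean(
                [np.asarray(s(triplets), dtype=float) for s in plan_scorers[_p]],
                axis=0,
            )

        out[plan] = (ensemble, th)
    return out


@dataclass
class RunConfig:
    triples_path: str | None = None
    out_dir: str | None = None
    test_size: int = 20
    stratify_by_relation: bool = False
    transx: TransXConfig = field(default_factory=TransXConfig)
    walk: WalkConfig = field(default_factory=WalkConfig)
    neg_ratio: float = 1.0
    alpha_reg: float = 1.0
    feature_plan: str = "two-stage"
    filtered: bool = True
    orientation: str = "higher"
    max_rank_queries: int | None = None
    seed: int = 0


_TOP_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str) -> RunConfig:
    """Parse a JSON run config; unspecified fields keep their defaults.

    ``transx`` and ``walk`` may be nested objects overriding individual
    hyper-parameters. Unknown keys raise with the list of valid ones.
    """
    with open(path) as fh:
        raw = json.load(fh)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_TOP_KEYS)}"
        )
    transx_kwargs = raw.pop("transx", {})
    walk_kwargs = raw.pop("walk", {})
    for sub, cls in ((transx_kwargs, TransXConfig), (walk_kwargs, WalkConfig)):
        bad = set(sub) - {f.name for f in dataclasses.fields(cls)}
        if bad:
            raise ValueError(
                f"unknown {cls.__name__} keys {sorted(bad)}; "
                f"valid: {sorted(f.name for f in dataclasses.fields(cls))}"
            )
    return RunConfig(
        transx=TransXConfig(**transx_kwargs), walk=WalkConfig(**walk_kwargs), **raw
    )


def derive_seeds(seed: int, n: int = 6) -> list[int]:
    """Fan a single global seed out to independent per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def run_pipeline(config: RunConfig, graph: KnowledgeGraph | None = None) -> dict:
    """Execute the full cascade pipeline; returns the metrics report.

    Either ``graph`` or ``config.triples_path`` must be provided. The report
    carries per-relation link accuracy, mean rank, hits@10, and the seeds and
    sub-configs needed to reproduce it.
    """
    if graph is None:
        if config.triples_path is None:
            raise ValueError("either a graph or config.triples_path is required")
        graph = load_triplets(config.triples_path)
    s_split, s_feat, s_neg, s_rankpick, s_tx, s_walk = derive_seeds(config.seed)
    transx_cfg = dataclasses.replace(config.transx, seed=s_tx)
    walk_cfg = dataclasses.replace(config.walk, seed=s_walk)

    train_graph, test = split_train_test(
        graph, config.test_size, s_split, stratify_by_relation=config.stratify_by_relation
    )

    kmodel = train_transx(train_graph, transx_cfg)
    adj = homogenize(train_graph)
    corpus = generate_walks(adj, walk_cfg)
    nemb = train_node_embedding(corpus, walk_cfg, n_nodes=graph.n_entities)

    train_pos = [t for t in train_graph.triplets]
    train_pos.sort()
    feats = build_feature_set(
        kmodel, nemb, train_pos, train_graph, config.neg_ratio,
        np.random.default_rng(s_feat),
    )
    cmodel = train_cascade(feats, alpha_reg=config.alpha_reg, plan=config.feature_plan)
    scorer = triplet_scorer(kmodel, nemb, cmodel)

    train_scores = predict_proba(cmodel, feats.F, feats.G)
    rels = np.array([t.relation for t in feats.triplets])
    thresholds = tasks.fit_relation_thresholds(
        train_scores, feats.y, rels, orientation=config.orientation
    )

    link = tasks.evaluate_link_accuracy(
        scorer, test, graph, thresholds, np.random.default_rng(s_neg)
    )

    queries = list(test)
    if config.max_rank_queries is not None and len(queries) > config.max_rank_queries:
        pick = np.random.default_rng(s_rankpick).choice(
            len(queries), size=config.max_rank_queries, replace=False
        )
        queries = [queries[i] for i in sorted(pick)]
    ranks, rank_rels = [], []
    for q in queries:
        for side in (Side.HEAD, Side.TAIL):
            ranks.append(
                tasks.rank_candidates(
                    scorer, q, side, graph,
                    filtered=config.filtered, orientation=config.orientation,
                )
            )
            rank_rels.append(q.relation)
    ranking = tasks.ranking_metrics(ranks, rank_rels, filtered=config.filtered)

    report = {
        "n_entities": graph.n_entities,
        "n_relations": graph.n_relations,
        "n_triplets": graph.n_triplets,
        "test_size": len(test),
        "feature_plan": config.feature_plan,
        "seeds": {
            "global": config.seed, "split": s_split, "features": s_feat,
            "negatives": s_neg, "transx": s_tx, "walk": s_walk,
        },
        "link": link,
        "ranking": {
            "mean_rank": ranking.mean_rank,
            "hits_at_10": ranking.hits_at_10,
            "per_relation": ranking.per_relation,
            "filtered": ranking.filtered,
            "n_queries": len(ranking.ranks),
        },
    }
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        kmodel.save(os.path.join(config.out_dir, "transx_model"))
        cmodel.save(os.path.join(config.out_dir, "cascade.json"))
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    return report
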