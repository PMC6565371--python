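# kgcascade

Knowledge-and-graph-embedding cascade for link, entity, and path prediction
in multi-relational biomedical networks.

Biochemical knowledge bases such as Chem2Bio2RDF store facts as directed
triplets *(head, relation, tail)* — a compound *binds* a gene, a disease is
*treated by* a compound. Predicting missing links in these graphs is hard for
translation-based knowledge embeddings alone, because biomedical networks are
sparse (most entities have a handful of facts) and extremely imbalanced (a
single gene may bind a hundred compounds). `kgcascade` implements a cascade
framework that fuses two complementary signals:

* **Translation embedding** (TransE / TranSparse): entities and relations are
  embedded so that a true fact satisfies *h + r ≈ t*; a triplet's
  dissimilarity is *d(h, r, t) = ‖h_p + r − t_p‖* (L1 or L2), where
  TranSparse first projects the entities through per-relation sparse
  matrices whose sparse degree adapts to each relation's fan-out. The
  per-triplet **semantic feature** is the residual *F(h, t) = |h_r + r − t_r|*.
* **Biased random-walk embedding** (node2vec-style): the graph is collapsed
  to an undirected homogeneous network and explored with second-order walks
  controlled by the return parameter *p* and in–out parameter *q*; a
  skip-gram model with negative sampling turns walk contexts into node
  vectors. The **graph feature** is the hadamard product
  *G(h, t) = u(h) ∗ u(t)*.
* **Two-stage logistic cascade**: stage one classifies on *G* alone; stage
  two classifies on *F* concatenated with stage one's probability, each stage
  minimizing an L2-regularized negative log-likelihood. The final-stage
  probability drives three tasks: per-relation thresholded link
  classification, filtered entity ranking (mean rank / hits@10), and greedy
  meta-path instantiation where a path's reliability is
  *P(path) = p_R1 · p_R2 · … · p_Rn · p_ht*.

A deterministic synthetic-data module generates planted translation graphs
(optionally with community structure), fan-out-controlled imbalanced graphs,
and logistic fixtures with known weights, so the whole pipeline is testable
without any external download.

## Worked example

Train the full pipeline on a 50-entity planted graph with community
structure, holding out 20 facts:

```python
import json
from kgcascade import (PlantedKGSpec, RunConfig, TransXConfig, WalkConfig,
                       make_translation_kg, run_pipeline, write_triplets)

graph, _ = make_translation_kg(PlantedKGSpec(n_clusters=5, seed=7))
write_triplets(graph, "example_triples.tsv")
config = RunConfig(
    triples_path="example_triples.tsv",
    test_size=20,
    transx=TransXConfig(model="transe", dim_entity=8, dim_relation=8,
                        margin=0.25, learn_rate=0.05, epochs=300,
                        norm="L2", batch_size=1),
    walk=WalkConfig(dim=16, walk_length=40, walks_per_node=10, context_size=5),
    seed=42,
)
report = run_pipeline(config)
print(json.dumps({
    "triplets": report["n_triplets"],
    "link_accuracy_macro": round(report["link"]["macro_accuracy"], 3),
    "mean_rank": report["ranking"]["mean_rank"],
    "hits_at_10": report["ranking"]["hits_at_10"],
}, indent=2))
```

prints

```json
{
  "triplets": 200,
  "link_accuracy_macro": 0.788,
  "mean_rank": 4.2,
  "hits_at_10": 1.0
}
```

Every held-out fact ranks in the top 10 of its 50-candidate filtered list
(hits@10 = 1.0, mean rank 4.2), and thresholded link classification reaches
~0.79 macro accuracy over the two relations — the in-sample thresholds
transfer imperfectly at this scale; see `docs/methods.md` for the
cross-fitted calibration that closes the gap.

The same flow is available from the shell:

```bash
kgc synth translation --seed 7 --out work/
kgc stats work/triples.tsv
kgc run --triples work/triples.tsv --seed 42
```

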