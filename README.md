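# neurodict

A neural dictionary for recognizing biomedical ontology concepts in text.

Clinical and research text is full of synonyms and non-standard phrasings:
an ontology such as the Human Phenotype Ontology or SNOMED-CT lists "Renal
neoplasm" with a few curated synonyms, but a report may say "renal cancer",
which appears nowhere in the ontology.  Rule-based dictionary annotators miss
such mentions; ordinary supervised NER cannot cope with tens of thousands of
classes that have almost no labeled examples.  `neurodict` takes the middle
road: it trains a classifier *on the ontology itself* — every name and
synonym is a training example for its concept — and generalizes to unseen
synonyms through pretrained word-vector geometry.  It is aimed at people
building phenotyping and concept-normalization pipelines over clinical notes
and biomedical literature.

## The model

A phrase of T tokens with word vectors x⁽¹⁾…x⁽ᵀ⁾ is encoded by a width-one
convolution, max-over-time pooling, and a normalized dense layer:

    v = max_t ELU(W x⁽ᵗ⁾ + b)
    e = ReLU(U v) / ‖ReLU(U v)‖₂

Each concept c has a learnable raw embedding H̄_c; the embedding actually
scored is composed along the taxonomy, H = A·H̄, where the sparse ancestry
matrix A gives concept i a unit weight on itself plus the (parent-averaged)
weights of all its ancestors — a child inherits its parents' position in
embedding space and learns only its local offset.  Classification is

    p = softmax(H·e + bias)

with a dummy NONE row trained on random n-grams from unrelated text so that
non-mentions can be rejected.  Longer documents are annotated by scoring all
within-sentence n-grams of 1–7 tokens, dropping candidates below a
validation-selected threshold, and resolving overlaps (same concept → keep
the smaller span; different concepts → keep the longer, more specific one).
Ensembles of seed-varied trainings average their predicted probabilities.
Evaluation covers micro/macro precision/recall/F1, ancestor-extended
variants with the Jaccard index, and R@k for isolated-phrase ranking.
See `docs/methods.md` for the full account.

## Worked example

The classic overlap case: a taxonomy contains "heart defect" and its child
"conotruncal heart defect", and both match inside one sentence.  The library
trains a small ensemble, picks the threshold on a tiny validation set, and
keeps only the longer, more specific mention:

```python
from neurodict.annotate import annotate_text
from neurodict.demo import DEMO_SENTENCE, demo_threshold, train_demo_ensemble

models = train_demo_ensemble(seed=0)
threshold = demo_threshold(models)
for a in annotate_text(models, DEMO_SENTENCE, threshold):
    print(a.doc_id, a.start, a.end, repr(a.text), a.concept, round(a.score, 3))
```

prints

```
doc 31 55 'conotruncal heart defect' DEMO:0000003 0.909
```

one annotation covering characters 31–55 of "The patient was diagnosed with
conotruncal heart defect": the three-token span, matched to the child concept
with ensemble probability 0.91.  The embedded "heart defect" span, which on
its own matches the parent concept, is correctly suppressed.

The same pipeline is available from the shell.  `neurodict fixtures` emits a
synthetic workspace (OBO ontology, word2vec-format vectors, negative corpus,
documents with gold labels); `train` fits a seed-varied ensemble and writes
`.npz` checkpoints plus a training log; `rank` prints the top-k concepts for
a phrase; `annotate` writes a TSV of non-overlapping mentions; `evaluate`
scores it against gold; `subset` extracts an ancestor-closed sub-ontology.

```
$ neurodict fixtures --out ws --seed 5 --n-concepts 10 --n-docs 4
$ neurodict train --ontology ws/ontology.obo --word-vectors ws/vectors.txt \
    --negatives ws/negatives.txt --variant NCR --concept-dim 32 \
    --conv-filters 32 --epochs 150 --batch-size 16 --ensemble-size 1 \
    --seed 0 --out ckpt
$ neurodict rank --checkpoint ckpt/model_seed0.npz --ontology ws/ontology.obo \
    -k 3 "t005b t000b"
rank	concept_id	name	score
1	TOY:0000005	t005a t000a	0.786529
2	TOY:0000000	t000a	0.084520
3	TOY:0000002	t002a t000a	0.029519
```

The queried phrase "t005b t000b" is a synonym of concept TOY:0000005 (name
"t005a t000a"): the model ranks that concept first with softmax probability
0.79, followed by its taxonomic ancestors.

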