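# Methods

## The model

`neurodict` implements a *neural dictionary*: a classifier that, given a word
or short phrase, produces a probability distribution over the concepts of a
biomedical ontology (HPO- or SNOMED-CT-style: concepts with a canonical name,
optional synonyms, and `is_a` taxonomic edges).  It is trained only on the
ontology's own names and synonyms (plus unlabeled negative text), never on an
annotated corpus, which is what makes it applicable to ontologies with tens of
thousands of classes and almost no labeled mentions per class.

### Phrase encoder

A phrase of T tokens is represented by pretrained word vectors
x⁽¹⁾…x⁽ᵀ⁾ ∈ R^d (d = 100 for the published setting; the vectors are a frozen
preprocessing product, e.g. fastText trained on MEDLINE abstracts).  The
encoder is a single convolution with filter width one followed by
max-over-time pooling:

    v = max_t ELU(W x⁽ᵗ⁾ + b),        W ∈ R^{F×d}, b ∈ R^F

where the max is elementwise over tokens, and a dense layer with ReLU and l2
normalization:

    e = ReLU(U v) / ‖ReLU(U v)‖₂,     U ∈ R^{c×F}

A width-one filter discards word order; the pooled representation is a set
summary of the tokens.  This is deliberate — with so little training data per
concept, order-sensitive encoders (LSTMs, attention) have too many parameters
to learn — and the package asserts the resulting exact order invariance as a
contract.  ELU uses α = 1.  The l2 normalization denominator is guarded by
ε = 1e−12: if every ReLU output is zero (reachable early in training), the
phrase maps to the zero vector rather than raising.

### Taxonomy-composed concept embeddings

Each concept c has a learnable *raw* embedding (the row of H̄), understood as
the features of c that are novel relative to its ancestors.  The embedding
actually scored, its *final* embedding, is composed through the taxonomy: a
concept's final embedding is its parent's final embedding (the average over
parents under multiple inheritance) plus its own raw row.  Unrolled, this is
a linear map H = A·H̄ with the sparse *ancestry matrix* A:

    row(i) = unit(i)                                    if i is a root
    row(i) = unit(i) + (1/|par(i)|) Σ_{p∈par(i)} row(p)  otherwise

so A[i,j] ≠ 0 only when j is an ancestor of i or j = i, A[i,i] = 1, and in a
tree the row of a depth-d node sums to d+1.  When a diamond makes an ancestor
reachable along several paths its coefficients accumulate additively (the
recursion implies it; coefficients are not capped at 1).  A is built in
topological order and stored sparsely (CSR); it is evaluated against an
independent memoized recursive oracle in the tests.

Scores are softmax(H·e + bias) with a per-concept bias (the standard
softmax-classifier reading).  Setting A = I recovers an ordinary flat softmax
classifier; the package exposes this as the hierarchy ablation and verifies
by finite differences that the embedding-table gradient then equals a flat
classifier's.

### The NONE class and negative sampling

To reject phrases that match no concept, one extra row of H̄ — a dummy NONE
class with no taxonomy parents (identity-composed) and its own bias — joins
the softmax.  Its training examples are random n-grams from an unrelated
corpus, with lengths uniform on {1..10} (phrases longer than 10 tokens are
assumed not to be mentions) and uniform start positions.

### Training

One training example per distinct (name-or-synonym string, concept) pair,
tokenized like documents.  Cross-entropy is minimized with Adam
(lr 0.002, β₁ = 0.9, β₂ = 0.999, ε = 1e−8), batch size 256, 100 epochs in the
published configuration; examples are reshuffled across minibatches every
epoch and the last partial batch is kept.  Word vectors stay frozen; the
learned parameters are W, b, U, H̄ and the bias.  Negatives are sampled once
before training (ratio 1:1 to positives by default; both the ratio and
per-epoch resampling are configurable).  No early stopping, weight decay or
dropout.  Initialization is Glorot-uniform for W, U and H̄ with zero biases.
Everything is float64 NumPy, so a fixed (config, plan, data) triple produces
a bitwise-identical checkpoint; ensembles vary only the seed, and inference
averages the member probabilities.

The four standard variants map to two flags: the full model (hierarchy +
negatives, named NCR in the package's variant table), NCR-H (A = I), NCR-N
(no negatives), NCR-HN (neither).

### Document annotation

Documents are lowercased, split into sentences at `[.?!;]` + whitespace, and
tokenized as maximal alphanumeric runs with character offsets into the
original string (spans are reported 0-based, half-open).  Every
within-sentence n-gram of 1–7 tokens is scored; each span keeps its best
non-NONE concept and that concept's (ensemble-averaged) probability;
candidates below the threshold are dropped.  The remaining overlaps are
resolved pairwise: same concept → keep the smaller n-gram; different
concepts → keep the longer one (preferring the specific "conotruncal heart
defect" over the general "heart defect" inside it).  The pairwise rules are
lifted to a greedy fixed point over a deterministic ordering (sentence,
start, end, concept id), with equal-length ties broken by score, then
lexicographic concept id; each step removes one candidate, so termination
and input-order independence are guaranteed.

The operating threshold is selected on a validation corpus as the grid value
maximizing micro F1 (default grid 0.5–0.95 in steps of 0.05, bracketing the
published per-variant values 0.85/0.8/0.8/0.75); ties go to the largest
threshold, favoring precision.

**Known limitation.** The final annotation set is *not* guaranteed monotone in
the threshold: removing a candidate can change which of two other overlapping
spans survives resolution.  We observed real violations at low thresholds
(≈0.4) on synthetic documents.  Monotonicity holds at the filter stage and,
empirically, over the operating threshold range; the tests assert exactly
that.

### Evaluation

Document-level sets: R_d reported, L_d gold concepts.  Micro P/R pool counts
over documents; macro P/R average per-document values, with the convention
that an empty R_d contributes precision 1.0 and an empty L_d recall 1.0 (the
same convention keeps the micro denominators total).  Extended metrics
replace each set by its ancestor closure E(S) before micro pooling, crediting
taxonomically close answers, and the Jaccard index is the pooled
|E(R)∩E(L)| / |E(R)∪E(L)|.  The pooling of the extended metrics across
documents is an interpretation (the alternative, per-document macro-style
averaging, is available via the per-document values); isolated-phrase ranking
is scored as R@k, the fraction of phrases whose gold concept is in the top k.

## Synthetic data

All tests and the acceptance script run on generated data; nothing is
downloaded.  The generator (`neurodict.fixtures`) emulates the structural
properties the method exploits:

* a rooted concept DAG (tree plus a 10% chance of one extra parent) in which
  a child's name is its own modifier token prepended to its parent's name, so
  names grow more specific with depth, as in a real phenotype taxonomy;
* every surface token belongs to a synonym group of 6 generated tokens; the
  name uses member 0, the 3 training synonyms use members 1–3, and 2
  *held-out paraphrases* per concept use members 4–5, which never occur in
  any training string;
* the word-vector fixture draws each group near a shared unit centroid
  (v = normalize(centroid + 0.25·noise), within-group cosine ≳ 0.9,
  asserted ≥ 0.8), mimicking what unsupervised pretraining does for real
  synonyms, while unrelated tokens are near-orthogonal;
* documents wrap verbatim name/synonym mentions in filler sentences drawn
  from a disjoint vocabulary, which also serves as the negative corpus.

Held-out paraphrase ranking is therefore solvable only through word-vector
geometry — the property the encoder is designed to exploit — and not by
string memorization.  The standard study condition is 30 concepts with 3
synonyms each, word vectors of dimension 25, concept dimension 64, 50 epochs
at batch 32, three training seeds; under it the seed-averaged held-out R@1 is
required to reach 0.8 (R@5 ≥ R@1).  What passing does **not** show: the
generator has no morphological variation, abbreviations, negation, polysemy
or register shift, so fixture scores say nothing quantitative about clinical
text; they validate the mechanism, not the deployment.

The demo world (`make_demo_world`) is the worked overlap-resolution example:
a three-concept taxonomy (root, "heart defect", "conotruncal heart defect")
with generic clinical filler.  Its negative corpus intersperses isolated
concept words (never two adjacent) in filler context, exactly as an unrelated
natural corpus would contain "heart" or "defect" outside any mention — without
this, bare sub-tokens score confidently and the same-concept rule can
collapse the full mention onto a sub-span.  The demo threshold is selected on
a four-document validation set by micro F1, mirroring the real procedure.

## Numerical and design choices

* Softmax is computed with max subtraction; probabilities sum to 1 ± 1e−9.
* Max-pool gradient routes to the first maximizing token per filter.
* `top_k` breaks score ties by lexicographic concept id for reproducibility.
* OBO parsing keeps all non-obsolete terms, treats every synonym string
  identically regardless of scope qualifier, records `alt_id` aliases, and
  rejects cycles (naming a member) and dangling `is_a` targets.  Multiple
  roots are allowed; no virtual super-root is added (a root's row is its unit
  vector either way).
* Out-of-vocabulary tokens map to the zero vector by default (contributing a
  learnable ELU(b) per filter); a deterministic hash-seeded unit vector
  policy is available for ablations.  Subword inference is not reimplemented.
* Checkpoints are single `.npz` archives holding the config, all parameters,
  the concept index, the ancestry matrix and the word-vector table; saving is
  byte-deterministic and loading round-trips bitwise.
* Problem sizes in the test-suite and acceptance script (10–30 concepts,
  word dims 16–25, 8 synthetic documents per split) are chosen so the full
  pipeline — including ensemble training — re-runs from scratch in seconds
  while still exercising every code path at DAG, not just tree, generality.
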