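# Methods

## The ensemble combiner

### Model

Let n span extractors run over a corpus. A *candidate* is any span
(doc, section, start, end) predicted by at least one extractor —
candidate identity is purely offset-based, so overlapping but unequal
spans are distinct candidates and near-miss boundaries are never merged
(a known limitation: the ensemble cannot repair a systematic one-
character boundary disagreement between extractors). Each candidate's
signature s ∈ {0,1}ⁿ records which extractors predicted exactly it.

The combiner models P(entity | signature) non-parametrically: for each
realized signature s it computes the precision of the derived extractor
Y(s), the set of spans predicted by every firing extractor and by no
silent one. The Y(s) sets partition the candidate pool, so cell
candidate counts always sum to the pool size. There are 2ⁿ − 1
estimable cells (the all-zero signature cannot produce a candidate).
No independence between extractors is assumed — that is the point: the
probability attached to "only extractors 1 and 3 agree" is whatever the
annotated corpus says it is, which majority voting or linear
interpolation cannot express.

### Estimation, scoring and calibration

Estimation is exact counting: probability = hits / candidates per cell,
reported raw (an optional add-a smoothing exists, default 0, because the
method's published tables report raw precisions). Estimation and scoring
corpora are separate inputs: the intended workflow estimates the table on
an annotated development corpus and applies it to a test corpus.

Scoring a *new* corpus can realize a signature the estimation corpus
never did. The fallback policy is selectable: the default scores such a
candidate with the unweighted mean of the single-extractor probabilities
of its firing extractors (available singles only, 0 if none); `zero` and
`error` policies are available. On the estimation corpus itself every
signature is realized, and a self-consistency guarantee holds: at any
threshold τ the retained set is a union of cells whose precision is ≥ τ,
so its pooled precision is ≥ τ. This is the calibration property the
acceptance script measures as a margin.

The precision–recall curve evaluates the threshold at every distinct
confidence plus the endpoints 0 and 1 with exact-span micro-averaged
scoring; recall and retained-set size are non-increasing in τ, and
recall at τ = 0 equals the recall of the union of all extractors.

## The CRF tagger

### Model

A first-order linear-chain CRF over labels {B, I, O}: one weight per
(feature, label) pair, one per (label, label) transition, plus start/end
potentials. Training maximises the L2-penalised conditional
log-likelihood with L-BFGS (scipy's implementation; gradient from
forward–backward in log space). Defaults: penalty 1.0, at most 100
iterations, relative-objective tolerance 1e-5. Training is deterministic
given the data — the objective is convex and the optimiser is started
from zero — so the `seed` field of the training configuration exists
only for interface stability.

The tagging pipeline is sentence detection → tokenization (the
tokenizer named in the model file) → feature assembly → Viterbi →
BIO decoding. An I following O is decoded as B rather than dropped.
No post-processing or abbreviation matching is applied. Per-entity
confidence is the product of the per-token marginal probabilities of the
decoded labels over the entity's tokens, clipped to [0, 1]: it is
available from any linear-chain CRF, monotone in model certainty, and
suitable for ranking, though not calibrated the way the ensemble's
probabilities are.

Gold mentions whose boundaries do not coincide with token boundaries are
skipped during label encoding and counted in the training diagnostics
rather than silently extended to token boundaries; extending would
fabricate training spans the annotator never marked.

### Features

Families and their neighbour windows (± tokens, re-keyed as
`word[-1]=…`):

| family | content | window |
|---|---|---|
| word | surface and lowercased surface | 2 |
| shape | has-digit, initial-capital, all-caps, all-lower, mixed-case, ends-in-sign, ends-in-digit, has-dash, starts-with-digit, formula heuristic | 1 |
| word class | per-character A/a/0/x pattern, full and run-collapsed | 1 |
| cluster | embedding-cluster id of the term (exact then lowercase lookup; no feature when absent) | 1 |
| gazetteer | token membership, full-entry runs, affix matches, boost | 1 |
| Soundex | phonetic code at the configured digit budget (default 7) | 0 |
| n-grams | character 2/3/4-grams | 0 |

High-cardinality families get the wider window; Soundex and n-grams stay
local to limit parameter growth. The windows are configurable per
family. Ablation toggles (`use_nlp`, `use_word2vec`, `use_soundex`,
`use_gazetteers`, `soundex_len` ∈ {3, 5, 7, 100}) switch families off
wholesale for feature studies.

Soundex is American Soundex with a configurable digit budget and no
zero-padding: padding would break the property that carbon and its
derivatives share a code across budget lengths, which is the reason the
feature exists. Tokens with no letters map to the sentinel `#` so
numeric tokens share one code. A subtlety worth recording: vowels break
digit runs while H and W are transparent, so deleting vowels from a word
can change its code even though deleting H/W cannot.

Lemmatization is a pluggable hook defaulting to identity (off), since
useful chemical lemmatizers are external; word-class conversion is
native. The sentence-start feature lets the model separate
sentence-initial capitalisation from meaningful capitalisation.

### Tokenization

The default `chem` tokenizer splits on whitespace, then peels leading
and trailing punctuation off each fragment with three exceptions that
chemical nomenclature forces: brackets balanced within the fragment stay
attached (`Ca(2+)`), internal punctuation between word characters never
splits (`1,2-dichloroethane` is one token), and a trailing period is
always split off. `whitespace` and `simple-punct` tokenizers are
registered for comparison, mirroring the practice of benchmarking
interchangeable tokenizers before committing to one. Word characters are
`str.isalnum()`, which includes Greek letters and sub/superscript
digits. Sentence boundaries are `.`/`!`/`?` followed by whitespace and
an uppercase letter (or end of text); tokenization runs per sentence, so
tokens never cross sentence boundaries.

The tokenizer benchmark scores a gold mention set: a space-free mention
is Correct iff a single token reproduces its exact span; a multi-word
mention (space the only separator) is Split Correct iff each word is
exactly one token; everything else is Incorrect. The strict single-token
reading of Correct was one of two defensible readings; the counts always
partition the gold set, and accuracy is an upper bound on the recall any
extractor can reach with that tokenizer.

## Synthetic data

The corpus generator emulates annotated PubMed-style abstracts: filler
prose with embedded chemical-like mentions built from a fragment grammar
(stems meth/eth/prop/… × suffixes -ane/-anol/-ylene/…, with di-/cyclo-/
iso-/… prefixes), formula tokens (`CO2`-like element-count strings
satisfying the formula heuristic), and two-word mentions
(`<name> acid/chloride/…`) at a configurable fraction. Defaults: 4
sentences per abstract, Poisson(1) mentions per sentence, 20% multiword,
25% formulas, a gazetteer covering 70% of the chemical vocabulary and a
cluster map concentrating chemical terms in 5 of 50 clusters. All
mentions are whitespace-delimited by construction, so gold spans are
token-aligned under the default tokenizer and the tokenizer benchmark
scores 100% — that is a generator guarantee, not a statement about real
corpora, where misaligned mentions (the benchmark's Incorrect class)
are a dominant error source. Likewise the planted dictionary/cluster
signal makes the tagging task strongly separable; held-out F1 near 1.0
on this corpus demonstrates that the pipeline is wired correctly, not
that the feature set reaches any particular accuracy on real abstracts,
which would require the external annotated corpus and extractors.

The extractor simulator inverts table estimation: for each signature
cell (count, q) it fabricates `count` distinct spans, assigns them to
exactly the firing extractors, and marks round(q·count) gold (`exact`
mode, making recovery integer-exact and separating logic errors from
sampling noise) or each gold with probability q (`stochastic` mode,
binomial noise ~ sqrt(q(1−q)/count) per cell). The realized table is
returned so tests compare estimate against realization, not against the
asymptotic q.

`train_cluster_map` is a small count-based embedding pipeline (windowed
co-occurrence → positive PMI → truncated SVD → K-Means) for integration
testing of the cluster-feature plumbing on generated corpora; production
cluster maps are trained offline on a large domain corpus and loaded
from two-column TSV.

## Problem sizes used in the checks

The acceptance script trains the tagger on 160/40 of a 200-document
corpus (~45 s), checks oracle equivalence on 200 random ensembles of up
to 4 extractors × 50 spans, calibration on 50 simulated instances, and
parameter recovery over 20 seeds with 20,000 candidates per cell —
large enough that the binomial standard error (~0.0035) keeps the worst
of 140 cell estimates an order of magnitude inside the 0.03 reporting
bound. The feature-ablation comparison in the test suite uses 40-document
corpora over 5 seeds, sizes at which each training finishes in seconds
while the planted signal still dominates noise.

## Known limitations

* Offset-identity candidates: the ensemble never merges near-miss spans.
* The CRF is first-order only; label interactions longer than adjacent
  pairs are not modelled.
* The `chem` tokenizer approximates chemistry-aware tokenizers
  behaviourally; it does not reproduce any particular tool's output
  byte-for-byte.
* The synthetic corpus does not emulate real abstract prose,
  abbreviations, or annotation noise; conclusions from it are about
  implementation correctness, not real-corpus accuracy.
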