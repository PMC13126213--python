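# Methods

## The screening problem

Systematic reviewers screen thousands of title/abstract records to find the
small fraction (typically 0.5–10%) relevant to their question.  AI-aided
screening tools reorder the unscreened records by predicted relevance using
*active learning*: a classifier is trained on the records labeled so far, the
top-ranked record is screened next, its label is fed back, and the cycle
repeats.  `screensim` simulates that loop on fully labeled collections: the
stored label stands in for the reviewer's decision, so a simulation replays
how screening *would* have unfolded under a given algorithm, and the complete
screening order (the *trace*) supports exact evaluation of costs, recalls,
and stopping rules.

## The simulation loop

`simulate.run_simulation` fits a relevance model on the labeled multiset
(after rebalancing), ranks the unlabeled records by score, reveals the stored
label of the top-ranked record, and repeats until the screening set is
exhausted.  Design choices:

* **Batched refits.**  With `retrain_interval = k`, the simulator reveals the
  top *k* of the current ranking in rank order without re-ranking mid-batch,
  then refits.  A full run therefore performs `ceil(candidates / k)` fits.
  Labeled records leave the candidate pool immediately even between refits.
* **Run to exhaustion.**  Stopping rules are evaluated afterwards on the
  trace, so every rule is compared on identical orderings.
* **Two accounting modes.**  When the initial training records belong to the
  screening collection they occupy trace positions 1..t and count toward all
  denominators (the ratio-manipulation study design); when the training set is
  drawn outside the screening set the trace covers screening records only (the
  fixed-relevant-count design).  The trace records which mode applied.
* **`classifier_id="oracle"`** scores candidates by their stored label — a
  perfect-ranking stub used for closed-form checks (SC@95% must then equal
  `ceil(0.95 R)/N_s` and FPR@95% must be 0).

## ML algorithms

Classifiers: logistic regression, multinomial naive Bayes, linear-kernel SVM
(raw decision margins; ranking needs no calibration), random forest
(100 trees), and a two-hidden-layer MLP (128 units per layer, clamped to the
training-set size so tiny initial fits cannot fail).  Feature extractors:
TF-IDF (lowercase unigrams, smoothed IDF `ln((1+N)/(1+df)) + 1`, L2-normalised
rows — the scikit-learn convention, documented so tests can hand-compute
entries) plus a plug-in registry for pretrained embedding extractors
(doc2vec, SBERT).  The package never downloads model weights; a deterministic
signed-hashing pseudo-embedding (`hashed_stub`) exercises the negative-valued
feature paths, in particular the naive Bayes incompatibility (NB requires
nonnegative features).

The TF-IDF vocabulary is fitted once on the full collection rather than on the
labeled records only: in a simulation all texts are available up front, and a
fixed vocabulary avoids feature-space churn across refits.

**Balancing.**  `dynamic_resampling` keeps the training multiset at its
original size while raising the relevant-class share to a target (default
0.5): relevant records are retained and replicated round-robin, irrelevant
records subsampled without replacement.  A multiset at or above the target
share passes through unchanged.  The published description of this rebalancing
is verbal, not a formula; this size-preserving scheme is our reconstruction of
"undersample irrelevant, oversample relevant, keep the set balanced".

**Certainty query.**  Candidates are sorted by score descending with ties
broken by original collection order (stable sort), which makes rankings — and
hence whole traces — bitwise reproducible given a seed.

## Synthetic collections

`synth.generate_corpus` draws bag-of-token documents from two multinomials
over a shared vocabulary.  Irrelevant documents use a Zipf-weighted
*background* distribution; relevant documents use the mixture
`signal_strength * signal-block + (1 - signal_strength) * background`, where
the signal block is a reserved vocabulary slice (10% of the vocabulary, at
least 10 tokens) the background never emits.  Parameters, with defaults:

| parameter         | default | meaning                                         |
|-------------------|---------|-------------------------------------------------|
| `n_total`         | 1000    | collection size N                               |
| `prevalence`      | 0.05    | relevant share; R = round(N x prevalence) exactly |
| `vocab_size`      | 500     | distinct tokens                                 |
| `signal_strength` | 0.7     | separability dial: 0 = chance, 1 = disjoint classes |
| `doc_length_mean` | 40      | Poisson mean tokens per record (floor 4)        |
| `noise_rate`      | 0.1     | share of relevant records drawn from the background |
| `seed`            | 0       | master seed; all sub-streams derived by hashing |

`noise_rate` emulates the well-documented tail problem: some relevant records
resemble nothing in the training set and are found late.  At the default 10%,
reaching high sensitivity requires screening deep into the collection even
when the ranking is otherwise excellent — which is exactly the regime where
stopping rules earn their keep.

What the generator does *not* emulate: real English with topical drift,
duplicated records, missing abstracts at realistic rates, or reviewers'
inconsistent label application.  Passing tests therefore demonstrate the
pipeline's arithmetic and ordering behaviour under controllable difficulty,
not expected screening costs on any real corpus.

## Manipulation designs

* **Ratio sampling** solves the target prevalence `p = a/b` in integers: the
  largest exact-prevalence subset has `k*a` relevant and `k*(b-a)` irrelevant
  records with `k = min(R // a, I // (b-a))`.  Raising prevalence discards
  irrelevant records; lowering it discards relevant ones.  Prevalence of the
  output is checked by rational equality, never floating point.  The exact-
  ratio rule (rather than a rounding tolerance) is our choice; it reproduces
  the fixed-count design's printed totals and makes prevalence testable by
  equality.
* **Fixed-relevant sampling** draws exactly `n_rel` relevant plus
  `n_rel (1-p)/p` irrelevant records (total `n_rel / p`), so the number of
  relevant records is constant across prevalence conditions — 20 relevant at
  1% / 2.5% / 5% gives collections of 2,000 / 800 / 400 records, and 40
  relevant gives 4,000 / 1,600 / 800.
* **Training sets** are drawn uniformly: inside the collection (the trace then
  starts with the pre-screened training records) or disjoint from a
  pre-sampled screening set, which keeps screening composition identical
  across training-set conditions.

## Metrics

All metrics are prefix functions of the trace.  With R relevant among N_s
screening records, `n*` = the smallest depth with TP >= `ceil(s*R)`:

* sensitivity = TP/(TP+FN); **SC@s** = n*/N_s; **FPR@s** = FP/(FP+TN) at n*;
  **RRF@p** = sensitivity at depth `floor(p*N_s)`; **WSS@s** = 1 - SC@s.

The ceiling threshold means 19 of 20 and 38 of 40 relevant records meet the
95% level exactly.  Levels such as 0.95 are snapped to exact rationals before
multiplication so `0.95 * 20` can never ceil to 20.  Values are stored as
fractions in [0, 1]; percentage rendering (2 decimals) is formatting only.

## Stopping rules

A rule maps a trace to the first position at which its condition *has been
met*; "met" is permanent (a completed consecutive-irrelevant run stays
satisfied), which is the checklist semantics a combined rule requires.  The
combined rule's position is therefore the maximum over member positions.
Fractional consecutive-irrelevant cutoffs convert per trace as
`ceil(fraction * N_s)`.  The breakout rule races a high-cutoff
consecutive-irrelevant run against a fallback (usually time-based) rule and
stops at whichever comes first.  The random-prescreening completion check
requires `max(1% of N, 100)` records screened and at least one relevant find;
criteria are evaluated per record, not at batch boundaries (the finer of the
two readings).  Every rule is verified against an independent brute-force
prefix-scan oracle on 1,000 random traces.

## Recommendations

`recommend` chains prevalence estimation (relevant found / randomly screened —
multiplying by the retrieval size gives an expected relevant *count*, exposed
separately), band lookup, and workload projection
`saving = 1 - (random share + time-based cutoff + data-driven allowance)`,
with hours at 30 s/record.  The default band table (edges 2.5% and 7.5%,
half-open `[low, high)`) ships only the two text-anchored entry sets — mid
band: time-based 35% + data-driven 5%; low band: time-based 40% + breakout
15% — and *fails closed* for the high band: unconfigured cutoffs raise
instead of guessing, and users supply their own `RecommendationTable` to
override.

## Experiments and aggregation

`enumerate_runs` materialises the full cross-product manifest; per-run seeds
are SHA-256 hashes of (master seed, collection, condition, replication,
training, algorithm), so results are independent of execution order and
parallel schedule.  `execute` isolates per-run failures as error rows.
Summaries use sample sd (ddof 1) and linear-interpolation quantiles (the
common statistical-software default; the convention is asserted against a
hand-rolled order-statistics oracle in the tests).

## Problem sizes used in the test suite

The published designs (84,000 / 54,000 artificial collections; 840,000 /
162,000 simulations on real abstract collections with pretrained embeddings)
are reproduced *as counts* by enumerating the manifests.  The executed
replication in the test suite is a scaled-down synthetic analogue of the
fixed-relevant-count design, chosen as a desk-scale configuration: 9 synthetic
collections (4,300 records, 2% prevalence, heterogeneity 0.15) x prevalences
{1%, 2.5%, 5%} x frequencies {8, 16} relevant records x 20 replications, LR +
TF-IDF with retrain interval 10 and 1 relevant + 10 irrelevant training
records, against a seeded random-order baseline.  The separability
(signal-strength) monotonicity check runs on a reduced single-cell grid
(20 seeds x 3 signal levels, 400-record collections, `noise_rate = 0` so the
separability dial is the only moving part).  These sizes are the package's own
trade-off between statistical resolution and a test suite that completes in
minutes; the qualitative contrasts they assert (active learning beats random
screening in every cell; more separable corpora never screen more expensively)
are scale-free.

## Known limitations

* Token-multinomial documents cannot expose failure modes tied to real
  language (synonymy, negation, topical drift within a review).
* The dynamic-resampling scheme matches the verbal description of the
  original, not a published formula; absolute SC values under heavy imbalance
  may differ from other implementations even at identical seeds.
* doc2vec/SBERT results depend on whichever pretrained embeddings a user
  plugs in; nothing is bundled.
* Whether a production screener re-ranks within a batch between refits is
  tool-specific; the no-re-rank choice here changes within-batch order only.
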