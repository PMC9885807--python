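# Methods

## Screening strategies

### Regex match-count screening

A screening term set is a list of multiword phrases with surface variants and
optional abbreviations (the packaged exemplar covers oxygen–glucose
deprivation: the canonical phrase, conjunction variants such as "deprived of
oxygen and glucose", and the abbreviation "OGD"). Text is NFKC-normalised and
all dash glyphs (hyphen, non-breaking hyphen, figure/en/em dash, minus) folded
to `-` before matching, because abstracts and PDF-extracted full text mix
these glyphs freely. Between the words of a phrase the pattern accepts runs of
spaces/tabs, dashes, slashes, or a single line break; a blank line is treated
as a paragraph boundary and never bridged, which makes match counts exactly
additive over `"\n\n"`-concatenation. Phrases match case-insensitively;
abbreviations match exact-case at word boundaries by default (configurable),
to avoid hits inside unrelated tokens. Matches are counted non-overlapping,
leftmost-first, with longer variants preferred at a given position.

A record's TiAb count is the title count plus the abstract count (a phrase
cannot span the title/abstract boundary); screening includes a record when
its count reaches a threshold, so threshold 1 means "mentioned at least
once". Default thresholds are 1 for TiAb and 2 for full text, the operating
points the count-ROC calibration selects on corpora of this shape; both are
arguments, and `optimal_threshold` re-derives them from a ROC curve when
asked.

### Evaluation statistics

From confusion counts: sensitivity Se = TP/(TP+FN), specificity
Sp = TN/(TN+FP), precision TP/(TP+FP). A zero denominator yields an explicit
`None` ("undefined"), never 0 and never an exception — a report must be able
to distinguish "no positives existed" from "perfect". The summary statistic
is the Euclidean distance to the perfect corner,

    d = sqrt((1 − Se)² + (1 − Sp)²),

ranging from 0 (perfect) to √2; the strategy or threshold minimising d is
considered optimal, with ties broken toward higher specificity and then
higher threshold (systematic-review screening already over-includes, so the
tie should not add more false positives).

ROC curves are empirical step functions over all distinct score thresholds
(include iff score ≥ t), anchored at (0,0); AUC is the trapezoidal area,
which on these step curves equals the tie-adjusted Mann–Whitney pairwise
probability — the test suite verifies that identity against an independent
pairwise oracle rather than assuming it. With all scores tied the curve is
the diagonal and AUC is 0.5.

`threshold_for_sensitivity` returns the largest threshold whose include-set
sensitivity reaches the target (default 0.95) on the supplied validation
scores; `project_corpus_scale` propagates (prevalence, Se, Sp) through a
corpus of arbitrary size in exact real arithmetic, leaving rounding to
presentation; `extrapolate_total` is the plain division found/Se.

Displayed metrics are rounded half-up to 3 decimals; internal values are
never rounded.

### Classifier

Featurization: word n-grams of length 1–3 over lowercased tokens (≥ 2 word
characters, plus single digits), n-grams below a minimum document frequency
(default 2) dropped, term-frequency weighting with L2 row normalisation
(tf-idf by flag). Only title-and-abstract text is featurized — the
classifier's entire point is to operate where full text is unavailable.

The model is a linear SVM trained by stochastic gradient descent on hinge
loss with L2 penalty (α = 1e-4), 10 shuffled epochs under the "optimal"
learning-rate schedule, all seeded; featurization and SGD are delegated to
scikit-learn (`CountVectorizer`, `TfidfTransformer`, `SGDClassifier`) behind
this package's interface. Raw margins are mapped to [0, 1] by a Platt-style
logistic calibration (a one-dimensional logistic regression fitted on the
training margins); the calibrated score is strictly increasing in the margin,
so thresholding the score is equivalent to thresholding the margin while
remaining interpretable as "strength of inclusion prediction". Models
round-trip through a versioned JSON container (vocabulary, weights,
calibration, hyperparameters, seed).

The train/validation split is a seeded uniform 80/20 partition (training
size = ⌊0.8·n⌋, so 2453 records split 1962/491). Identical corpus,
hyperparameters and seed reproduce identical weights.

### Error correction

Ranking human/machine discrepancies by |label − score| (label as 0/1, score
calibrated) is the simplest faithful reading of "largest discrepancy"; ties
break by record id for stability. The top k (default 100) are rescreened by
an oracle, their labels replaced, and the classifier retrained from scratch
on the corrected corpus. The corpus is re-split with the *same* seed, so the
validation set differs from the pre-correction one only where labels were
corrected, and the before/after comparison at the 0.95-sensitivity threshold
is like-for-like. One round is the default; iteration is possible but out of
the default workflow. Whether to re-split or freeze the original split was an
open design point; re-splitting with the same seed was chosen because label
corrections must be allowed to propagate into validation metrics, which is
the quantity the loop is meant to improve.

### Reconciliation and the gold standard

`reconcile` is symmetric in the first two reviewers: agreement stands,
disagreement falls to the arbitration decision, and a missing arbitration is
a structured error carrying the record id. The gold standard starts from
reconciled full-text decisions — the most complete single source — and sends
every record on which *any* comparison method (human TiAb, regex TiAb, regex
full text) disagrees to a senior-reviewer oracle, whose verdict becomes gold.
Gold labels can therefore differ from the full-text decisions only on
conflicted records, and the bookkeeping identity
|gold includes| = |full-text includes| + additions − removals is asserted in
the tests.

## Synthetic corpora

The generator emulates the features of real screening corpora that the
methods are sensitive to, with all randomness from one seeded generator:

* **Prevalence** — labels are Bernoulli(prevalence); default 0.062.
* **Match counts** — relevant records carry 1 + Poisson(12) full-text
  mentions, capped at 281 (a long right tail); irrelevant records mention the
  term at all with probability 0.03, then 1 + Poisson(1) times — which puts
  the full-text false-positive rate at a count threshold of 2 near 2%.
* **Abstract omission** — a relevant record's abstract carries ≥ 1 mention
  with probability 0.862; otherwise the abstract is silent and only full-text
  methods can find the record. Irrelevant abstracts mention the term with
  probability 0.005. Full text always contains the abstract verbatim, so
  full-text counts dominate TiAb counts by construction.
* **Topic signal** — tokens come from an "in vitro" pool, an
  "other-research" pool and a shared background; own-class pool words appear
  at rate base + separation·scale (defaults 0.05 + 0.30·0.20 = 0.11) and
  other-class words at the base rate, so the class-conditional distributions
  genuinely overlap (Bayes error > 0) and the separation knob controls
  classifier AUC monotonically.
* **Reviewers** — independent per-reviewer false-negative/false-positive
  rates; arbitration is generated only on disagreement, so with two reviewers
  at fnr 0.1 and a perfect arbitrator the reconciled miss rate is 0.1² = 0.01
  (verified in simulation against the closed form).

The standard classifier-study corpus is n = 2500 at prevalence 0.30 with
separation 0.30. Filler text is synthetic numbered tokens, not prose: the
generator reproduces *statistical* structure (counts, omission rates,
separability), not linguistic structure, so passing tests demonstrate that
the methods behave as designed under these mechanisms — they do not certify
performance numbers on real bibliographic text, where vocabulary burstiness,
topic drift and correlated reviewer errors all exist and are not modelled.
Reviewer errors here are independent across reviewers and records.

## Numerical and I/O conventions

* Absent abstract/full text is distinct from empty and round-trips through
  JSONL (missing key) and CSV (companion boolean column); eligibility
  filtering excludes conference abstracts, abstract-less and non-English
  records, tallying exactly one reason per exclusion, and *retains* records
  lacking full text (TiAb-only analysis remains valid for them; the
  comparison restricts itself to the full-text subset and reports the subset
  size).
* Records without explicit ids get deterministic ids hashed from source
  position and title.
* RIS import reads TY/TI/AB/LA/ID tags and flags conference types
  (CPAPER/ABST/CONF); RIS never supplies full text.
* The comparison analysis set is the subset with machine-readable full text,
  so every method row shares one denominator.
* Test problem sizes are scaled to what the properties need: 20-seed
  stochastic properties run on the standard 2500-record corpus, distributional
  checks on corpora of 600–5172 records, and ROC/regex property fixtures on
  ~1000 randomized small instances.

## Known limitations

* The packaged term set covers the quoted surface variants of one exemplar
  topic; real reviews must author their own YAML term sets, and regex recall
  is only as good as the variant list.
* The classifier is bag-of-words and English-tokenization only; no stemming,
  no MeSH expansion, no multilingual support.
* Human-screening AUC is not defined from a single binary decision and is
  deliberately left blank in reports for unscored methods.
* Corpus-scale projections assume Se/Sp transport unchanged to the target
  corpus; that is arithmetic, not inference.
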