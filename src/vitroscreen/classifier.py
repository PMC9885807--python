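"""Tri-gram bag-of-words linear classifier for citation screening.

Documents (title + abstract text only) are featurized as word n-grams of
length 1–3, term-frequency weighted with L2 row normalisation, and fed
to a linear max-margin classifier (hinge loss + L2 penalty) optimised by
stochastic gradient descent over seeded, shuffled epochs.  Raw margins
are mapped to inclusion scores in [0, 1] by a Platt-style logistic
calibration fitted on the training margins; higher scores mean a
stronger prediction of inclusion.  The calibrated score feeds the
recall-targeted thresholding in :mod:`vitroscreen.evaluation` and the
error-correction loop in :mod:`vitroscreen.error_correction`.

Everything is reproducible from (corpus, hyperparameters, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer, TfidfTransformer
from sklearn.linear_model import LogisticRegression, SGDClassifier

from .corpus_io import Record, ValidationError

logger = logging.getLogger(__name__)

#: Lowercase tokens of >= 2 word characters, plus single digits.
TOKEN_PATTERN = r"(?u)\b\w\w+\b|\b\d\b"


@dataclass(frozen=True)
class Hyperparameters:
    """Training knobs; defaults follow common SGD text-classification practice."""

    loss: str = "hinge"
    alpha: float = 1e-4          # L2 regularisation strength
    epochs: int = 10
    learning_rate: str = "optimal"
    ngram_range: tuple[int, int] = (1, 3)
    min_df: int = 2              # n-grams rarer than this are dropped
    use_tfidf: bool = False      # default: tf with L2 row normalisation


@dataclass
class LabeledCorpus:
    """Records plus one include/exclude label per record."""

    records: list[Record]
    labels: dict[str, bool]

    def __post_init__(self) -> None:
        ids = {r.id for r in self.records}
        if ids != set(self.labels):
            raise ValidationError("Every record must have exactly one label")

    def __len__(self) -> int:
        return len(self.records)

    def texts(self) -> list[str]:
        return [r.tiab() for r in self.records]

    def y(self) -> np.ndarray:
        return np.array([self.labels[r.id] for r in self.records], dtype=int)

    def n_positive(self) -> int:
        return int(sum(self.labels.values()))

    def with_labels(self, new_labels: Mapping[str, bool]) -> "LabeledCorpus":
        merged = dict(self.labels)
        merged.update(new_labels)
        return LabeledCorpus(records=list(self.records), labels=merged)


def split(corpus: LabeledCorpus, train_fraction: float = 0.8, seed: int = 0
          ) -> tuple[LabeledCorpus, LabeledCorpus]:
    """Seeded uniform random partition; training size = floor(fraction * n)."""
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    n = len(corpus)
    if n < 2:
        raise ValidationError("Need at least two records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    def take(idx):
        recs = [corpus.records[i] for i in idx]
        return LabeledCorpus(records=recs, labels={r.id: corpus.labels[r.id] for r in recs})
    return take(order[:n_train]), take(order[n_train:])


@dataclass(frozen=True)
class Vocabulary:
    """Deterministic n-gram -> column-index bijection."""

    index: dict[str, int]
    ngram_range: tuple[int, int]
    min_df: int

    def __len__(self) -> int:
        return len(self.index)


def fit_vocabulary(texts: Sequence[str], ngram_range: tuple[int, int] = (1, 3),
                   min_df: int = 1) -> Vocabulary:
    """Build the word 1–3-gram vocabulary a classifier would use."""
    if not any(t.strip() for t in texts):
        raise ValidationError("Cannot fit a vocabulary on an all-empty corpus")
    vec = CountVectorizer(lowercase=True, token_pattern=TOKEN_PATTERN,
                          ngram_range=ngram_range, min_df=min_df)
    try:
        vec.fit(texts)
    except ValueError as exc:
        raise ValidationError(f"Empty vocabulary: {exc}") from exc
    return Vocabulary(index={k: int(v) for k, v in vec.vocabulary_.items()},
                      ngram_range=ngram_range, min_df=min_df)


class ScreeningClassifier:
    """SGD-trained linear SVM over tri-gram bag-of-words features.

    sklearn-style estimator: construct with hyperparameters and a seed,
    ``fit`` on a :class:`LabeledCorpus`, then ``score`` records to get
    calibrated inclusion probabilities in [0, 1].
    """

    def __init__(self, params: Hyperparameters | None = None, seed: int = 0) -> None:
        self.params = params or Hyperparameters()
        self.seed = int(seed)
        self._vectorizer: CountVectorizer | None = None
        self._tfidf: TfidfTransformer | None = None
        self._svm: SGDClassifier | None = None
        self.calibration_slope_: float | None = None
        self.calibration_intercept_: float | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, train: LabeledCorpus) -> "ScreeningClassifier":
        y = train.y()
        if y.min() == y.max():
            raise ValidationError("Training set must contain both classes")
        p = self.params
        self._vectorizer = CountVectorizer(
            lowercase=True, token_pattern=TOKEN_PATTERN,
            ngram_range=p.ngram_range, min_df=p.min_df,
        )
        try:
            counts = self._vectorizer.fit_transform(train.texts())
        except ValueError as exc:
            raise ValidationError(f"Empty vocabulary: {exc}") from exc
        self._tfidf = TfidfTransformer(use_idf=p.use_tfidf, norm="l2")
        X = self._tfidf.fit_transform(counts)
        self._svm = SGDClassifier(
            loss=p.loss, penalty="l2", alpha=p.alpha, max_iter=p.epochs,
            learning_rate=p.learning_rate, tol=None, shuffle=True,
            random_state=self.seed,
        )
        self._svm.fit(X, y)
        self._fit_calibration(self._svm.decision_function(X), y)
        return self

    def _fit_calibration(self, margins: np.ndarray, y: np.ndarray) -> None:
        # Platt-style: 1-D logistic regression of label on margin.
        lr = LogisticRegression(C=1.0, solver="lbfgs")
        lr.fit(margins.reshape(-1, 1), y)
        self.calibration_slope_ = float(lr.coef_[0, 0])
        self.calibration_intercept_ = float(lr.intercept_[0])

    # -- inference ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if self._svm is None:
            raise ValidationError("Classifier is not fitted")

    def decision_function(self, texts: Sequence[str]) -> np.ndarray:
        self._check_fitted()
        X = self._tfidf.transform(self._vectorizer.transform(texts))
        return self._svm.decision_function(X)

    def score_texts(self, texts: Sequence[str]) -> np.ndarray:
        m = self.decision_function(texts)
        z = self.calibration_slope_ * m + self.calibration_intercept_
        return 1.0 / (1.0 + np.exp(-z))

    def score(self, records: Sequence[Record]) -> dict[str, float]:
        """Calibrated inclusion score in [0, 1] per record id."""
        empties = [r.id for r in records if not r.title and not r.abstract]
        if empties:
            logger.warning("Scoring %d records with no title or abstract", len(empties))
        s = self.score_texts([r.tiab() for r in records])
        return {r.id: float(v) for r, v in zip(records, s)}

    # -- introspection / persistence --------------------------------------

    @property
    def vocabulary(self) -> Vocabulary:
        self._check_fitted()
        return Vocabulary(
            index={k: int(v) for k, v in self._vectorizer.vocabulary_.items()},
            ngram_range=self.params.ngram_range, min_df=self.params.min_df,
        )

    @property
    def weights(self) -> np.ndarray:
        self._check_fitted()
        return self._svm.coef_.ravel().copy()

    @property
    def bias(self) -> float:
        self._check_fitted()
        return float(self._svm.intercept_[0])

    def to_json(self, path: str | Path) -> None:
        self._check_fitted()
        obj = {
            "format_version": 1,
            "hyperparameters": {**asdict(self.params),
                                "ngram_range": list(self.params.ngram_range)},
            "seed": self.seed,
            "vocabulary": self._vectorizer.vocabulary_
            and {k: int(v) for k, v in self._vectorizer.vocabulary_.items()},
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "idf": (self._tfidf.idf_.tolist() if self.params.use_tfidf else None),
            "calibration": {"slope": self.calibration_slope_,
                            "intercept": self.calibration_intercept_},
        }
        Path(path).write_text(json.dumps(obj), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScreeningClassifier":
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
        hp = obj["hyperparameters"]
        hp["ngram_range"] = tuple(hp["ngram_range"])
        model = cls(params=Hyperparameters(**hp), seed=obj["seed"])
        p = model.params
        vec = CountVectorizer(lowercase=True, token_pattern=TOKEN_PATTERN,
                              ngram_range=p.ngram_range, min_df=p.min_df,
                              vocabulary=obj["vocabulary"])
        vec._validate_vocabulary()
        model._vectorizer = vec
        tfidf = TfidfTransformer(use_idf=p.use_tfidf, norm="l2")
        n_feat = len(obj["vocabulary"])
        if p.use_tfidf:
            tfidf.idf_ = np.asarray(obj["idf"])
        else:
            # fit on a trivial doc just to mark the transformer usable
            from scipy.sparse import csr_matrix
            tfidf.fit(csr_matrix((1, n_feat)))
        model._tfidf = tfidf
        svm = SGDClassifier(loss=p.loss, penalty="l2", alpha=p.alpha)
        svm.coef_ = np.asarray([obj["weights"]])
        svm.intercept_ = np.asarray([obj["bias"]])
        svm.classes_ = np.array([0, 1])
        model._svm = svm
        model.calibration_slope_ = obj["calibration"]["slope"]
        model.calibration_intercept_ = obj["calibration"]["intercept"]
        return model


#: Spec-facing alias: a fitted ScreeningClassifier *is* the model object.
ClassifierModel = ScreeningClassifier


def train(train_corpus: LabeledCorpus, params: Hyperparameters | None = None,
          seed: int = 0) -> ScreeningClassifier:
    """Convenience wrapper: construct and fit a :class:`ScreeningClassifier`."""
    return ScreeningClassifier(params=params, seed=seed).fit(train_corpus)
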