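"""The ML core of the active-learning loop: feature extraction, training-set
balancing, classifier fitting, and certainty-based ranking.

Feature extractors and classifiers are selected by the names the screening
literature uses (``tfidf``, ``doc2vec``, ``sbert`` x ``lr``, ``nb``, ``svm``,
``rf``, ``nn2layer``).  TF-IDF is the built-in extractor: lowercased unigrams,
smoothed IDF ``ln((1+N)/(1+df)) + 1`` and L2-normalised rows (the scikit-learn
convention), with the vocabulary fitted once on the full collection — in a
simulation every text is available up front, and a fixed vocabulary avoids
churn across refits.

Embedding extractors (doc2vec, SBERT) produce dense, possibly negative vectors
and require pretrained models; they are supported through a plug-in registry
(:func:`register_extractor`) with a single contract: rows aligned to the input
records.  ``hashed_stub`` is a deterministic signed-hashing pseudo-embedding
that exercises the negative-valued code paths (e.g. the naive Bayes
incompatibility) without any model download.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import HashingVectorizer, TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from ._seeds import derive_seed
from .records import Collection, Record

CLASSIFIERS = ("lr", "nb", "svm", "rf", "nn2layer")
EXTRACTORS = ("tfidf", "doc2vec", "sbert", "hashed_stub")


@dataclass
class FeatureMatrix:
    """Numeric features for a set of records, rows aligned to ``ids``."""

    matrix: object  # scipy sparse or numpy array, shape (n_records, n_features)
    extractor_id: str
    ids: list[str]
    nonnegative: bool

    def rows_for(self, ids: Sequence[str]):
        index = {rid: i for i, rid in enumerate(self.ids)}
        return self.matrix[[index[i] for i in ids]]


@dataclass(frozen=True)
class ALConfig:
    """One active-learning algorithm configuration.

    ``retrain_interval`` is the number of labels revealed between model
    refits (1 = refit after every screened abstract).
    """

    classifier_id: str = "lr"
    extractor_id: str = "tfidf"
    query_strategy: str = "certainty"
    balance_strategy: str = "dynamic_resampling"
    retrain_interval: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier_id not in CLASSIFIERS + ("oracle",):
            raise ValueError(f"unknown classifier {self.classifier_id!r}")
        if self.extractor_id not in EXTRACTORS:
            raise ValueError(f"unknown extractor {self.extractor_id!r}")
        if self.query_strategy != "certainty":
            raise ValueError("only the certainty query strategy is implemented")
        if self.balance_strategy not in ("dynamic_resampling", "none"):
            raise ValueError(f"unknown balance strategy {self.balance_strategy!r}")
        if self.retrain_interval < 1:
            raise ValueError("retrain_interval must be >= 1")

    @property
    def name(self) -> str:
        return f"{self.classifier_id}+{self.extractor_id}"


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

_PLUGIN_EXTRACTORS: dict[str, Callable[[list[str]], np.ndarray]] = {}


def register_extractor(name: str, fn: Callable[[list[str]], np.ndarray]) -> None:
    """Register an embedding plug-in: texts -> row-aligned numeric matrix."""
    _PLUGIN_EXTRACTORS[name] = fn


def extract_features(
    collection: Collection,
    extractor_id: str = "tfidf",
    extra_records: Sequence[Record] = (),
    **params,
) -> FeatureMatrix:
    """Vectorise every record of ``collection`` (plus ``extra_records``).

    ``extra_records`` lets an externally drawn training set share the feature
    space of the screening collection.  Records with empty text yield all-zero
    rows with a warning.
    """
    records = list(collection) + list(extra_records)
    if not records:
        raise ValueError("cannot extract features from an empty collection")
    texts = [r.text for r in records]
    ids = [r.id for r in records]

    if extractor_id == "tfidf":
        vec = TfidfVectorizer(lowercase=True, **params)
        try:
            matrix = vec.fit_transform(texts)
        except ValueError as exc:  # all-stopword corpus etc.
            raise ValueError(f"TF-IDF vocabulary is empty: {exc}") from exc
        nonnegative = True
    elif extractor_id == "hashed_stub":
        vec = HashingVectorizer(
            n_features=params.pop("n_features", 64),
            alternate_sign=True,
            norm="l2",
            **params,
        )
        matrix = np.asarray(vec.transform(texts).todense())
        nonnegative = bool((matrix >= 0).all())
    elif extractor_id in _PLUGIN_EXTRACTORS:
        matrix = np.asarray(_PLUGIN_EXTRACTORS[extractor_id](texts))
        if matrix.shape[0] != len(records):
            raise ValueError(
                f"extractor plug-in {extractor_id!r} broke row alignment"
            )
        nonnegative = bool((matrix >= 0).all())
    elif extractor_id in EXTRACTORS:
        raise ValueError(
            f"extractor {extractor_id!r} needs a registered plug-in providing "
            "pretrained embeddings; see register_extractor()"
        )
    else:
        raise ValueError(f"unknown extractor {extractor_id!r}")

    zero_rows = np.asarray(abs(matrix).sum(axis=1)).ravel() == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} record(s) produced empty feature rows",
            stacklevel=2,
        )
    return FeatureMatrix(
        matrix=matrix, extractor_id=extractor_id, ids=ids, nonnegative=nonnegative
    )


def check_compatibility(classifier_id: str, features: FeatureMatrix) -> bool:
    """Naive Bayes cannot consume negative feature values; all else is fine."""
    return not (classifier_id == "nb" and not features.nonnegative)


# ---------------------------------------------------------------------------
# Balancing
# ---------------------------------------------------------------------------

def balance_training(
    labeled: Sequence[tuple[Record, int]],
    strategy: str = "dynamic_resampling",
    seed: int = 0,
    target_share: float = 0.5,
) -> list[tuple[Record, int]]:
    """Rebalance the labeled multiset before fitting.

    ``dynamic_resampling`` keeps the multiset size at ``len(labeled)`` while
    pushing the relevant-class share up toward ``target_share``: every
    relevant record is retained and replicated (round-robin) until the class
    holds ``round(target_share * n)`` slots, and the irrelevant class is
    subsampled without replacement into the remainder.  A multiset already at
    or above the target share passes through unchanged.  ``none`` is the
    identity.
    """
    labeled = list(labeled)
    rel = [(r, y) for r, y in labeled if y == 1]
    irr = [(r, y) for r, y in labeled if y == 0]
    if not rel or not irr:
        raise ValueError("balancing requires both classes in the labeled set")
    if strategy == "none":
        return labeled
    n = len(labeled)
    n_rel_target = int(round(target_share * n))
    if len(rel) >= n_rel_target:
        return labeled
    rng = np.random.default_rng(derive_seed(seed, "balance", n, len(rel)))
    rel_out = [rel[i % len(rel)] for i in range(n_rel_target)]
    n_irr_target = n - n_rel_target
    pick = rng.choice(len(irr), size=n_irr_target, replace=False)
    irr_out = [irr[i] for i in pick]
    return rel_out + irr_out


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

@dataclass
class RelevanceModel:
    """A fitted classifier exposing one contract: higher score = more relevant."""

    classifier_id: str
    estimator: object
    _proba: bool = field(default=True)

    def score(self, features) -> np.ndarray:
        if self._proba:
            proba = self.estimator.predict_proba(features)
            idx = list(self.estimator.classes_).index(1)
            return proba[:, idx]
        return self.estimator.decision_function(features)


def _build_estimator(classifier_id: str, seed: int, n_train: int):
    if classifier_id == "lr":
        return LogisticRegression(max_iter=1000, random_state=seed), True
    if classifier_id == "nb":
        return MultinomialNB(), True
    if classifier_id == "svm":
        # ranking needs only the margin; no probability calibration
        return LinearSVC(random_state=seed), False
    if classifier_id == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed), True
    if classifier_id == "nn2layer":
        hidden = max(2, min(128, n_train))
        return (
            MLPClassifier(
                hidden_layer_sizes=(hidden, hidden),
                activation="relu",
                max_iter=500,
                random_state=seed,
            ),
            True,
        )
    raise ValueError(f"unknown classifier {classifier_id!r}")


def fit_model(
    features: FeatureMatrix,
    training: Sequence[tuple[Record, int]],
    classifier_id: str,
    seed: int = 0,
) -> RelevanceModel:
    """Fit a relevance classifier on a (balanced) labeled multiset."""
    if not check_compatibility(classifier_id, features):
        raise ValueError(
            f"{classifier_id} cannot process negative feature values "
            f"from extractor {features.extractor_id!r}"
        )
    y = np.array([label for _, label in training])
    if len(set(y.tolist())) < 2:
        raise ValueError("training multiset must contain both classes")
    X = features.rows_for([r.id for r, _ in training])
    row_norms = (
        np.asarray(abs(X).sum(axis=1)).ravel()
        if sp.issparse(X)
        else np.abs(X).sum(axis=1)
    )
    for cls in (0, 1):
        if (row_norms[y == cls] == 0).all():
            raise ValueError(
                f"degenerate features: every class-{cls} training row is zero"
            )
    estimator, proba = _build_estimator(classifier_id, seed, len(training))
    with warnings.catch_warnings():
        # tiny training sets make MLP convergence warnings routine
        warnings.simplefilter("ignore")
        estimator.fit(X, y)
    return RelevanceModel(classifier_id=classifier_id, estimator=estimator,
                          _proba=proba)


def rank_candidates(
    model: RelevanceModel, features: FeatureMatrix, candidate_ids: Sequence[str]
) -> list[str]:
    """Order candidates by relevance score, descending; stable ties.

    Ties are broken by the candidates' given order (original collection
    order), via a stable sort on the negated scores.
    """
    if not candidate_ids:
        raise ValueError("no candidates to rank")
    scores = model.score(features.rows_for(candidate_ids))
    order = np.argsort(-np.asarray(scores), kind="stable")
    return [candidate_ids[i] for i in order]
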