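"""Feature extraction, compatibility, balancing, fitting, ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from screensim import (
    ALConfig,
    balance_training,
    check_compatibility,
    extract_features,
    fit_model,
    rank_candidates,
    register_extractor,
)
from screensim.engine import FeatureMatrix, RelevanceModel

from conftest import make_collection


class TestTfidf:
    def test_disjoint_token_sets_are_orthogonal(self):
        coll = make_collection([0, 0], texts=["alpha beta gamma", "delta epsilon zeta"])
        fm = extract_features(coll, "tfidf")
        X = fm.matrix.toarray()
        assert np.dot(X[0], X[1]) == pytest.approx(0.0)

    def test_idf_floor_hand_computed(self):
        """A token in every document gets idf = ln((1+N)/(1+df)) + 1 = 1."""
        coll = make_collection([0, 0], texts=["apple common", "banana common"])
        fm = extract_features(coll, "tfidf")
        X = fm.matrix.toarray()
        vocab_sorted = ["apple", "banana", "common"]
        idf_rare = math.log(3 / 2) + 1  # ln((1+2)/(1+1)) + 1
        idf_common = 1.0                # ln((1+2)/(1+2)) + 1
        raw = np.array([idf_rare, 0.0, idf_common])
        expected_row0 = raw / np.linalg.norm(raw)
        np.testing.assert_allclose(X[0], expected_row0, atol=1e-12)
        assert fm.ids == coll.ids() and len(vocab_sorted) == X.shape[1]

    def test_empty_text_gives_zero_row_with_warning(self):
        coll = make_collection([0, 0], texts=["useful words here", "q"])
        # 'q' shorter than the 2-char token pattern -> vectorises to nothing
        with pytest.warns(UserWarning, match="empty feature rows"):
            fm = extract_features(coll, "tfidf")
        assert fm.matrix.toarray()[1].sum() == 0

    def test_unknown_extractor(self, tiny_collection):
        with pytest.raises(ValueError, match="unknown extractor"):
            extract_features(tiny_collection, "bag_of_vibes")

    def test_embedding_extractor_requires_plugin(self, tiny_collection):
        with pytest.raises(ValueError, match="plug-in"):
            extract_features(tiny_collection, "sbert")

    def test_plugin_registration(self, tiny_collection):
        register_extractor("doc2vec", lambda texts: np.ones((len(texts), 4)) * -0.5)
        try:
            fm = extract_features(tiny_collection, "doc2vec")
            assert fm.matrix.shape == (tiny_collection.N, 4)
            assert not fm.nonnegative
        finally:
            from screensim.engine import _PLUGIN_EXTRACTORS

            _PLUGIN_EXTRACTORS.pop("doc2vec", None)


class TestCompatibility:
    def test_hashed_stub_is_signed(self, tiny_collection):
        fm = extract_features(tiny_collection, "hashed_stub")
        assert fm.nonnegative is False

    def test_nb_rules(self, tiny_collection):
        tfidf = extract_features(tiny_collection, "tfidf")
        hashed = extract_features(tiny_collection, "hashed_stub")
        assert check_compatibility("nb", tfidf)
        assert not check_compatibility("nb", hashed)
        for clf in ("lr", "svm", "rf", "nn2layer"):
            assert check_compatibility(clf, hashed)

    def test_fit_refuses_incompatible(self, tiny_collection):
        hashed = extract_features(tiny_collection, "hashed_stub")
        labeled = [(r, r.label) for r in tiny_collection]
        with pytest.raises(ValueError, match="negative"):
            fit_model(hashed, labeled, "nb")


class TestBalancing:
    def _labeled(self, n_rel, n_irr, coll_size=40):
        coll = make_collection([1] * n_rel + [0] * (coll_size - n_rel))
        recs = list(coll)
        return [(r, 1) for r in recs[:n_rel]] + [
            (r, 0) for r in recs[n_rel:n_rel + n_irr]
        ]

    def test_minority_relevant_upweighted(self):
        out = balance_training(self._labeled(1, 10), "dynamic_resampling", seed=1)
        assert len(out) == 11
        n_rel = sum(y for _, y in out)
        assert n_rel >= 5
        # every relevant slot is a copy of the single relevant record
        rel_ids = {r.id for r, y in out if y == 1}
        assert len(rel_ids) == 1

    def test_already_balanced_unchanged(self):
        labeled = self._labeled(5, 5)
        assert balance_training(labeled, "dynamic_resampling", seed=1) == labeled

    def test_none_strategy_is_identity(self):
        labeled = self._labeled(2, 9)
        assert balance_training(labeled, "none", seed=1) == labeled

    def test_single_class_errors(self):
        labeled = self._labeled(0, 5)
        with pytest.raises(ValueError, match="both classes"):
            balance_training(labeled, "dynamic_resampling", seed=1)


class TestFitAndRank:
    def _dummy_features(self, ids):
        return FeatureMatrix(
            matrix=np.eye(len(ids)), extractor_id="hashed_stub",
            ids=list(ids), nonnegative=True,
        )

    def _fixed_score_model(self, score_map):
        class _Est:
            def predict_proba(self_inner, X):
                raise NotImplementedError

        model = RelevanceModel("lr", _Est(), _proba=False)
        model.estimator.decision_function = lambda X: np.asarray(
            [score_map[i] for i in np.argmax(X, axis=1)]
        )
        return model

    def test_rank_by_descending_score(self):
        ids = ["a", "b", "c"]
        fm = self._dummy_features(ids)
        model = self._fixed_score_model({0: 0.2, 1: 0.9, 2: 0.5})
        assert rank_candidates(model, fm, ids) == ["b", "c", "a"]

    def test_equal_scores_preserve_order(self):
        ids = ["a", "b", "c", "d"]
        fm = self._dummy_features(ids)
        model = self._fixed_score_model(dict.fromkeys(range(4), 0.5))
        assert rank_candidates(model, fm, ids) == ids

    def test_single_candidate(self):
        fm = self._dummy_features(["only"])
        model = self._fixed_score_model({0: 0.1})
        assert rank_candidates(model, fm, ["only"]) == ["only"]

    @given(scores=st.lists(st.integers(0, 5), min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_ranking_is_permutation(self, scores):
        ids = [f"c{i}" for i in range(len(scores))]
        fm = self._dummy_features(ids)
        model = self._fixed_score_model(dict(enumerate(map(float, scores))))
        ranked = rank_candidates(model, fm, ids)
        assert sorted(ranked) == sorted(ids)

    def test_separable_case_lr_ranks_perfectly(self, tiny_collection):
        fm = extract_features(tiny_collection, "tfidf")
        labeled = [(r, r.label) for r in tiny_collection]
        model = fit_model(fm, labeled, "lr", seed=0)
        ranked = rank_candidates(model, fm, tiny_collection.ids())
        labels_in_rank = [tiny_collection.by_id(i).label for i in ranked]
        assert labels_in_rank == sorted(labels_in_rank, reverse=True)

    @pytest.mark.parametrize("clf", ["lr", "nb", "svm", "rf", "nn2layer"])
    def test_deterministic_given_seed(self, clf, medium_corpus):
        fm = extract_features(medium_corpus, "tfidf")
        labeled = [(r, r.label) for r in list(medium_corpus)[:60]]
        if sum(y for _, y in labeled) == 0:
            labeled.append((medium_corpus.relevant()[0], 1))
        ids = medium_corpus.ids()[:50]

        def scores():
            model = fit_model(fm, labeled, clf, seed=42)
            return model.score(fm.rows_for(ids))

        np.testing.assert_array_equal(scores(), scores())

    def test_nn2layer_tiny_training_set(self, tiny_collection):
        fm = extract_features(tiny_collection, "tfidf")
        recs = list(tiny_collection)
        labeled = [(recs[0], 1), (recs[3], 1), (recs[1], 0), (recs[2], 0)]
        model = fit_model(fm, labeled, "nn2layer", seed=0)
        assert np.isfinite(model.score(fm.rows_for(tiny_collection.ids()))).all()

    def test_degenerate_features_rejected(self):
        fm = FeatureMatrix(
            matrix=np.vstack([np.zeros(3), np.ones(3)]),
            extractor_id="tfidf",
            ids=["z", "o"],
            nonnegative=True,
        )
        coll = make_collection([1, 0])
        labeled = [(coll[0], 1), (coll[1], 0)]
        fm.ids = coll.ids()
        with pytest.raises(ValueError, match="degenerate"):
            fit_model(fm, labeled, "lr")

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ALConfig(classifier_id="gpt")
        with pytest.raises(ValueError):
            ALConfig(retrain_interval=0)
        assert ALConfig().name == "lr+tfidf"


def test_near_separable_corpus_ranked_perfectly_after_1plus1_training():
    """On full-signal, zero-noise corpora, LR + TF-IDF trained on one relevant
    and one irrelevant record ranks all relevant screening records above all
    irrelevant ones in >= 90% of seeds."""
    from screensim import SyntheticCorpusSpec, generate_corpus

    wins = 0
    n_seeds = 20
    for seed in range(n_seeds):
        coll = generate_corpus(
            SyntheticCorpusSpec(
                n_total=150, prevalence=0.1, signal_strength=1.0,
                noise_rate=0.0, doc_length_mean=20, seed=seed,
            )
        )
        fm = extract_features(coll, "tfidf")
        training = [(coll.relevant()[0], 1), (coll.irrelevant()[0], 0)]
        model = fit_model(fm, training, "lr", seed=seed)
        train_ids = {r.id for r, _ in training}
        candidates = [i for i in coll.ids() if i not in train_ids]
        ranked = rank_candidates(model, fm, candidates)
        labels = [coll.by_id(i).label for i in ranked]
        if labels == sorted(labels, reverse=True):
            wins += 1
    assert wins >= 0.9 * n_seeds
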