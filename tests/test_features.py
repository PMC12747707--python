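import math

import numpy as np
import pytest

from fscnlp.features import (
    FeatureSelectionConfig,
    build_dfm,
    prerank,
    project,
    rfe_select,
    tfidf,
    top_features_per_class,
)
from fscnlp.nb import fit_nb
from fscnlp.preprocess import NGramDoc, default_dutch_config, preprocess_corpus
from fscnlp.synthetic import paper_calibrated_config, generate_corpus


def docs_from(feature_lists) -> list[NGramDoc]:
    return [NGramDoc(id=f"d{i}", features=tuple(fs)) for i, fs in enumerate(feature_lists)]


class TestBuildDfm:
    def test_toy_counts(self):
        dfm = build_dfm(docs_from([["a", "a", "b"], ["a"]]))
        assert dfm.feature_names == ("a", "b")
        assert dfm.counts.toarray().tolist() == [[2, 1], [1, 0]]

    def test_single_doc(self):
        dfm = build_dfm(docs_from([["x", "y", "x"]]))
        assert dfm.counts.shape == (1, 2)

    def test_row_sums_equal_feature_list_lengths(self):
        corpus, _ = generate_corpus(paper_calibrated_config(n_letters=60, seed=21))
        docs = preprocess_corpus(corpus, default_dutch_config())
        dfm = build_dfm(docs)
        row_sums = np.asarray(dfm.counts.sum(axis=1)).ravel()
        assert row_sums.tolist() == [len(d.features) for d in docs]

    def test_feature_order_lexicographic_and_no_zero_columns(self):
        dfm = build_dfm(docs_from([["b", "a"], ["c"]]))
        assert dfm.feature_names == ("a", "b", "c")
        assert (np.asarray(dfm.counts.sum(axis=0)).ravel() > 0).all()

    def test_empty_docs_error(self):
        with pytest.raises(ValueError):
            build_dfm([])
        with pytest.raises(ValueError):
            build_dfm(docs_from([[], []]))


class TestTfidf:
    def test_hand_computed_weights(self):
        wm = tfidf(build_dfm(docs_from([["a", "b"], ["b"]])))
        # a: df=1 of N=2 -> idf = log10(2); b: df=2 -> idf = 0
        a = wm.feature_names.index("a")
        b = wm.feature_names.index("b")
        assert wm.weights[0, a] == pytest.approx(math.log10(2), abs=1e-12)
        assert wm.idf[b] == 0.0
        assert wm.weights[:, b].toarray().ravel().tolist() == [0.0, 0.0]

    def test_linearity_in_term_frequency(self):
        wm1 = tfidf(build_dfm(docs_from([["a", "c"], ["c"]])))
        wm2 = tfidf(build_dfm(docs_from([["a", "a", "c"], ["c"]])))
        a1 = wm1.weights[0, wm1.feature_names.index("a")]
        a2 = wm2.weights[0, wm2.feature_names.index("a")]
        assert a2 == pytest.approx(2 * a1, abs=1e-12)

    def test_sparsity_pattern_preserved_except_df_equals_n(self):
        corpus, _ = generate_corpus(paper_calibrated_config(n_letters=40, seed=22))
        dfm = build_dfm(preprocess_corpus(corpus, default_dutch_config()))
        wm = tfidf(dfm)
        everywhere = wm.idf == 0
        counts = dfm.counts.toarray()
        weights = wm.weights.toarray()
        assert ((weights != 0) == ((counts != 0) & ~everywhere[None, :])).all()


class TestPrerank:
    def test_ordering_by_column_sum(self):
        docs = docs_from([["a"] * 5 + ["c"] * 3 + ["b"], ["a", "c"]])
        wm = tfidf(build_dfm(docs))
        sums = {f: s for f, s in zip(wm.feature_names, wm.column_sums())}
        expected = sorted(wm.feature_names, key=lambda f: (-sums[f], f))[:2]
        assert prerank(wm, 2) == expected

    def test_k_exceeding_vocabulary_returns_all(self):
        wm = tfidf(build_dfm(docs_from([["a", "b"], ["b", "c"]])))
        assert sorted(prerank(wm, 100)) == ["a", "b", "c"]

    def test_tie_break_lexicographic(self):
        wm = tfidf(build_dfm(docs_from([["b", "a"], ["c", "d"]])))
        # all four features have identical tf-idf mass
        assert prerank(wm, 2) == ["a", "b"]


def _toy_labeled_matrix(n_per_class=10, seed=0):
    """Docs with one class-pure feature, one uninformative feature."""
    rng = np.random.default_rng(seed)
    docs, labels = [], []
    for i in range(n_per_class):
        docs.append(["pure", "noise"] * int(rng.integers(1, 4)) + ["filler"])
        labels.append("epilepsy")
    for i in range(n_per_class):
        docs.append(["noise"] * int(rng.integers(1, 4)) + ["filler"])
        labels.append("no_epilepsy")
    return docs_from(docs), labels


class TestRfeSelect:
    def test_pure_feature_outranks_uninformative(self):
        docs, labels = _toy_labeled_matrix()
        wm = tfidf(build_dfm(docs))
        sel = rfe_select(wm, labels, FeatureSelectionConfig(prerank_k=3, final_k=2, cv_folds=3, seed=0))
        assert "pure" in sel.names
        assert sel.names.index("pure") < len(sel.names) - 1 or "noise" not in sel.names

    def test_final_k_equal_to_available_returns_all(self):
        docs, labels = _toy_labeled_matrix()
        wm = tfidf(build_dfm(docs))
        sel = rfe_select(wm, labels, FeatureSelectionConfig(prerank_k=3, final_k=3, cv_folds=3, seed=0))
        assert sorted(sel.names) == ["filler", "noise", "pure"]

    def test_deterministic_and_document_order_invariant(self):
        corpus, _ = generate_corpus(paper_calibrated_config(n_letters=120, seed=30))
        binary = corpus.subset(l.id for l in corpus if l.final_dx != "unclear")
        docs = preprocess_corpus(binary, default_dutch_config())
        labels = [l.final_dx for l in binary]
        wm = tfidf(build_dfm(docs))
        cfg = FeatureSelectionConfig(prerank_k=400, final_k=50, cv_folds=3, seed=4)
        sel1 = rfe_select(wm, labels, cfg)
        sel2 = rfe_select(wm, labels, cfg)
        assert sel1.names == sel2.names
        # reversed document order, same fold seed: selection must not change
        perm = list(range(len(docs)))[::-1]
        docs_r = [docs[i] for i in perm]
        labels_r = [labels[i] for i in perm]
        wm_r = tfidf(build_dfm(docs_r))
        sel3 = rfe_select(wm_r, labels_r, cfg)
        assert set(sel3.names) == set(sel1.names)

    def test_single_class_labels_rejected(self):
        docs, _ = _toy_labeled_matrix()
        wm = tfidf(build_dfm(docs))
        with pytest.raises(ValueError):
            rfe_select(wm, ["epilepsy"] * len(docs), FeatureSelectionConfig(prerank_k=3, final_k=2))


class TestProject:
    def test_unseen_features_give_zero_row(self):
        train = docs_from([["a", "b"], ["b"]])
        wm = tfidf(build_dfm(train))
        test = docs_from([["zzz", "qqq"]])
        W = project(test, list(wm.feature_names), wm.idf_table)
        assert W.weights.toarray().tolist() == [[0.0, 0.0]]

    def test_training_doc_projects_to_its_own_row(self):
        train = docs_from([["a", "b", "a"], ["b", "c"]])
        wm = tfidf(build_dfm(train))
        W = project(train, list(wm.feature_names), wm.idf_table)
        assert np.allclose(W.weights.toarray(), wm.weights.toarray())

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            project(docs_from([["a"]]), [], {})

    def test_test_set_cannot_influence_fitted_objects(self):
        corpus, _ = generate_corpus(paper_calibrated_config(n_letters=100, seed=31))
        binary = corpus.subset(l.id for l in corpus if l.final_dx != "unclear")
        docs = preprocess_corpus(binary, default_dutch_config())
        labels = [l.final_dx for l in binary]
        wm = tfidf(build_dfm(docs))
        cfg = FeatureSelectionConfig(prerank_k=300, final_k=40, cv_folds=3, seed=1)
        sel = rfe_select(wm, labels, cfg)
        idf_before = dict(wm.idf_table)
        names_before = tuple(sel.names)
        # project two different "test sets"; fitted objects must be untouched
        project(docs_from([["trekkingen"]]), sel, wm.idf_table)
        project(docs_from([["flauwvallen", "duizelig"]]), sel, wm.idf_table)
        assert wm.idf_table == idf_before
        assert tuple(sel.names) == names_before


class TestTopFeaturesPerClass:
    def _toy_model(self):
        docs = docs_from(
            [["drooled", "filler"], ["drooled", "filler"], ["dizzy", "filler"], ["dizzy", "filler"]]
        )
        labels = ["epilepsy", "epilepsy", "no_epilepsy", "no_epilepsy"]
        dfm = build_dfm(docs)
        return fit_nb(dfm.counts, labels, alpha=0.5, vocabulary=dfm.feature_names)

    def test_class_pure_feature_heads_its_list(self):
        top = top_features_per_class(self._toy_model(), m=2)
        assert top["epilepsy"][0][0] == "drooled"
        assert top["no_epilepsy"][0][0] == "dizzy"

    def test_symmetry_under_label_swap(self):
        docs = docs_from(
            [["drooled", "filler"], ["drooled", "filler"], ["dizzy", "filler"], ["dizzy", "filler"]]
        )
        dfm = build_dfm(docs)
        m1 = fit_nb(dfm.counts, ["epilepsy", "epilepsy", "no_epilepsy", "no_epilepsy"], alpha=0.5, vocabulary=dfm.feature_names)
        m2 = fit_nb(dfm.counts, ["no_epilepsy", "no_epilepsy", "epilepsy", "epilepsy"], alpha=0.5, vocabulary=dfm.feature_names)
        t1, t2 = top_features_per_class(m1, m=3), top_features_per_class(m2, m=3)
        assert [f for f, _ in t1["epilepsy"]] == [f for f, _ in t2["no_epilepsy"]]

    def test_m_zero_and_m_truncation(self):
        model = self._toy_model()
        assert top_features_per_class(model, m=0) == {"epilepsy": [], "no_epilepsy": []}
        top = top_features_per_class(model, m=99)
        assert len(top["epilepsy"]) == len(model.vocabulary)
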