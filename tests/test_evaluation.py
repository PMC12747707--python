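import math

import numpy as np
import pytest

from fscnlp.corpus_io import Corpus
from fscnlp.evaluation import (
    AnalysisConfig,
    ConfusionMatrix,
    analysis_b_testset,
    compute_metrics,
    confusion,
    mcnemar,
    run_analysis_a,
    run_analysis_b,
    stratified_split,
)
from fscnlp.features import FeatureSelectionConfig
from fscnlp.pipeline import NBArmConfig
from fscnlp.synthetic import (
    SynthConfig,
    default_vocab_spec,
    VocabSpec,
    generate_corpus,
    paper_calibrated_config,
)

from conftest import make_corpus, make_letter


def small_analysis_config(**kwargs) -> AnalysisConfig:
    return AnalysisConfig(
        nb=NBArmConfig(
            selection=FeatureSelectionConfig(prerank_k=500, final_k=60, cv_folds=3),
            alpha_grid=(1.0,),
            cv_folds=3,
        ),
        **kwargs,
    )


class TestStratifiedSplit:
    def test_exact_proportions_single_site(self):
        letters = [("tekst nummer %d hier" % i, "epilepsy") for i in range(40)]
        letters += [("andere tekst %d" % i, "no_epilepsy") for i in range(60)]
        corpus = make_corpus(letters)
        split = stratified_split(corpus, test_fraction=0.2, seed=0)
        test = corpus.subset(split.test_ids)
        assert len(split.test_ids) == 20
        assert sum(l.final_dx == "epilepsy" for l in test) == 8
        assert sum(l.final_dx == "no_epilepsy" for l in test) == 12

    def test_deterministic_and_disjoint(self):
        corpus, _ = generate_corpus(paper_calibrated_config(n_letters=200, seed=8))
        s1 = stratified_split(corpus, seed=5)
        s2 = stratified_split(corpus, seed=5)
        assert s1 == s2
        assert not set(s1.train_ids) & set(s1.test_ids)

    def test_final_unclear_letters_are_not_eligible(self):
        corpus, _ = generate_corpus(paper_calibrated_config(n_letters=300, seed=9))
        split = stratified_split(corpus, seed=1)
        ids = set(split.train_ids) | set(split.test_ids)
        assert ids == {l.id for l in corpus if l.final_dx != "unclear"}

    def test_tiny_stratum_goes_to_train_with_warning(self):
        corpus = make_corpus(
            [("een brief tekst", "epilepsy")] + [("brief %d" % i, "no_epilepsy") for i in range(10)]
        )
        with pytest.warns(UserWarning, match="stratum"):
            split = stratified_split(corpus, seed=0)
        assert "L000" in split.train_ids

    def test_paper_scale_split_sizes(self):
        corpus, _ = generate_corpus(paper_calibrated_config(n_letters=1561, seed=12))
        split = stratified_split(corpus, test_fraction=0.2, seed=12)
        n_eligible = sum(l.final_dx != "unclear" for l in corpus)
        assert len(split.train_ids) + len(split.test_ids) == n_eligible
        # 80/20 of ~1472 eligible letters: about 1173 train / 293 test
        assert abs(len(split.test_ids) - round(0.2 * n_eligible)) <= 4  # stratum rounding
        assert math.isclose(len(split.test_ids) / n_eligible, 0.2, abs_tol=0.01)


class TestAnalysisBTestset:
    def test_membership_rules(self):
        corpus = Corpus(
            (
                make_letter(id="in1", initial_dx="unclear", final_dx="epilepsy"),
                make_letter(id="in2", initial_dx="unclear", final_dx="no_epilepsy"),
                make_letter(id="out1", initial_dx="unclear", final_dx="unclear"),
                make_letter(id="out2", initial_dx="epilepsy", final_dx="epilepsy"),
            )
        )
        assert analysis_b_testset(corpus) == ("in1", "in2")

    def test_empty_result_warns(self):
        corpus = Corpus((make_letter(id="a", initial_dx="epilepsy", final_dx="epilepsy"),))
        with pytest.warns(UserWarning):
            assert analysis_b_testset(corpus) == ()


class TestConfusion:
    def test_perfect_classifier(self):
        truth = ["epilepsy"] * 10 + ["no_epilepsy"] * 20
        cm = confusion(truth, truth)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (10, 20, 0, 0)

    def test_all_positive_predictions(self):
        truth = ["epilepsy"] * 10 + ["no_epilepsy"] * 20
        cm = confusion(["epilepsy"] * 30, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (10, 20, 0, 0)

    def test_published_embedding_counts_sum_to_test_size(self):
        cm = ConfusionMatrix(tp=40, tn=176, fp=62, fn=15)
        assert cm.n_total == 293

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(["epilepsy"], ["epilepsy", "no_epilepsy"])

    def test_n_total_override_cannot_undercount(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=5, tn=5, fp=0, fn=0, n_total=8)


class TestComputeMetrics:
    def test_published_analysis_a_nb_accuracy(self):
        # printed counts with the printed denominator of 293
        cm = ConfusionMatrix(tp=62, tn=153, fp=40, fn=30, n_total=293)
        rep = compute_metrics(cm)
        assert rep.accuracy.value == pytest.approx(215 / 293)
        assert round(rep.accuracy.value, 2) == 0.73

    def test_perfect_matrix_all_ones(self):
        rep = compute_metrics(ConfusionMatrix(tp=10, tn=20, fp=0, fn=0))
        for m in (rep.accuracy, rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert m.value == 1.0
            assert m.ci_high == 1.0

    def test_exact_ci_small_sample(self):
        rep = compute_metrics(ConfusionMatrix(tp=1, fn=1, fp=0, tn=0))
        assert rep.sensitivity.value == 0.5
        assert rep.sensitivity.ci_low == pytest.approx(0.0126, abs=5e-4)
        assert rep.sensitivity.ci_high == pytest.approx(0.9874, abs=5e-4)

    def test_undefined_ratio_flagged_not_zero(self):
        rep = compute_metrics(ConfusionMatrix(tp=0, fn=0, fp=5, tn=5))
        assert not rep.sensitivity.defined
        assert math.isnan(rep.sensitivity.value)
        assert rep.specificity.defined

    def test_ci_boundaries_at_extremes(self):
        rep = compute_metrics(ConfusionMatrix(tp=0, fn=10, fp=0, tn=10))
        assert rep.sensitivity.ci_low == 0.0
        assert rep.specificity.ci_high == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_accuracy_prevalence_identity(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, fn, tn = (int(x) for x in rng.integers(1, 50, size=4))
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
        rep = compute_metrics(cm)
        prev = (tp + fn) / cm.n_total
        lhs = rep.accuracy.value
        rhs = rep.sensitivity.value * prev + rep.specificity.value * (1 - prev)
        assert abs(lhs - rhs) < 1e-12

    def test_wilson_and_wald_methods_available(self):
        cm = ConfusionMatrix(tp=30, tn=40, fp=10, fn=20)
        for method in ("wilson", "normal"):
            rep = compute_metrics(cm, ci_method=method)
            assert rep.accuracy.ci_low < rep.accuracy.value < rep.accuracy.ci_high

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(tp=0, fp=0, fn=0, tn=0))


class TestMcNemar:
    def test_closed_form_with_correction(self):
        correct1 = [True] * 5 + [False] * 10 + [True] * 35
        correct2 = [False] * 5 + [True] * 10 + [True] * 35
        res = mcnemar(correct1, correct2, correction=True)
        assert (res.b, res.c) == (5, 10)
        assert res.chi2 == pytest.approx(16 / 15, abs=1e-9)
        assert res.p == pytest.approx(0.3017, abs=5e-4)

    def test_balanced_discordance_uncorrected(self):
        correct1 = [True, False] * 6
        correct2 = [False, True] * 6
        res = mcnemar(correct1, correct2, correction=False)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_identical_models(self):
        same = [True, False, True, True]
        res = mcnemar(same, same)
        assert res.b == res.c == 0
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_symmetry_under_model_swap(self):
        rng = np.random.default_rng(3)
        c1 = rng.random(100) < 0.7
        c2 = rng.random(100) < 0.75
        r12 = mcnemar(c1, c2)
        r21 = mcnemar(c2, c1)
        assert r12.chi2 == r21.chi2 and r12.p == r21.p

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(9)
        c1 = rng.random(200) < 0.7
        c2 = rng.random(200) < 0.72
        ours = mcnemar(c1, c2, correction=True)
        table = [
            [int(np.sum(c1 & c2)), int(np.sum(c1 & ~c2))],
            [int(np.sum(~c1 & c2)), int(np.sum(~c1 & ~c2))],
        ]
        sm = sm_mcnemar(table, exact=False, correction=True)
        assert ours.chi2 == pytest.approx(float(sm.statistic), abs=1e-9)
        assert ours.p == pytest.approx(float(sm.pvalue), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mcnemar([True], [True, False])


class TestAnalyses:
    def test_signal_free_corpus_yields_majority_rate(self):
        base = default_vocab_spec()
        vocab = VocabSpec(
            background=base.background,
            stopwords=base.stopwords,
            epilepsy_signal={k: 1.0 for k in list(base.epilepsy_signal)[:5]},
            control_signal={k: 1.0 for k in list(base.control_signal)[:5]},
        )
        cfg = SynthConfig(n_letters=400, vocab_spec=vocab, seed=77)
        corpus, _ = generate_corpus(cfg)
        rep = run_analysis_a(corpus, small_analysis_config(), seed=77)
        test = corpus.subset(
            set(l.id for l in corpus if l.final_dx != "unclear")
        )
        majority = 0.614 / (0.329 + 0.614)
        for entry in rep.models.values():
            acc = entry["metrics"]["accuracy"]["value"]
            se = math.sqrt(majority * (1 - majority) / rep.n_test)
            assert abs(acc - majority) < 3 * se + 0.05

    def test_analysis_a_report_structure_and_discipline(self):
        corpus, _ = generate_corpus(paper_calibrated_config(n_letters=350, seed=21))
        rep = run_analysis_a(corpus, small_analysis_config(), seed=21)
        assert set(rep.models) == {"nb", "embed"}
        assert rep.mcnemar is not None and rep.mcnemar["df"] == 1
        assert rep.top_features is not None
        cm = rep.models["nb"]["confusion"]
        assert cm["tp"] + cm["fp"] + cm["fn"] + cm["tn"] == rep.n_test
        assert rep.n_train + rep.n_test == sum(
            1 for l in corpus if l.final_dx != "unclear" and l.word_count >= 20
        )

    def test_analysis_b_testset_disjoint_from_training(self):
        corpus, _ = generate_corpus(paper_calibrated_config(n_letters=350, seed=22))
        rep = run_analysis_b(corpus, small_analysis_config(), seed=22)
        test_ids = set(analysis_b_testset(corpus))
        assert rep.n_test == len([l for l in corpus if l.id in test_ids and l.word_count >= 20])
        assert rep.n_train + rep.n_test == sum(
            1 for l in corpus if l.final_dx != "unclear" and l.word_count >= 20
        )

    def test_corpus_without_initially_unclear_warns(self):
        letters = [
            make_letter(id=f"L{i}", text="brief tekst nummer %d woorden" % i,
                        initial_dx="epilepsy" if i % 3 else "no_epilepsy",
                        final_dx="epilepsy" if i % 3 else "no_epilepsy")
            for i in range(30)
        ]
        # fix initial == final so no letter is initially unclear
        corpus = Corpus(tuple(letters))
        with pytest.warns(UserWarning):
            analysis_b_testset(corpus)

    def test_mcnemar_of_model_against_itself_is_null(self):
        corpus, _ = generate_corpus(paper_calibrated_config(n_letters=250, seed=23))
        cfg = small_analysis_config()
        r1 = run_analysis_a(corpus, cfg, seed=23)
        r2 = run_analysis_a(corpus, cfg, seed=23)
        c1 = r1.models["nb"]["confusion"]
        c2 = r2.models["nb"]["confusion"]
        assert c1 == c2  # identical run -> identical predictions
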