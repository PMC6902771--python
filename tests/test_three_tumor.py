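import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirindex import preprocess, simulate, three_tumor
from mirindex.lasso_logistic import BinaryLassoModel

CLASSES = ("GBM", "PCNSL", "metastatic")


def _forced_model(positive_label, call_positive, mirna_ids=("m1", "m2"), n_active=0):
    """A model whose probability is saturated, forcing the requested binary call."""
    k = len(mirna_ids)
    coefs = np.zeros(k)
    coefs[:n_active] = 1e-9  # active but negligible, for sparsity bookkeeping
    return BinaryLassoModel(
        mirna_ids=list(mirna_ids),
        coefficients=coefs,
        intercept=50.0 if call_positive else -50.0,
        lambda_=0.1,
        positive_label=positive_label,
        negative_label="others",
        center=np.zeros(k),
        scale=np.ones(k),
    )


class TestDecisionTable:
    def test_exhaustive_truth_table_over_all_pairings(self):
        sample = {"m1": 0.0, "m2": 0.0}
        pairings = [
            (CLASSES[0], CLASSES[1], CLASSES[2]),
            (CLASSES[1], CLASSES[2], CLASSES[0]),
            (CLASSES[0], CLASSES[2], CLASSES[1]),
        ]
        for a, b, c in pairings:
            for call_a, call_b in itertools.product([True, False], repeat=2):
                model = three_tumor.combine_binary(
                    _forced_model(a, call_a), _forced_model(b, call_b), (a, b, c)
                )
                expected = {
                    (True, False): a,
                    (False, True): b,
                    (False, False): c,
                    (True, True): three_tumor.NOT_DETERMINED,
                }[(call_a, call_b)]
                assert three_tumor.classify_three(model, sample) == expected

    def test_double_positive_is_not_determined(self):
        model = three_tumor.combine_binary(
            _forced_model("GBM", True), _forced_model("PCNSL", True), CLASSES
        )
        assert three_tumor.classify_three(model, {"m1": 0, "m2": 0}) == "not_determined"

    def test_identical_positive_classes_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            three_tumor.combine_binary(
                _forced_model("GBM", True), _forced_model("GBM", False), CLASSES
            )

    def test_decision_table_covers_all_four_outcomes(self):
        model = three_tumor.combine_binary(
            _forced_model("GBM", True), _forced_model("PCNSL", False), CLASSES
        )
        table = model.decision_table
        assert set(table.keys()) == set(itertools.product([True, False], repeat=2))
        assert set(table.values()) == {"GBM", "PCNSL", "metastatic", "not_determined"}


class TestCrossTab:
    def test_all_correct_is_diagonal(self):
        truths = ["GBM"] * 4 + ["PCNSL"] * 3 + ["metastatic"] * 2
        tab = three_tumor.cross_tabulate(truths, truths, CLASSES)
        assert tab.counts.loc["GBM", "GBM"] == 4
        assert tab.counts.values.sum() == 9
        off = tab.counts.values.sum() - np.trace(tab.counts.values[:3, :3])
        assert off == 0

    def test_column_fractions(self):
        truths = ["GBM"] * 10
        preds = ["GBM"] * 9 + ["PCNSL"]
        tab = three_tumor.cross_tabulate(preds, truths, CLASSES)
        np.testing.assert_allclose(tab.fractions["GBM"].values, [0.9, 0.1, 0.0, 0.0])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            three_tumor.cross_tabulate(["GBM"], ["astrocytoma"], CLASSES)

    @settings(max_examples=30, deadline=None)
    @given(
        preds=st.lists(
            st.sampled_from(list(CLASSES) + [three_tumor.NOT_DETERMINED]),
            min_size=1, max_size=30,
        ),
        seed=st.integers(0, 1000),
    )
    def test_columns_conserve_class_counts(self, preds, seed):
        rng = np.random.default_rng(seed)
        truths = rng.choice(CLASSES, len(preds))
        tab = three_tumor.cross_tabulate(preds, truths, CLASSES)
        for g in CLASSES:
            assert tab.counts[g].sum() == (truths == g).sum()


class TestRepresentativeSelection:
    def _data(self, rng, n=30):
        X = rng.normal(size=(n, 2))
        labels = np.array(
            ["GBM"] * (n // 2) + ["PCNSL"] * (n // 4) + ["metastatic"] * (n - n // 2 - n // 4),
            dtype=object,
        )
        return X, labels

    def test_single_candidate_returned_unchanged(self, rng):
        X, labels = self._data(rng)
        cand = three_tumor.combine_binary(
            _forced_model("GBM", True), _forced_model("PCNSL", False), CLASSES
        )
        winner, acc = three_tumor.select_representative([cand], X, ["m1", "m2"], labels)
        assert winner is cand
        assert acc == (labels == "GBM").mean()  # always calls GBM

    def test_higher_accuracy_wins(self, rng):
        X, labels = self._data(rng)
        always_gbm = three_tumor.combine_binary(
            _forced_model("GBM", True), _forced_model("PCNSL", False), CLASSES
        )
        always_met = three_tumor.combine_binary(
            _forced_model("GBM", False), _forced_model("PCNSL", False), CLASSES
        )
        winner, acc = three_tumor.select_representative(
            [always_met, always_gbm], X, ["m1", "m2"], labels
        )
        assert winner is always_gbm  # GBM is the majority class here

    def test_sparser_candidate_wins_ties(self, rng):
        X, labels = self._data(rng)
        dense = three_tumor.combine_binary(
            _forced_model("GBM", True, n_active=2),
            _forced_model("PCNSL", False, n_active=2),
            CLASSES,
        )
        sparse = three_tumor.combine_binary(
            _forced_model("GBM", True, n_active=1),
            _forced_model("PCNSL", False, n_active=1),
            CLASSES,
        )
        winner, _ = three_tumor.select_representative(
            [dense, sparse], X, ["m1", "m2"], labels
        )
        assert winner is sparse

    def test_no_candidates_rejected(self, rng):
        X, labels = self._data(rng)
        with pytest.raises(ValueError):
            three_tumor.select_representative([], X, ["m1", "m2"], labels)


class TestStratifiedSplit:
    def test_printed_cohort_composition(self):
        labels = np.array(
            ["GBM"] * 85 + ["PCNSL"] * 42 + ["metastatic"] * 28, dtype=object
        )
        mask = three_tumor.stratified_split(labels, 0.8, np.random.default_rng(0))
        got = {
            g: ((labels[mask] == g).sum(), (labels[~mask] == g).sum())
            for g in CLASSES
        }
        assert got == {"GBM": (68, 17), "PCNSL": (34, 8), "metastatic": (23, 5)}

    def test_tiny_class_rejected(self):
        labels = np.array(["A"] * 10 + ["B"], dtype=object)
        with pytest.raises(ValueError, match="too small"):
            three_tumor.stratified_split(labels, 0.8, np.random.default_rng(0))


@pytest.fixture(scope="module")
def cohort(tiny_three_tumor):
    raw, ann, truth = tiny_three_tumor
    norm, report = preprocess.preprocess_pipeline(raw, ann)
    cands = [
        m for m in report.kept_mirnas if m not in set(preprocess.DEFAULT_CONTROLS)
    ]
    X = norm.log2_for(cands)
    labels = ann.groups_for(norm.sample_ids)
    return X, labels, cands, truth


class TestRepeatedModels:
    def test_same_master_seed_reproduces_models(self, cohort):
        X, labels, cands, _ = cohort
        a = three_tumor.repeated_binary_models(
            X, labels, "GBM", mirna_ids=cands, n_repeats=2, seed=3, n_folds=5
        )
        b = three_tumor.repeated_binary_models(
            X, labels, "GBM", mirna_ids=cands, n_repeats=2, seed=3, n_folds=5
        )
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(
                ra.model.coefficients, rb.model.coefficients
            )
            assert ra.heldout_auc == rb.heldout_auc

    def test_single_repeat_is_one_split_fit(self, cohort):
        X, labels, cands, _ = cohort
        summary = three_tumor.repeated_binary_models(
            X, labels, "PCNSL", mirna_ids=cands, n_repeats=1, seed=0, n_folds=5
        )
        assert len(summary.records) == 1
        assert 0.0 <= summary.records[0].heldout_auc <= 1.0

    def test_strong_signatures_build_accurate_index(self, cohort):
        X, labels, cands, _ = cohort
        result = three_tumor.build_three_tumor_index(
            X, labels, cands, classes=CLASSES, n_repeats=2, seed=1, n_folds=5
        )
        assert result.training_accuracy >= 0.8
        # obvious-GBM sample: every GBM marker pushed 4 log2 units up/down
        preds = three_tumor.classify_matrix(result.representative, X, cands)
        gbm_sens = (preds[labels == "GBM"] == "GBM").mean()
        assert gbm_sens >= 0.8


def test_null_effects_classify_at_baseline_rate():
    """With no planted markers both binary models stay near-empty and nearly
    everything lands in the residual class, so 3-class accuracy sits near 1/3."""
    accs = []
    for rep in range(20):
        cfg = simulate.three_tumor_config(
            seed=500 + rep,
            n_mirnas=30,
            group_sizes={"GBM": 20, "PCNSL": 20, "metastatic": 20},
            marker_effects={},
        )
        raw, ann, _ = simulate.generate_cohort(cfg)
        norm, report = preprocess.preprocess_pipeline(raw, ann)
        cands = [
            m for m in report.kept_mirnas
            if m not in set(preprocess.DEFAULT_CONTROLS)
        ]
        X = norm.log2_for(cands)
        labels = ann.groups_for(norm.sample_ids)
        mask = three_tumor.stratified_split(labels, 0.8, np.random.default_rng(rep))
        result = three_tumor.build_three_tumor_index(
            X[mask], labels[mask], cands, classes=CLASSES,
            n_repeats=1, seed=rep, n_folds=5,
        )
        preds = three_tumor.classify_matrix(result.representative, X[~mask], cands)
        accs.append(three_tumor.three_class_accuracy(preds, labels[~mask]))
    assert np.mean(accs) == pytest.approx(1 / 3, abs=0.1)
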