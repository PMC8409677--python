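"""Tukey grouping, factor analysis, discriminant classification."""

import numpy as np
import pytest

from melissoscope import stats
from melissoscope.book import DESCRIPTORS
from melissoscope.errors import (ContractViolation, DegenerateDataError)
from melissoscope.stackio import FeatureTable


def _table_from_column(values_by_taxon, descriptor="length"):
    """Feature table with one meaningful descriptor, rest constant 1.0."""
    records = []
    for taxon, values in values_by_taxon.items():
        for i, v in enumerate(values):
            row = {d: 1.0 for d in DESCRIPTORS}
            row[descriptor] = float(v)
            row.update(grain_id=f"{taxon}:{i}", taxon=taxon, modality="BF")
            records.append(row)
    return FeatureTable.from_records(records)


class TestTukeyLetters:
    def test_far_separated_groups_get_distinct_letters(self, rng):
        table = _table_from_column({
            "A": rng.normal(0, 1, 50), "B": rng.normal(10, 1, 50)})
        g = stats.tukey_letters(table, "length")
        assert set(g.letters["A"]) & set(g.letters["B"]) == set()

    def test_identical_groups_share_a_letter(self, rng):
        vals = rng.normal(5, 1, 40)
        table = _table_from_column({"A": vals, "B": vals + rng.normal(0, 0.01, 40)})
        g = stats.tukey_letters(table, "length")
        assert g.letters["A"] == g.letters["B"] == "a"

    def test_letters_encode_pairwise_decisions(self, rng):
        """Compact letters are consistent with the studentized-range
        decisions computed independently (Tukey–Kramer oracle)."""
        from scipy.stats import studentized_range
        groups = {"A": rng.normal(0, 1, 10), "B": rng.normal(1.2, 1, 12),
                  "C": rng.normal(3.0, 1, 10)}
        table = _table_from_column(groups)
        g = stats.tukey_letters(table, "length")
        names = list(groups)
        k = len(names)
        n_tot = sum(len(v) for v in groups.values())
        mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / (n_tot - k)
        for i in range(k):
            for j in range(i + 1, k):
                a, b = names[i], names[j]
                se = np.sqrt(mse / 2 * (1 / len(groups[a]) + 1 / len(groups[b])))
                q = abs(groups[a].mean() - groups[b].mean()) / se
                p = studentized_range.sf(q, k, n_tot - k)
                share = bool(set(g.letters[a]) & set(g.letters[b]))
                assert share == (p >= 0.05)

    def test_degenerate_data_rejected(self):
        table = _table_from_column({"A": [1.0] * 5, "B": [1.0] * 5})
        with pytest.raises(DegenerateDataError):
            stats.tukey_letters(table, "length")

    def test_needs_two_taxa(self, rng):
        table = _table_from_column({"A": rng.normal(0, 1, 5)})
        with pytest.raises(ContractViolation):
            stats.tukey_letters(table, "length")


class TestFactorModel:
    def test_two_variable_closed_form(self, rng):
        n = 200_000
        x = rng.standard_normal(n)
        y = 0.8 * x + np.sqrt(1 - 0.8 ** 2) * rng.standard_normal(n)
        fm = stats.fit_factor_model(np.stack([x, y], axis=1))
        assert fm.eigenvalues[0] == pytest.approx(1.8, abs=0.01)
        assert fm.eigenvalues[1] == pytest.approx(0.2, abs=0.01)

    def test_independent_variables_identity_limit(self, rng):
        fm = stats.fit_factor_model(rng.standard_normal((5000, 4)))
        assert np.allclose(fm.eigenvalues, 1.0, atol=0.15)

    def test_eigenvalue_sum_is_p(self, rng):
        data = rng.standard_normal((300, 12)) @ rng.standard_normal((12, 12))
        fm = stats.fit_factor_model(data)
        assert fm.eigenvalues.sum() == pytest.approx(12.0, rel=1e-9)

    def test_loading_column_sum_of_squares_is_eigenvalue(self, rng):
        data = rng.standard_normal((150, 6)) @ rng.standard_normal((6, 6))
        fm = stats.fit_factor_model(data)
        np.testing.assert_allclose((fm.loadings ** 2).sum(axis=0),
                                   fm.eigenvalues, rtol=1e-9)

    def test_scores_zero_mean_with_eigenvalue_covariance(self, rng):
        data = rng.standard_normal((400, 5)) @ rng.standard_normal((5, 5))
        fm = stats.fit_factor_model(data)
        assert np.allclose(fm.scores.mean(axis=0), 0.0, atol=1e-10)
        cov = np.cov(fm.scores, rowvar=False)
        np.testing.assert_allclose(np.diag(cov), fm.eigenvalues, rtol=1e-8)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_constant_column_named_in_error(self, rng):
        data = rng.standard_normal((50, 3))
        data[:, 1] = 7.0
        with pytest.raises(DegenerateDataError, match="x1"):
            stats.fit_factor_model(data)


class TestRetainFactors:
    def test_correlated_pair_keeps_first_factor_only(self, rng):
        n = 100_000
        x = rng.standard_normal(n)
        y = 0.8 * x + 0.6 * rng.standard_normal(n)
        fm = stats.fit_factor_model(np.stack([x, y], axis=1))
        assert stats.retain_factors(fm) == [0]

    def test_independent_variables_keep_all(self, rng):
        fm = stats.fit_factor_model(rng.standard_normal((8000, 3)))
        assert stats.retain_factors(fm) == [0, 1, 2]

    def test_book_table_retention_is_plausible(self):
        from melissoscope import phantoms
        table = phantoms.sample_feature_table(n_per_taxon=200, modality="BF",
                                              rng_seed=0)
        fm = stats.fit_factor_model(table)
        retained = stats.retain_factors(fm)
        assert 1 <= len(retained) <= 30
        assert retained == sorted(retained)


class TestLDA:
    def test_two_univariate_classes(self):
        x = np.concatenate([np.random.default_rng(0).normal(-5, 1, 100),
                            np.random.default_rng(1).normal(5, 1, 100)])[:, None]
        labels = ["a"] * 100 + ["b"] * 100
        model = stats.fit_lda(x, labels)
        assert model.axes.shape == (1, 1)
        assert model.centroids[0, 0] == pytest.approx(-model.centroids[1, 0],
                                                      rel=0.2)
        pred = stats.classify(model, x)
        assert (pred == np.array(labels)).mean() == 1.0

    def test_shuffled_labels_are_chance_level(self, rng):
        x = rng.standard_normal((600, 4))
        labels = np.array(["a", "b", "c"] * 200)
        model = stats.fit_lda(x, labels)
        assert model.eigenvalues[0] < 0.1
        pred = stats.classify(model, x)
        ccr = (pred == labels).mean()
        assert abs(ccr - 1 / 3) < 0.12

    def test_axes_match_plain_eigensolver_oracle(self, rng):
        """Discriminant axes agree with a direct eig(inv(Sw) @ Sb) solve."""
        x = np.vstack([rng.normal((0, 0), 1, (30, 2)),
                       rng.normal((4, 1), 1, (30, 2)),
                       rng.normal((1, 5), 1, (30, 2))])
        labels = np.repeat(["a", "b", "c"], 30)
        model = stats.fit_lda(x, labels)
        w, v = np.linalg.eig(np.linalg.inv(model.within_scatter)
                             @ model.between_scatter)
        order = np.argsort(w.real)[::-1]
        np.testing.assert_allclose(np.sort(model.eigenvalues)[::-1],
                                   w.real[order][:len(model.eigenvalues)],
                                   rtol=1e-8)
        for j in range(model.axes.shape[1]):
            ours = model.axes[:, j]
            theirs = v.real[:, order[j]]
            cos = abs(ours @ theirs) / (np.linalg.norm(ours)
                                        * np.linalg.norm(theirs))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_agreement_with_sklearn_reference(self, rng):
        """Predictions match scikit-learn's LDA on balanced classes."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        x = np.vstack([rng.normal((0, 0, 0), 1.0, (80, 3)),
                       rng.normal((3, 1, 0), 1.0, (80, 3)),
                       rng.normal((0, 3, 2), 1.0, (80, 3))])
        labels = np.repeat(["a", "b", "c"], 80)
        ours = stats.classify(stats.fit_lda(x, labels), x)
        ref = LinearDiscriminantAnalysis().fit(x, labels).predict(x)
        assert (ours == ref).mean() >= 0.99

    def test_tie_goes_to_first_label(self):
        x = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        model = stats.fit_lda(
            np.array([[-1.0], [-1.2], [1.0], [1.2]]), ["b", "b", "a", "a"])
        mid = (model.centroids[0] + model.centroids[1]) / 2
        # invert the projection is unnecessary: feed a point projecting to mid
        point = np.linalg.lstsq(model.axes.T, mid, rcond=None)[0][None, :]
        assert stats.classify(model, point)[0] == "a"

    def test_dimension_mismatch_rejected(self, rng):
        x = rng.standard_normal((40, 3))
        model = stats.fit_lda(x, ["a"] * 20 + ["b"] * 20)
        with pytest.raises(ContractViolation):
            stats.classify(model, rng.standard_normal((5, 2)))


class TestConfusion:
    def test_perfect_prediction(self):
        cm = stats.confusion_and_ccr(["a", "b", "c"], ["a", "b", "c"])
        assert cm.overall_ccr == 100.0
        assert np.trace(cm.counts) == 3

    def test_single_class_predictor_balanced(self):
        true = [t for t in "abcdefg" for _ in range(10)]
        pred = ["a"] * 70
        cm = stats.confusion_and_ccr(true, pred)
        assert cm.overall_ccr == pytest.approx(100 / 7)
        assert cm.counts.sum(axis=1).tolist() == [10] * 7

    def test_unknown_label_rejected(self):
        with pytest.raises(ContractViolation):
            stats.confusion_and_ccr(["a"], ["z"], classes=["a", "b"])


class TestPipelineProperties:
    def test_ccr_invariant_under_affine_rescaling(self):
        from melissoscope import phantoms
        table = phantoms.sample_feature_table(n_per_taxon=60, modality="BF",
                                              rng_seed=8)
        base = stats.classify_pipeline(table).confusion.overall_ccr
        scaled = table.frame.copy()
        for i, d in enumerate(DESCRIPTORS):
            scaled[d] = scaled[d] * (i + 2) * 0.37 + 11.0 * i
        rescaled = stats.classify_pipeline(
            FeatureTable(scaled)).confusion.overall_ccr
        assert rescaled == pytest.approx(base, abs=1e-9)

    def test_ccr_monotone_in_class_separation(self):
        """Inflating within-taxon spread can only hurt the classifier."""
        from melissoscope.book import stats_book
        from melissoscope import phantoms
        book = stats_book()
        inflated = {"BF": {t: {d: (m, 4 * sd + 1e-6) for d, (m, sd) in
                               book["BF"][t].items()}
                           for t in book["BF"]}}
        tight = phantoms.sample_feature_table(n_per_taxon=80, modality="BF",
                                              rng_seed=5)
        loose = phantoms.sample_feature_table(inflated, n_per_taxon=80,
                                              modality="BF", rng_seed=5)
        ccr_tight = stats.classify_pipeline(tight).confusion.overall_ccr
        ccr_loose = stats.classify_pipeline(loose).confusion.overall_ccr
        assert ccr_tight > ccr_loose

    def test_cross_validated_ccr_close_to_resubstitution(self):
        from melissoscope import phantoms
        table = phantoms.sample_feature_table(n_per_taxon=60, modality="Ph",
                                              rng_seed=9)
        resub = stats.classify_pipeline(table)
        cv = stats.classify_pipeline(table, cross_validate=True)
        assert cv.cross_validated
        assert cv.confusion.overall_ccr <= resub.confusion.overall_ccr + 5.0
        assert cv.confusion.overall_ccr > 60.0
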