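import numpy as np
import pytest
from scipy import stats

from ihcloc.biomarker import (
    SCORE_DIM,
    fit_gamma,
    flag_biomarker,
    image_score_vector,
    intensity_distance_control,
    intensity_histogram,
    null_control,
    screen_protein,
    translocation_test,
)


class TestTranslocationTest:
    def test_identical_groups_give_p_one(self):
        a = np.array([[0.1], [0.2], [0.3]])
        assert translocation_test(a, a.copy())[0] == 1.0

    def test_closed_form_pooled_t(self):
        """{1,2,3} vs {4,5,6}: pooled t = -3.674, two-sided p ~ 0.0214."""
        p = translocation_test(np.array([[1.0], [2.0], [3.0]]),
                               np.array([[4.0], [5.0], [6.0]]))[0]
        t = -3.0 / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        expected = 2 * stats.t.sf(abs(t), 4)
        assert p == pytest.approx(expected, abs=1e-9)
        assert p == pytest.approx(0.0214, abs=5e-4)

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (6, 1))
        b = rng.normal(0.8, 1, (7, 1))
        p = translocation_test(a, b)[0]
        pooled = np.concatenate([a[:, 0], b[:, 0]])
        t_obs = abs(stats.ttest_ind(a[:, 0], b[:, 0]).statistic)
        n_perm = 100_000
        prng = np.random.default_rng(42)
        perms = np.argsort(prng.random((n_perm, 13)), axis=1)
        ga = pooled[perms[:, :6]]
        gb = pooled[perms[:, 6:]]
        va = ga.var(axis=1, ddof=1)
        vb = gb.var(axis=1, ddof=1)
        sp = np.sqrt(((6 - 1) * va + (7 - 1) * vb) / (6 + 7 - 2))
        t = (ga.mean(axis=1) - gb.mean(axis=1)) / (sp * np.sqrt(1 / 6 + 1 / 7))
        frac = (np.abs(t) >= t_obs - 1e-12).mean()
        assert abs(p - frac) < 0.01

    def test_zero_variance_dimensions_imputed(self):
        a = np.full((3, 2), 0.5)
        b = np.column_stack([np.full(3, 0.5), np.full(3, 0.9)])
        p = translocation_test(a, b)
        assert p[0] == 1.0 and p[1] == 0.0

    def test_welch_variant_differs_under_heteroscedasticity(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, (5, 1))
        b = rng.normal(0.5, 2.0, (15, 1))
        ps = translocation_test(a, b, "student")[0]
        pw = translocation_test(a, b, "welch")[0]
        assert ps != pw

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            translocation_test(np.zeros((1, 3)), np.zeros((5, 3)))

    def test_type_one_error_calibrated(self):
        """Same-distribution groups (m=5, n=15): per-dimension rejection rate
        at alpha=0.05 stays in [0.04, 0.06] over 2000 replicates."""
        rng = np.random.default_rng(7)
        reps = 2000
        rejections = 0
        a = rng.normal(0, 1, (reps, 5))
        b = rng.normal(0, 1, (reps, 15))
        p = stats.ttest_ind(a, b, axis=1).pvalue
        rate = (p < 0.05).mean()
        assert 0.04 <= rate <= 0.06
        # spot-check our wrapper agrees with the vectorized scipy call
        ours = translocation_test(a[0][:, None], b[0][:, None])[0]
        assert ours == pytest.approx(p[0], abs=1e-12)


class TestFlagBiomarker:
    def test_no_small_p_no_flag(self):
        assert not flag_biomarker(np.full(21, 0.5))

    def test_single_small_p_flags(self):
        p = np.full(21, 0.9)
        p[13] = 0.01
        assert flag_biomarker(p)

    def test_bonferroni_is_stricter(self):
        p = np.full(21, 0.9)
        p[0] = 0.01
        assert flag_biomarker(p)
        assert not flag_biomarker(p, correction="bonferroni")

    def test_min_p_rule_is_liberal_under_correlated_null(self):
        """With 21 correlated null dimensions, the uncorrected min-p rule
        flags well above the nominal 5% - the documented liberality."""
        rng = np.random.default_rng(3)
        flags = 0
        n_prot = 1000
        cov = 0.7 * np.ones((21, 21)) + 0.3 * np.eye(21)
        L = np.linalg.cholesky(cov)
        for _ in range(n_prot):
            a = rng.normal(0, 1, (5, 21)) @ L.T
            b = rng.normal(0, 1, (15, 21)) @ L.T
            flags += flag_biomarker(translocation_test(a, b))
        assert flags / n_prot > 0.05


class TestNullControl:
    def test_deterministic_and_split_sizes(self):
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, (7, 21))
        p1 = null_control(m, seed=4)
        p2 = null_control(m, seed=4)
        assert np.array_equal(p1, p2)
        assert p1.shape == (21,)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError, match="4"):
            null_control(np.zeros((3, 21)))

    def test_same_class_proteins_mostly_large_p(self):
        """Non-translocating proteins: >= 85% of half-split control P values
        exceed 0.05 (desk-scale mirror of the normal-split control)."""
        rng = np.random.default_rng(5)
        large = 0
        total = 0
        for prot in range(200):
            m = rng.normal(0.4, 0.1, (6, 21))  # one protein, same class
            p = null_control(m, seed=prot)
            large += (p > 0.05).sum()
            total += p.size
        assert large / total >= 0.80  # >= 85% expected minus 0.05 tolerance


class TestScreenProtein:
    def _vectors(self, rng, n, shift=0.0):
        base = rng.dirichlet((8, 1, 1), n)  # class-i-dominant triples
        v = np.tile(base, 7)
        if shift:
            swap = v.copy()
            for k in range(7):
                v[:, 3 * k], v[:, 3 * k + 1] = swap[:, 3 * k + 1] + shift, swap[:, 3 * k] - shift / 2
        return np.clip(v, 0, 1)

    def test_translocating_protein_flagged_with_locations(self):
        rng = np.random.default_rng(0)
        normal = self._vectors(rng, 5)
        cancer = self._vectors(rng, 15, shift=0.3)
        rep = screen_protein("P1", normal, cancer)
        assert rep.is_biomarker
        assert rep.predicted_normal_location == "i"
        assert rep.predicted_normal_location != rep.predicted_cancer_location

    def test_stable_protein_not_flagged(self):
        rng = np.random.default_rng(1)
        rep = screen_protein("P2", self._vectors(rng, 5), self._vectors(rng, 15))
        assert not rep.is_biomarker
        assert rep.predicted_normal_location == rep.predicted_cancer_location == "i"


class TestImageScoreVector:
    def test_length_blocks_and_order(self):
        from ihcloc.classify import train_svm

        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.2, (10, 3)), rng.normal(2, 0.2, (10, 3)),
                       rng.normal(4, 0.2, (10, 3))])
        y = np.repeat([0, 1, 2], 10)
        models = [train_svm(X, y, grid=((1.0,), (0.5,)), seed=s) for s in range(7)]
        v = image_score_vector(models, [X[0]] * 7)
        assert v.shape == (SCORE_DIM,)
        triples = v.reshape(7, 3)
        assert np.allclose(triples.sum(axis=1), 1.0, atol=1e-9)

    def test_wrong_model_count_rejected(self):
        with pytest.raises(ValueError, match="7"):
            image_score_vector([], [])


class TestIntensityDistanceControl:
    def test_gamma_mle_parameter_recovery(self):
        rng = np.random.default_rng(0)
        k, theta = fit_gamma(rng.gamma(2.0, 1.5, 10_000))
        assert abs(k - 2.0) < 0.1
        assert abs(theta - 1.5) < 0.1

    def test_histogram_normalized(self):
        h = intensity_histogram(np.random.default_rng(0).random((32, 32)))
        assert h.shape == (64,)
        assert h.sum() == pytest.approx(1.0)

    def test_distances_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.dirichlet(np.ones(64)), rng.dirichlet(np.ones(64))
        assert np.linalg.norm(a - b) == np.linalg.norm(b - a)

    def test_fits_similar_for_matched_groups(self):
        rng = np.random.default_rng(2)

        def hists(n):
            return [rng.dirichlet(np.ones(64) * 5) for _ in range(n)]

        normal = {f"P{i}": hists(4) for i in range(8)}
        cancer = {f"P{i}": hists(10) for i in range(8)}
        flags = {f"P{i}": i < 4 for i in range(8)}
        fits = intensity_distance_control(normal, cancer, flags)
        (kd, td), (ku, tu) = fits["detected"], fits["undetected"]
        assert kd > 0 and ku > 0
        # same generative process in both groups -> similar gamma scale
        assert 0.5 < (kd * td) / (ku * tu) < 2.0

    def test_identical_images_rejected(self):
        h = [np.full(64, 1 / 64)]
        with pytest.raises(ValueError, match="degenerate|zero"):
            intensity_distance_control({"P": h * 3}, {"P": h * 3}, {"P": True})
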