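"""Statistical core: CCA vs regression oracle, projection replication,
Stouffer combination, Li-Ji effective tests, round-robin symmetry."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from facemod.assoc import (
    cca_single_snp,
    li_ji_meff,
    project_effect_score,
    replication_test,
    round_robin_meta,
    stouffer_combine,
    study_threshold,
)


class TestCcaSingleSnp:
    def test_matches_regression_f_oracle(self, rng):
        """With one genetic variable, Rao's F on Wilks' Lambda is the overall
        regression F; check against statsmodels on random instances."""
        worst = 0.0
        for _ in range(25):
            n, k = int(rng.integers(40, 200)), int(rng.integers(2, 8))
            scores = rng.normal(size=(n, k))
            g = rng.binomial(2, 0.3, n).astype(float)
            g += 0.1 * scores[:, 0] * rng.integers(0, 2)
            res = cca_single_snp(g, scores)
            fit = sm.OLS(g - g.mean(), sm.add_constant(scores - scores.mean(0))).fit()
            worst = max(worst, abs(res.p_value - fit.f_pvalue))
            assert np.isclose(res.cc**2, fit.rsquared, atol=1e-10)
        assert worst < 1e-10

    def test_perfect_linear_combination(self, rng):
        scores = rng.normal(size=(100, 4))
        g = scores @ np.array([1.0, -2.0, 0.5, 0.0])
        res = cca_single_snp(g, scores)
        assert res.cc > 1 - 1e-6
        assert res.p_value < 1e-100

    def test_constant_dosage_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            cca_single_snp(np.ones(50), rng.normal(size=(50, 3)))

    def test_singular_scores_rejected(self, rng):
        s = rng.normal(size=(50, 3))
        s = np.column_stack([s, s[:, 0]])
        with pytest.raises(ValueError, match="singular"):
            cca_single_snp(rng.binomial(2, 0.3, 50).astype(float), s)

    def test_loadings_unit_norm_positive_orientation(self, rng):
        scores = rng.normal(size=(200, 5))
        g = scores[:, 1] + 0.5 * rng.normal(size=200)
        res = cca_single_snp(g, scores)
        assert np.isclose(np.linalg.norm(res.loadings), 1.0)
        variate = scores @ res.loadings
        assert np.corrcoef(variate, g)[0, 1] > 0

    def test_covariate_dof_correction_shrinks_p_dof(self, rng):
        scores = rng.normal(size=(80, 5))
        g = rng.binomial(2, 0.3, 80).astype(float)
        r0 = cca_single_snp(g, scores, n_covariates=0)
        r10 = cca_single_snp(g, scores, n_covariates=10)
        assert r10.dof[1] == r0.dof[1] - 10


class TestProjectionReplication:
    def test_basis_vector_projection(self, rng):
        scores = rng.normal(size=(30, 4))
        e1 = np.eye(4)[0]
        np.testing.assert_array_equal(project_effect_score(scores, e1), scores[:, 0])

    def test_projection_linear(self, rng):
        scores = rng.normal(size=(30, 4))
        a, b = rng.normal(size=4), rng.normal(size=4)
        np.testing.assert_allclose(
            project_effect_score(scores, 2 * a + b),
            2 * project_effect_score(scores, a) + project_effect_score(scores, b),
            atol=1e-12,
        )

    def test_discovery_projection_reproduces_canonical_variate(self, rng):
        scores = rng.normal(size=(150, 5))
        g = scores[:, 0] - 0.4 * scores[:, 2] + rng.normal(size=150)
        res = cca_single_snp(g, scores)
        variate = project_effect_score(scores, res.loadings)
        # equals the fitted values of the dosage regression up to scale
        beta, *_ = np.linalg.lstsq(scores - scores.mean(0), g - g.mean(), rcond=None)
        fitted = (scores - scores.mean(0)) @ beta
        r = np.corrcoef(variate, fitted)[0, 1]
        assert r > 1 - 1e-10

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            project_effect_score(rng.normal(size=(10, 3)), np.ones(4))

    def test_null_slope_gives_half(self):
        g = np.tile([0.0, 1.0, 2.0], 12)
        e = np.tile([1.0, -2.0, 1.0], 12)  # exactly orthogonal to centered g
        assert np.isclose(replication_test(e, g), 0.5, atol=1e-12)

    def test_sign_flip_complements_p(self, rng):
        g = rng.binomial(2, 0.3, 200).astype(float)
        e = 0.2 * g + rng.normal(size=200)
        p = replication_test(e, g)
        assert np.isclose(replication_test(-e, g), 1 - p, atol=1e-12)

    def test_concordant_replication_power(self, rng):
        """Planted effect 0.5 SD per allele at n=1000: replication p is small."""
        ps = []
        for _ in range(100):
            g = rng.binomial(2, 0.3, 1000).astype(float)
            e = 0.5 * g + rng.normal(size=1000)
            ps.append(replication_test(e, g))
        assert np.median(ps) < 0.05

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(ValueError, match="zero-variance"):
            replication_test(np.zeros(20), rng.binomial(2, 0.4, 20).astype(float))


class TestStouffer:
    def test_single_p_identity(self):
        assert np.isclose(stouffer_combine([0.37]), 0.37, atol=1e-12)

    def test_three_nominal_fives_closed_form(self):
        z = 3 * stats.norm.isf(0.05) / np.sqrt(3)
        expected = stats.norm.sf(z)
        got = stouffer_combine([0.05, 0.05, 0.05])
        assert np.isclose(got, expected, rtol=1e-12)
        assert np.isclose(got, 2.19e-3, rtol=5e-3)

    def test_null_center(self):
        assert np.isclose(stouffer_combine([0.5, 0.5]), 0.5, atol=1e-12)

    def test_concordant_combination_beats_each_input(self):
        ps = [0.04, 0.03, 0.049]
        assert stouffer_combine(ps) < min(ps)

    def test_weights_shift_toward_heavier_study(self):
        ps = [0.01, 0.5]
        up = stouffer_combine(ps, weights=[10, 1])
        down = stouffer_combine(ps, weights=[1, 10])
        assert up < stouffer_combine(ps) < down

    def test_boundary_p_rejected(self):
        with pytest.raises(ValueError):
            stouffer_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            stouffer_combine([0.5, 1.0])


class TestLiJi:
    def test_identity_gives_t(self):
        for t in (3, 10, 37):
            assert li_ji_meff(np.eye(t)).meff == t

    def test_all_ones_gives_one(self):
        assert li_ji_meff(np.ones((8, 8))).meff == 1

    def test_two_by_two_hand_computed(self):
        c = np.array([[1.0, 0.6], [0.6, 1.0]])
        res = li_ji_meff(c)
        assert np.isclose(res.raw, 2.0, atol=1e-12)  # f(1.6)+f(0.4) = 1.6+0.4
        assert res.meff == 2

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            li_ji_meff(np.array([[1.0, 0.2], [0.5, 1.0]]))


class TestStudyThreshold:
    def test_printed_study_cutoff(self):
        assert f"{study_threshold(37, 30, 3, 0.05):.2e}" == "1.50e-05"

    def test_no_correction(self):
        assert study_threshold(1, 1, 1, 0.05) == 0.05

    def test_ratio_arm_cutoff(self):
        assert np.isclose(study_threshold(42, 1, 1, 0.05), 1.19e-3, atol=5e-6)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            study_threshold(0, 30, 3)


def _toy_cohorts(rng, n_cohorts=3, n=120, k=4, beta=0.0):
    scores, dosages = [], []
    direction = rng.normal(size=k)
    direction /= np.linalg.norm(direction)
    for _ in range(n_cohorts):
        s = rng.normal(size=(n, k))
        g = rng.binomial(2, 0.3, n).astype(float)
        s = s + beta * np.outer(g, direction)
        scores.append(s)
        dosages.append(g)
    proj = {
        (d, r): scores[r]
        for d in range(n_cohorts)
        for r in range(n_cohorts)
        if d != r
    }
    return scores, proj, dosages


class TestRoundRobin:
    def test_identical_cohorts_identical_meta(self, rng):
        s = rng.normal(size=(100, 3))
        g = rng.binomial(2, 0.25, 100).astype(float)
        g[0] = 1.0  # guard against constant draws
        scores = [s, s.copy(), s.copy()]
        proj = {(d, r): s for d in range(3) for r in range(3) if d != r}
        res = round_robin_meta(scores, proj, [g, g.copy(), g.copy()])
        metas = {round(m.p_meta, 14) for m in res}
        assert len(metas) == 1

    def test_three_rotations_produced(self, rng):
        scores, proj, dosages = _toy_cohorts(rng)
        res = round_robin_meta(scores, proj, dosages, cohort_labels=["a", "b", "c"])
        assert [m.rotation for m in res] == ["a", "b", "c"]

    def test_planted_effect_monotone_in_beta(self):
        """Stronger planted effects never worsen the median meta p (shared
        seeds across the beta grid)."""
        medians = []
        for beta in (0.0, 0.2, 0.4):
            ps = []
            for seed in range(12):
                rng = np.random.default_rng(1000 + seed)
                scores, proj, dosages = _toy_cohorts(rng, beta=beta)
                res = round_robin_meta(scores, proj, dosages)
                ps.extend(m.p_meta for m in res)
            medians.append(np.median(ps))
        assert medians[0] > medians[1] > medians[2]

    def test_agrees_with_manual_composition(self, rng):
        """round_robin_meta equals cca + project + replicate + stouffer done
        by hand for each rotation."""
        scores, proj, dosages = _toy_cohorts(rng, beta=0.3)
        res = round_robin_meta(scores, proj, dosages)
        for d, m in enumerate(res):
            disc = cca_single_snp(dosages[d], scores[d])
            reps = [r for r in range(3) if r != d]
            ps = [disc.p_value]
            for r in reps:
                eff = project_effect_score(proj[(d, r)], disc.loadings)
                ps.append(replication_test(eff, dosages[r]))
            expected = stouffer_combine(np.clip(ps, 1e-300, 1 - 1e-16))
            assert np.isclose(m.p_meta, expected, rtol=1e-8, atol=1e-12)
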