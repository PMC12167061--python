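"""Neff bookkeeping, PRS scoring, AUC estimation/meta-analysis, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prscap.ceiling import auc_max
from prscap.effects import EffectProfile
from prscap.gwas_tools import (
    AucEstimate,
    PrsWeights,
    auc_with_se,
    convergence_curve,
    effective_sample_size,
    meta_auc,
    per_variant_neff_filter,
    prs_score,
    shrink_weights,
    simulate_gwas_effects,
    strata_odds_ratio,
)


class TestEffectiveSampleSize:
    def test_balanced_design(self):
        assert effective_sample_size(1000, 1000) == pytest.approx(2000.0)

    @pytest.mark.parametrize(
        "n_case,n_control,expected",
        [
            (5_000, 50_000, 18_182),
            (15_420, 15_062, 30_478),
            (60_801, 123_504, 162_973),
            (74_124, 824_006, 272_026),
            (10_365, 16_110, 25_228),
            (21_982, 41_944, 57_693),
        ],
    )
    def test_published_study_values(self, n_case, n_control, expected):
        assert round(effective_sample_size(n_case, n_control)) == expected

    def test_positive_counts_required(self):
        with pytest.raises(ValueError):
            effective_sample_size(0, 100)


class TestPerVariantNeffFilter:
    def test_all_at_max_kept(self):
        v = np.full(10, 500.0)
        assert per_variant_neff_filter(v, 500.0).all()

    def test_boundary_exclusion(self):
        mask = per_variant_neff_filter(np.array([0.49, 0.5, 1.1, 1.11]), 1.0)
        assert mask.tolist() == [False, True, True, False]

    def test_planted_violations_counted(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(0.6, 1.0, 100)
        v[:7] = 0.2
        v[7:12] = 1.5
        mask = per_variant_neff_filter(v, 1.0)
        assert (~mask).sum() == 12


class TestPrsScore:
    def test_zero_weights(self):
        x = np.random.default_rng(0).integers(0, 3, (5, 4)).astype(float)
        w = PrsWeights(gamma=np.zeros(4))
        assert np.all(prs_score(w, x) == 0)

    def test_single_variant_identity(self):
        x = np.array([[0.0], [1.0], [2.0]])
        assert np.array_equal(prs_score(PrsWeights(gamma=np.array([1.0])), x), [0, 1, 2])

    def test_flipped_allele_hand_computed(self):
        x = np.array([[1.0, 0.0, 2.0]])
        w = PrsWeights(gamma=np.array([0.5, 1.0, 2.0]), orientation=np.array([1.0, 1.0, -1.0]))
        # flipped third variant scores on 2 - 2 = 0: 0.5*1 + 1*0 + 2*0
        assert prs_score(w, x)[0] == pytest.approx(0.5)

    def test_unresolved_orientation_rejected(self):
        with pytest.raises(ValueError, match="orientation"):
            PrsWeights(gamma=np.array([1.0]), orientation=np.array([0.0]))


def _auc_all_pairs(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    case, ctrl = s[y], s[~y]
    tot = 0.0
    for c in case:
        tot += np.sum(c > ctrl) + 0.5 * np.sum(c == ctrl)
    return tot / (case.size * ctrl.size)


class TestAucWithSe:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        assert auc_with_se(labels.astype(float), labels).auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        est = auc_with_se(rng.normal(size=20000), rng.integers(0, 2, 20000))
        assert est.auc == pytest.approx(0.5, abs=0.02)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        scores = rng.integers(0, 5, n).astype(float)  # ties guaranteed
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        est = auc_with_se(scores, labels)
        assert est.auc == pytest.approx(_auc_all_pairs(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        scores = rng.normal(size=500) + np.repeat([0, 1], 250)
        labels = np.repeat([0, 1], 250)
        assert auc_with_se(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_delong_variance_close_to_hanley(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=400) + np.repeat([0, 0.8], 200)
        labels = np.repeat([0, 1], 200)
        vh = auc_with_se(scores, labels, method="hanley").variance
        vd = auc_with_se(scores, labels, method="delong").variance
        assert vd == pytest.approx(vh, rel=0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_with_se(np.arange(5.0), np.ones(5))


class TestMetaAuc:
    def test_single_estimate_identity(self):
        e = AucEstimate(auc=0.63, variance=0.004, n_case=10, n_control=20)
        out = meta_auc([e])
        assert out.auc == pytest.approx(0.63)
        assert out.variance == pytest.approx(0.004)

    def test_equal_variances_arithmetic_mean(self):
        ests = [
            AucEstimate(auc=a, variance=0.01, n_case=5, n_control=5) for a in (0.55, 0.65, 0.75)
        ]
        assert meta_auc(ests).auc == pytest.approx(0.65)

    def test_hand_computed_weighted_mean(self):
        ests = [
            AucEstimate(auc=0.6, variance=0.01, n_case=5, n_control=5),
            AucEstimate(auc=0.7, variance=0.0025, n_case=5, n_control=5),
        ]
        out = meta_auc(ests)
        assert out.auc == pytest.approx(0.68, abs=1e-12)
        assert out.se == pytest.approx(np.sqrt(1 / 500), abs=1e-12)

    def test_combined_variance_below_minimum(self):
        ests = [
            AucEstimate(auc=0.6, variance=0.01, n_case=5, n_control=5),
            AucEstimate(auc=0.62, variance=0.02, n_case=5, n_control=5),
        ]
        assert meta_auc(ests).variance <= 0.01

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            meta_auc([])


class TestStrataOddsRatio:
    def test_independent_scores_or_near_one(self):
        ors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=20000)
            labels = rng.uniform(size=20000) < 0.3
            or_, (lo, hi) = strata_odds_ratio(scores, labels, 0.05)
            ors.append(or_)
        assert np.mean(ors) == pytest.approx(1.0, abs=0.08)

    def test_hand_computed_table(self):
        # top stratum (k=2): cases 1, controls 1; rest: cases 1, controls 7
        scores = np.array([9.0, 8.0, 7.0, 1, 2, 3, 4, 5, 6, 0])
        labels = np.array([1, 0, 1, 0, 0, 0, 0, 0, 0, 0])
        or_, _ = strata_odds_ratio(scores, labels, 0.2)
        assert or_ == pytest.approx((1 * 7) / (1 * 1))

    def test_zero_cell_signalled(self):
        scores = np.arange(20.0)
        labels = (scores >= 19).astype(int)  # the single case is in the top stratum
        with pytest.raises(ZeroDivisionError, match="cases_rest"):
            strata_odds_ratio(scores, labels, 0.1)


class TestSimulatedGwas:
    def _effects(self, m=500, h2=0.3, seed=0):
        rng = np.random.default_rng(seed)
        beta = rng.normal(size=m)
        beta *= np.sqrt(h2 / np.sum(beta**2))
        return EffectProfile(
            beta=beta, alpha=0.0, sigma2_g_alpha=1.0, h2_target=h2, maf=np.full(m, 0.2)
        )

    def test_estimates_converge_with_n(self):
        eff = self._effects()
        bh = simulate_gwas_effects(eff, 10**9, seed=1)
        assert np.allclose(bh, eff.beta, atol=1e-3)

    def test_sampling_variance_scales(self):
        eff = self._effects(m=2000)
        n = 50
        reps = np.stack([simulate_gwas_effects(eff, n, seed=s) - eff.beta for s in range(30)])
        assert reps.var() == pytest.approx(1 / n, rel=0.1)

    def test_determinism(self):
        eff = self._effects()
        assert np.array_equal(
            simulate_gwas_effects(eff, 100, seed=5), simulate_gwas_effects(eff, 100, seed=5)
        )

    def test_shrinkage_factor(self):
        eff_hat = np.ones(3)
        w = shrink_weights(eff_hat, n_gwas=20_000, m_variants=2_000, h2=0.3)
        assert np.allclose(w.gamma, 0.75)
        assert np.all(shrink_weights(eff_hat, 100, 10, 0.0).gamma == 0)

    def test_convergence_noise_floor_and_scaling(self):
        eff = self._effects(m=2000, h2=0.3)
        curve = convergence_curve(eff, K=0.2, n_grid=[10], n_test=3000, reps=10, seed=0)
        # weights are almost pure noise when N << M/h2
        assert curve["auc_mean"].iloc[0] == pytest.approx(0.5, abs=0.03)

    def test_convergence_bounded_by_ceiling(self):
        eff = self._effects(m=200, h2=0.3)
        curve = convergence_curve(
            eff, K=0.2, n_grid=[100, 1000, 10000], n_test=3000, reps=8, seed=1
        )
        bound = auc_max(0.3, 0.2)
        assert np.all(curve["auc_mean"] <= bound + 3 * curve["auc_se"] + 0.01)
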