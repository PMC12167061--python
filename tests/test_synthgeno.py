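"""Generator statistics: LD decay, MAF spectra, imputation targets, phenotypes."""

import numpy as np
import pytest
from scipy import stats

from prscap import coverage, synthgeno
from prscap.effects import sample_alpha_effects
from prscap.gwas_tools import auc_with_se


def _mean_lag_r2(panel, lag):
    d = panel.true_dosage.astype(float)
    vals = []
    for j in range(d.shape[1] - lag):
        a, b = d[:, j], d[:, j + lag]
        if a.std() > 0 and b.std() > 0:
            vals.append(np.corrcoef(a, b)[0, 1] ** 2)
    return float(np.mean(vals))


class TestGeneratePanel:
    def test_determinism(self):
        a = synthgeno.generate_panel(200, 100, ld_strength=0.8, seed=42)
        b = synthgeno.generate_panel(200, 100, ld_strength=0.8, seed=42)
        assert np.array_equal(a.true_dosage, b.true_dosage)
        assert a.meta.equals(b.meta)

    def test_independence_at_zero_ld(self):
        panel = synthgeno.generate_panel(1000, 500, ld_strength=0.0, seed=1)
        assert _mean_lag_r2(panel, 1) < 0.01

    def test_ld_decays_with_distance(self):
        panel = synthgeno.generate_panel(1000, 500, ld_strength=0.9, seed=1)
        assert _mean_lag_r2(panel, 1) > _mean_lag_r2(panel, 10)

    def test_realized_frequencies_match_spectrum(self):
        spec = synthgeno.uniform_spectrum(0.05, 0.5)
        panel = synthgeno.generate_panel(2000, 200, ld_strength=0.0, maf_spec=spec, seed=7)
        freq = panel.true_dosage.mean(axis=0) / 2
        se = np.sqrt(panel.maf * (1 - panel.maf) / (2 * panel.n_individuals))
        assert np.mean(np.abs(freq - panel.maf) / se < 3) > 0.99
        # sampled MAFs pass a goodness-of-fit check against the spectrum
        ks = stats.kstest(spec.cdf(panel.maf), "uniform")
        assert ks.pvalue > 0.01

    def test_positions_strictly_increasing(self):
        panel = synthgeno.generate_panel(10, 500, seed=3)
        assert np.all(np.diff(panel.pos) > 0)
        assert np.all((panel.maf > 0) & (panel.maf <= 0.5))

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            synthgeno.generate_panel(1, 10)
        with pytest.raises(ValueError):
            synthgeno.generate_panel(10, 10, ld_strength=1.0)


class TestDesignateGenotyped:
    def test_full_fraction_selects_all(self):
        panel = synthgeno.generate_panel(50, 40, seed=0)
        out = synthgeno.designate_genotyped(panel, synthgeno.fraction(1.0), seed=0)
        assert out.is_genotyped.all()

    def test_empty_selection_errors(self):
        panel = synthgeno.generate_panel(50, 40, seed=0)
        with pytest.raises(ValueError, match="no variants"):
            synthgeno.designate_genotyped(panel, synthgeno.fraction(0.0), seed=0)

    def test_maf_biased_prefers_common(self):
        panel = synthgeno.generate_panel(100, 400, seed=5)
        out = synthgeno.designate_genotyped(panel, synthgeno.maf_biased(0.05), seed=5)
        s = out.is_genotyped
        assert 0 < s.sum() < s.size
        assert out.maf[s].mean() > out.maf[~s].mean()


class TestEmulateImputation:
    def test_perfect_quality_is_identity(self):
        panel = synthgeno.generate_panel(100, 30, seed=2)
        panel = synthgeno.designate_genotyped(panel, synthgeno.fraction(0.5), seed=2)
        out = synthgeno.emulate_imputation(panel, 1.0, seed=2)
        assert np.array_equal(out.imputed_dosage, out.true_dosage)

    def test_zero_quality_uncorrelated(self):
        spec = synthgeno.uniform_spectrum(0.2, 0.5)
        panel = synthgeno.generate_panel(2000, 30, ld_strength=0, maf_spec=spec, seed=2)
        panel = synthgeno.designate_genotyped(panel, synthgeno.fraction(1 / 30), seed=2)
        out = synthgeno.emulate_imputation(panel, 0.0, seed=2)
        ut = ~out.is_genotyped
        r2 = [
            coverage.imputation_r2(out.true_dosage[:, j], out.imputed_dosage[:, j])
            for j in np.flatnonzero(ut)
        ]
        # under independence E[r2] = 1/(n-1); 3 SE of a squared correlation
        assert np.mean(r2) < 3.0 / 2000

    def test_intermediate_target_within_band(self):
        spec = synthgeno.uniform_spectrum(0.2, 0.5)
        panel = synthgeno.generate_panel(5000, 60, ld_strength=0, maf_spec=spec, seed=3)
        panel = synthgeno.designate_genotyped(panel, synthgeno.fraction(0.1), seed=3)
        out = synthgeno.emulate_imputation(panel, 0.36, seed=3)
        ut = np.flatnonzero(~out.is_genotyped)
        r2 = np.array(
            [coverage.imputation_r2(out.true_dosage[:, j], out.imputed_dosage[:, j]) for j in ut]
        )
        assert 0.30 <= r2.mean() <= 0.42
        assert np.all((r2 > 0.30 - 0.1) & (r2 < 0.42 + 0.1))

    def test_frequency_conservation(self, calibrated_panel):
        p = calibrated_panel
        maf = p.maf
        se = np.sqrt(2 * maf * (1 - maf) / p.n_individuals)
        dev = np.abs(p.imputed_dosage.mean(axis=0) - p.true_dosage.mean(axis=0)) / se
        assert np.mean(dev < 3) > 0.99

    def test_invalid_target_rejected(self):
        panel = synthgeno.generate_panel(50, 10, seed=1)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            synthgeno.emulate_imputation(panel, 1.5, seed=1)

    def test_calibrated_orderings(self, calibrated_panel, calibrated_capture):
        """The preset reproduces the qualitative real-data structure: mean
        imputation r² above mean tagging ρ², and the two positively correlated."""
        t = calibrated_capture
        ut = ~t.is_genotyped
        assert t.r2_imput[ut].mean() > t.rho2[ut].mean()
        assert np.corrcoef(t.rho2[ut], t.r2_imput[ut])[0, 1] > 0.3


class TestAnnotations:
    def test_empty_set(self):
        panel = synthgeno.generate_panel(10, 50, seed=0)
        ann = synthgeno.generate_annotations(panel, 0, seed=0)
        assert len(ann) == 0

    def test_single_near_total_coverage(self):
        panel = synthgeno.generate_panel(10, 200, seed=0)
        ann = synthgeno.generate_annotations(panel, 1, (0.995, 0.999), seed=0, max_intervals=1)
        from prscap.enrichment import annotate_variants

        ind = annotate_variants(panel, ann)
        assert ind.iloc[:, 0].mean() > 0.9

    def test_counts_track_coverage(self):
        panel = synthgeno.generate_panel(10, 2000, seed=3)
        ann = synthgeno.generate_annotations(panel, 100, (1e-5, 0.647), seed=3)
        from prscap.enrichment import annotate_variants

        ind = annotate_variants(panel, ann)
        counts = ind.sum(axis=0).to_numpy()
        assert np.all(counts > 0)  # anchoring guarantees every track hits a variant
        cov = np.array([ann.coverage_fraction(n) for n in ind.columns])
        assert stats.spearmanr(cov, counts).statistic > 0.8

    def test_invalid_coverage_bounds(self):
        panel = synthgeno.generate_panel(10, 50, seed=0)
        with pytest.raises(ValueError):
            synthgeno.generate_annotations(panel, 3, (0.5, 0.2), seed=0)

    def test_determinism(self):
        panel = synthgeno.generate_panel(10, 200, seed=4)
        a = synthgeno.generate_annotations(panel, 10, seed=9)
        b = synthgeno.generate_annotations(panel, 10, seed=9)
        assert a.tracks.keys() == b.tracks.keys()
        assert all(np.array_equal(a.tracks[k], b.tracks[k]) for k in a.tracks)


class TestLiabilityPhenotype:
    def test_null_heritability_gives_random_labels(self):
        panel = synthgeno.generate_panel(4000, 50, seed=1)
        eff = sample_alpha_effects(panel.maf, 0.0, h2_target=0.0, seed=1)
        pheno = synthgeno.simulate_liability_phenotype(panel, eff, 0.5, seed=1)
        score = pheno.genetic_score + np.random.default_rng(0).normal(0, 1e-9, 4000)
        auc = auc_with_se(score, pheno.labels).auc
        assert abs(auc - 0.5) < 0.03

    @pytest.mark.parametrize("k_prev", [0.01, 0.1, 0.25, 0.5])
    def test_prevalence_reproduced(self, k_prev):
        # many moderately common causal variants: the polygenic-score CLT
        # regime the liability threshold presumes
        spec = synthgeno.uniform_spectrum(0.01, 0.5)
        panel = synthgeno.generate_panel(20000, 400, maf_spec=spec, seed=2)
        eff = sample_alpha_effects(panel.maf, -0.5, h2_target=0.3, seed=2)
        pheno = synthgeno.simulate_liability_phenotype(panel, eff, k_prev, seed=2)
        se = np.sqrt(k_prev * (1 - k_prev) / 20000)
        assert abs(pheno.labels.mean() - k_prev) < 4 * se

    def test_liability_unit_variance(self):
        panel = synthgeno.generate_panel(20000, 100, seed=3)
        eff = sample_alpha_effects(panel.maf, -0.5, h2_target=0.5, seed=3)
        pheno = synthgeno.simulate_liability_phenotype(panel, eff, 0.1, seed=3)
        assert abs(pheno.liability.var() - 1.0) < 0.1

    def test_determinism(self):
        panel = synthgeno.generate_panel(100, 20, seed=5)
        eff = sample_alpha_effects(panel.maf, -1.0, h2_target=0.4, seed=5)
        a = synthgeno.simulate_liability_phenotype(panel, eff, 0.2, seed=8)
        b = synthgeno.simulate_liability_phenotype(panel, eff, 0.2, seed=8)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.liability, b.liability)
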