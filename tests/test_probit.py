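import numpy as np
import pytest
import statsmodels.api as sm

from oilqsar.probit import (
    DoseResponseDataset,
    NonConvergenceError,
    abbott_correct,
    fit_probit,
    lc_quantile,
)
from oilqsar.simulate import BioassaySimSpec, gen_bioassay

SYMMETRIC = DoseResponseDataset(
    groups=((1.0, 20, 2), (10.0, 20, 10), (100.0, 20, 18)))


class TestAbbott:
    def test_zero_control_noop(self):
        ds = DoseResponseDataset(groups=((1.0, 20, 5), (10.0, 20, 15)),
                                 control=(20, 0))
        assert abbott_correct(ds) is ds

    def test_rescaling(self):
        ds = DoseResponseDataset(groups=((1.0, 10, 6), (10.0, 10, 1)),
                                 control=(10, 2))
        corr = abbott_correct(ds)
        assert corr.groups[0][2] == pytest.approx(10 * (0.6 - 0.2) / 0.8)
        assert corr.groups[1][2] == 0.0  # clipped at zero

    def test_total_control_mortality_rejected(self):
        ds = DoseResponseDataset(groups=((1.0, 10, 6), (10.0, 10, 8)),
                                 control=(10, 10))
        with pytest.raises(ValueError):
            abbott_correct(ds)


class TestFit:
    def test_symmetric_lc50_exact(self):
        fit = fit_probit(SYMMETRIC)
        assert fit.lc50 == pytest.approx(10.0, rel=1e-9)
        assert fit.converged

    def test_all_zero_mortality_raises(self):
        ds = DoseResponseDataset(groups=((1.0, 20, 0), (10.0, 20, 0)))
        with pytest.raises(NonConvergenceError):
            fit_probit(ds)

    def test_all_dead_raises(self):
        ds = DoseResponseDataset(groups=((1.0, 20, 20), (10.0, 20, 20)))
        with pytest.raises(NonConvergenceError):
            fit_probit(ds)

    def test_matches_statsmodels_glm(self):
        spec = BioassaySimSpec(lc50=50, slope=2.5, replicates=5, seed=11)
        for ds in gen_bioassay(spec):
            fit = fit_probit(ds)
            x = np.log10([g[0] for g in ds.groups])
            n = np.array([g[1] for g in ds.groups])
            y = np.array([g[2] for g in ds.groups])
            res = sm.GLM(
                np.column_stack([y, n - y]), sm.add_constant(x),
                family=sm.families.Binomial(sm.families.links.Probit()),
            ).fit()
            assert fit.alpha == pytest.approx(res.params[0], abs=1e-4)
            assert fit.beta == pytest.approx(res.params[1], abs=1e-4)

    def test_local_optimality(self):
        fit = fit_probit(SYMMETRIC)

        def loglik(a, b):
            x = np.log10([g[0] for g in SYMMETRIC.groups])
            n = np.array([g[1] for g in SYMMETRIC.groups], float)
            y = np.array([g[2] for g in SYMMETRIC.groups], float)
            from scipy.stats import norm
            p = np.clip(norm.cdf(a + b * x), 1e-12, 1 - 1e-12)
            return float((y * np.log(p) + (n - y) * np.log(1 - p)).sum())

        base = loglik(fit.alpha, fit.beta)
        eps = 1e-3
        for da, db in ((eps, 0), (-eps, 0), (0, eps), (0, -eps),
                       (eps, eps), (-eps, -eps)):
            assert loglik(fit.alpha + da, fit.beta + db) <= base + 1e-12

    def test_dose_unit_equivariance(self):
        fit1 = fit_probit(SYMMETRIC)
        scaled = DoseResponseDataset(
            groups=tuple((d * 7.0, n, y) for d, n, y in SYMMETRIC.groups))
        fit2 = fit_probit(scaled)
        assert fit2.lc50 == pytest.approx(7.0 * fit1.lc50, rel=1e-8)
        assert fit2.beta == pytest.approx(fit1.beta, rel=1e-8)
        assert fit2.lc50_ci[0] == pytest.approx(7.0 * fit1.lc50_ci[0], rel=1e-6)
        assert fit2.lc50_ci[1] == pytest.approx(7.0 * fit1.lc50_ci[1], rel=1e-6)


class TestQuantiles:
    def test_median_equals_lc50(self):
        fit = fit_probit(SYMMETRIC)
        lc, _, _ = lc_quantile(fit, 0.5)
        assert lc == pytest.approx(fit.lc50, rel=1e-12)

    def test_extreme_quantile_wider_ci(self):
        spec = BioassaySimSpec(lc50=50, slope=1.2, replicates=1, seed=3)
        fit = fit_probit(gen_bioassay(spec)[0])
        _, (lo50, hi50), _ = lc_quantile(fit, 0.5)
        _, (lo99, hi99), _ = lc_quantile(fit, 0.99)
        assert np.log10(hi99) - np.log10(lo99) > np.log10(hi50) - np.log10(lo50)

    def test_invalid_quantile(self):
        fit = fit_probit(SYMMETRIC)
        with pytest.raises(ValueError):
            lc_quantile(fit, 1.5)


class TestMonteCarlo:
    def test_lc50_consistency_quick(self):
        spec = BioassaySimSpec(lc50=50, slope=2.5, replicates=150, seed=21)
        est = [fit_probit(ds).lc50 for ds in gen_bioassay(spec)]
        assert np.mean(est) == pytest.approx(50.0, rel=0.05)

    def test_median_consistent_under_logit_truth(self, rng):
        # generate from a logistic dose-response; probit LC50 stays consistent
        doses = np.array([10.0, 25.0, 50.0, 100.0, 250.0])
        eta = 1.7 * (np.log10(doses) - np.log10(50.0))
        p = 1.0 / (1.0 + np.exp(-2.2 * eta))
        est = []
        for _ in range(150):
            deaths = rng.binomial(60, p)
            ds = DoseResponseDataset(
                groups=tuple((d, 60, int(k)) for d, k in zip(doses, deaths)))
            est.append(fit_probit(ds).lc50)
        assert np.mean(est) == pytest.approx(50.0, rel=0.06)


class TestDatasetValidation:
    def test_nonpositive_dose(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(groups=((0.0, 20, 1), (10.0, 20, 5)))

    def test_single_dose(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(groups=((10.0, 20, 1), (10.0, 20, 5)))

    def test_bad_counts(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(groups=((1.0, 20, 25), (10.0, 20, 5)))
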