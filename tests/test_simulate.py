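import numpy as np
import pytest
from scipy import stats

from oilqsar.regression import fit_ols
from oilqsar.simulate import BioassaySimSpec, QsarSimSpec, gen_bioassay, gen_qsar


class TestBioassay:
    def test_seed_reproducibility(self):
        spec = BioassaySimSpec(replicates=3, seed=5)
        a = gen_bioassay(spec)
        b = gen_bioassay(spec)
        assert [ds.groups for ds in a] == [ds.groups for ds in b]

    def test_step_function_limit(self):
        spec = BioassaySimSpec(lc50=50, slope=100.0,
                               doses=(10.0, 25.0, 100.0, 250.0), seed=1)
        ds = gen_bioassay(spec)[0]
        mort = {d: k / n for d, n, k in ds.groups}
        assert mort[10.0] == 0.0 and mort[25.0] == 0.0
        assert mort[100.0] == 1.0 and mort[250.0] == 1.0

    def test_expected_mortality_at_lc50(self):
        spec = BioassaySimSpec(lc50=50)
        assert spec.mortality(50.0) == pytest.approx(0.5)

    def test_empirical_mortality_within_3se(self):
        spec = BioassaySimSpec(lc50=50, slope=2.5, replicates=1000, seed=1)
        datasets = gen_bioassay(spec)
        for j, dose in enumerate(spec.doses):
            p = spec.mortality(dose)
            total_n = spec.n_per_group * spec.replicates
            dead = sum(ds.groups[j][2] for ds in datasets)
            se = np.sqrt(p * (1 - p) / total_n)
            assert abs(dead / total_n - p) < 3 * se + 1e-12

    def test_datasets_satisfy_invariants(self):
        for ds in gen_bioassay(BioassaySimSpec(replicates=20, seed=2)):
            for d, n, k in ds.groups:
                assert d > 0 and 0 <= k <= n

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            BioassaySimSpec(lc50=-1)
        with pytest.raises(ValueError):
            BioassaySimSpec(slope=0)


class TestQsarSim:
    def test_seed_reproducibility(self):
        a = gen_qsar(QsarSimSpec(seed=3))
        b = gen_qsar(QsarSimSpec(seed=3))
        assert a[0].equals(b[0])
        assert a[1].equals(b[1])

    def test_noise_free_exact_recovery(self):
        spec = QsarSimSpec(noise_sd=0.0, seed=4, intercept=2.5)
        X, y, truth = gen_qsar(spec)
        m = fit_ols(X[list(truth.planted_names)], y)
        assert m.r2 == pytest.approx(1.0)
        assert truth.realized_r2 == pytest.approx(1.0)
        for name, coef in zip(truth.planted_names, truth.coefficients):
            assert m.raw_coefficients[name] == pytest.approx(coef)
        assert m.intercept == pytest.approx(2.5)

    def test_coefficients_within_3se_large_n(self):
        spec = QsarSimSpec(n_compounds=4000, n_descriptors=6,
                           planted=(0, 1), coefficients=(1.0, -0.5),
                           noise_sd=1.0, seed=8)
        X, y, truth = gen_qsar(spec)
        m = fit_ols(X[list(truth.planted_names)], y)
        se = 1.0 / np.sqrt(spec.n_compounds)  # unit-variance regressors
        for name, coef in zip(truth.planted_names, truth.coefficients):
            assert abs(m.raw_coefficients[name] - coef) < 3 * se

    def test_equicorrelation_structure(self):
        spec = QsarSimSpec(n_compounds=6000, n_descriptors=4,
                           correlation=0.5, seed=9)
        X, _, _ = gen_qsar(spec)
        corr = np.corrcoef(X.to_numpy().T)
        off = corr[np.triu_indices(4, 1)]
        assert np.allclose(off, 0.5, atol=0.05)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            QsarSimSpec(n_descriptors=5, correlation=-0.5)

    def test_mismatched_coefficients(self):
        with pytest.raises(ValueError):
            QsarSimSpec(planted=(0, 1), coefficients=(1.0,))

    def test_realized_r2_near_target(self):
        # noise tuned for true R2 ~ 0.85 (signal variance 2.0); single
        # realizations fluctuate, so check the average over seeds
        vals = [gen_qsar(QsarSimSpec(noise_sd=0.6, seed=s))[2].realized_r2
                for s in range(12)]
        assert np.mean(vals) == pytest.approx(0.85, abs=0.05)

    def test_expected_mortality_distribution(self):
        # probit-link means: mortality 0.5 at LC50 by construction
        spec = BioassaySimSpec(lc50=123.0)
        assert stats.norm.cdf(0.0) == pytest.approx(spec.mortality(123.0))
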