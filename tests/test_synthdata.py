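"""Generator contracts: LD structure, dosage noise, disease model, cohorts."""

import numpy as np
import pandas as pd
import pytest

from conftest import tiny_config
from episcan.core import fit_logistic
from episcan.qc import hwe_exact_test
from episcan.synthdata import (
    CohortBundle,
    SimulationConfig,
    add_imputation_noise,
    simulate_genotypes,
    simulate_haplotype_pool,
    simulate_phenotypes,
    simulate_study,
)
from episcan.types import ConfigurationError, DosageMatrix


def _layout(mafs, duplicate_of=None):
    df = pd.DataFrame(
        {"snp_id": [f"v{i}" for i in range(len(mafs))], "target_maf": mafs}
    )
    if duplicate_of:
        df["duplicate_of"] = duplicate_of
    return df


def _pairwise_r2(G):
    c = np.corrcoef(G.T)
    return c**2


class TestHaplotypePool:
    def test_block_size_one_removes_ld(self):
        pool = simulate_haplotype_pool(1000, _layout([0.3] * 12), 1, seed=1)
        r2 = _pairwise_r2(pool.haplotypes.astype(float))
        off = r2[np.triu_indices(12, k=1)]
        assert off.mean() < 0.05

    def test_duplicate_column_r2_is_one(self):
        layout = _layout([0.3, 0.3, 0.25], duplicate_of=["", "v0", ""])
        pool = simulate_haplotype_pool(500, layout, 3, seed=2)
        H = pool.haplotypes.astype(float)
        assert np.corrcoef(H[:, 0], H[:, 1])[0, 1] ** 2 == pytest.approx(1.0)

    def test_pool_frequency_near_target(self):
        pool = simulate_haplotype_pool(2000, _layout([0.3] * 5), 5, seed=3)
        freqs = pool.haplotypes.mean(axis=0)
        assert ((freqs > 0.25) & (freqs < 0.35)).all()

    def test_ld_decays_within_block_and_vanishes_across(self):
        pool = simulate_haplotype_pool(4000, _layout([0.3] * 10), 5, seed=4)
        H = pool.haplotypes.astype(float)
        r2 = _pairwise_r2(H)
        adjacent = np.mean([r2[i, i + 1] for i in (0, 1, 2, 3)])
        distant = np.mean([r2[i, i + 4] for i in (0,)])
        assert adjacent > distant  # monotone decay with index distance
        cross = np.mean([r2[i, j] for i in range(5) for j in range(5, 10)])
        assert cross < 0.05

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_haplotype_pool(1, _layout([0.3]), 1, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_haplotype_pool(10, _layout([0.0]), 1, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_haplotype_pool(10, _layout([0.3]), 0, seed=0)


class TestSimulateGenotypes:
    def test_all_zero_pool_gives_zero_dosages(self):
        pool = simulate_haplotype_pool(100, _layout([0.3, 0.3]), 1, seed=5)
        pool.haplotypes[:] = 0
        dm = simulate_genotypes(pool, 50, seed=6)
        assert (dm.dosages == 0).all()

    def test_hardy_weinberg_proportions(self):
        pool = simulate_haplotype_pool(2000, _layout([0.3]), 1, seed=7)
        dm = simulate_genotypes(pool, 5000, seed=8)
        g = dm.dosages[:, 0]
        f = pool.haplotypes[:, 0].mean()
        assert g.mean() / 2 == pytest.approx(f, abs=0.02)
        counts = [int((g == k).sum()) for k in (0, 1, 2)]
        # genotypes are two independent pool draws -> HWE holds exactly
        assert hwe_exact_test(*counts) > 1e-4

    def test_seed_determinism_and_bad_n(self):
        pool = simulate_haplotype_pool(200, _layout([0.2, 0.4]), 2, seed=9)
        a = simulate_genotypes(pool, 100, seed=10)
        b = simulate_genotypes(pool, 100, seed=10)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        with pytest.raises(ConfigurationError):
            simulate_genotypes(pool, 0, seed=1)


class TestImputationNoise:
    @staticmethod
    def _dm(n=2000, maf=0.3, seed=0):
        rg = np.random.default_rng(seed)
        G = rg.binomial(2, maf, size=(n, 1)).astype(float)
        return DosageMatrix([f"s{i}" for i in range(n)], ["v0"], G)

    def test_r2_one_is_identity(self):
        dm = self._dm()
        noisy, realized = add_imputation_noise(dm, 1.0, seed=1)
        np.testing.assert_array_equal(noisy.dosages, dm.dosages)
        assert realized[0] == 1.0

    def test_low_quality_target_hit_and_recorded(self):
        dm = self._dm()
        noisy, realized = add_imputation_noise(dm, 0.3, seed=2)
        direct = np.corrcoef(dm.dosages[:, 0], noisy.dosages[:, 0])[0, 1] ** 2
        assert 0.25 < realized[0] < 0.35
        assert realized[0] == pytest.approx(direct, abs=1e-12)
        assert noisy.dosages.min() >= 0.0 and noisy.dosages.max() <= 2.0

    def test_constant_snp_flagged_zero(self):
        dm = DosageMatrix(["a", "b", "c"], ["v0"], np.zeros((3, 1)))
        noisy, realized = add_imputation_noise(dm, 0.9, seed=3)
        assert realized[0] == 0.0
        np.testing.assert_array_equal(noisy.dosages, dm.dosages)

    def test_invalid_target_rejected(self):
        with pytest.raises(ConfigurationError):
            add_imputation_noise(self._dm(), 0.0, seed=4)


class TestSimulatePhenotypes:
    @staticmethod
    def _null_config():
        return tiny_config(
            beta0=0.0, beta1=0.0, beta2=0.0, beta3=0.0,
            site_count=1, site_effects=(0.0,), ancestry_effect=(0.0, 0.0),
        )

    @staticmethod
    def _dm(config, n, seed):
        rg = np.random.default_rng(seed)
        ids = config.index_gene.snp_ids() + [
            s for g in config.partner_genes for s in g.snp_ids()
        ]
        G = rg.binomial(2, 0.3, size=(n, len(ids))).astype(float)
        return DosageMatrix([f"s{i}" for i in range(n)], ids, G)

    def test_null_model_case_fraction_half(self):
        config = self._null_config()
        dm = self._dm(config, 5000, seed=1)
        pheno = simulate_phenotypes(dm, config, seed=2)
        frac = pheno["status"].mean()
        assert abs(frac - 0.5) < 2 * np.sqrt(0.25 / 5000)

    def test_seed_determinism(self):
        config = self._null_config()
        dm = self._dm(config, 500, seed=3)
        a = simulate_phenotypes(dm, config, seed=4)
        b = simulate_phenotypes(dm, config, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_planted_snp_is_error(self):
        config = self._null_config()
        dm = DosageMatrix(["a", "b"], ["other"], np.zeros((2, 1)))
        with pytest.raises(ConfigurationError):
            simulate_phenotypes(dm, config, seed=5)

    def test_interaction_coefficient_recovered_by_refit(self):
        """Parameter-recovery oracle: refitting the generative model on a
        large draw returns the planted interaction within ~2 SE."""
        config = tiny_config(
            beta0=-0.3, beta1=0.0, beta2=0.0, beta3=float(np.log(2.0)),
            site_count=1, site_effects=(0.0,), ancestry_effect=(0.0, 0.0),
        )
        dm = self._dm(config, 50_000, seed=6)
        pheno = simulate_phenotypes(dm, config, seed=7)
        snp_a, snp_b = config.planted_snp_ids()
        dA, dB = dm.column(snp_a), dm.column(snp_b)
        X = np.column_stack([np.ones(len(dA)), dA, dB, dA * dB])
        fit = fit_logistic(pheno["status"].to_numpy(dtype=float), X)
        assert fit.coefficients[3] == pytest.approx(np.log(2.0), abs=0.05)


class TestSimulateStudy:
    def test_cohorts_are_independent_draws(self, small_bundle):
        disc = small_bundle.discovery.dosages
        rep = small_bundle.replication.dosages
        assert disc.snp_ids == rep.snp_ids
        n = min(disc.n_samples, rep.n_samples)
        for j in range(0, disc.n_snps, 7):
            a, b = disc.dosages[:n, j], rep.dosages[:n, j]
            if a.std() > 0 and b.std() > 0:
                assert abs(np.corrcoef(a, b)[0, 1]) < 0.15

    def test_deterministic_given_seed(self):
        cfg = tiny_config(n_cases=80, n_controls=80, n_background_snps=20)
        b1 = simulate_study(cfg, seed=77)
        b2 = simulate_study(cfg, seed=77)
        np.testing.assert_array_equal(
            b1.discovery.dosages.dosages, b2.discovery.dosages.dosages
        )
        pd.testing.assert_frame_equal(b1.discovery.samples, b2.discovery.samples)

    def test_case_control_quotas_exact(self, small_bundle):
        counts = small_bundle.discovery.samples["status"].value_counts()
        assert counts[1] == small_bundle.truth.n_cases
        assert counts[0] == small_bundle.truth.n_controls

    def test_minor_allele_convention(self, small_bundle):
        means = np.nanmean(small_bundle.discovery.dosages.dosages, axis=0)
        assert means.max() <= 1.0 + 1e-9

    def test_round_trip_through_files(self, small_bundle, tmp_path):
        small_bundle.save(tmp_path)
        back = CohortBundle.load(tmp_path)
        np.testing.assert_allclose(
            back.discovery.dosages.dosages,
            small_bundle.discovery.dosages.dosages,
            atol=5e-5,
        )
        assert back.truth.to_dict() == small_bundle.truth.to_dict()
        assert [r.gene for r in back.regions] == [
            r.gene for r in small_bundle.regions
        ]
        assert (
            back.discovery.samples["status"].tolist()
            == small_bundle.discovery.samples["status"].tolist()
        )

    def test_generative_inferential_consistency(self):
        """Refitting the true four-term model across replicates covers the
        planted coefficients: all four within 3 SE in >= 95% of runs."""
        config = tiny_config(
            n_cases=600, n_controls=600,
            beta0=-0.3, beta1=0.15, beta2=0.1, beta3=float(np.log(2.0)),
            site_count=1, site_effects=(0.0,), ancestry_effect=(0.0, 0.0),
            n_background_snps=0,
            imputation_r2_low=1.0, imputation_r2_high=1.0,
        )
        truth = np.array([config.beta1, config.beta2, config.beta3])
        hits = 0
        n_rep = 100
        for r in range(n_rep):
            bundle = simulate_study(config, seed=1000 + r)
            dm = bundle.discovery.dosages
            y = bundle.discovery.samples["status"].to_numpy(dtype=float)
            sa, sb = config.planted_snp_ids()
            dA, dB = dm.column(sa), dm.column(sb)
            X = np.column_stack([np.ones(len(y)), dA, dB, dA * dB])
            fit = fit_logistic(y, X)
            if not fit.converged:
                continue
            # the intercept absorbs the case-control ascertainment; the
            # slope coefficients are the comparable quantities
            ok = np.abs(fit.coefficients[1:] - truth) <= 3 * fit.standard_errors[1:]
            hits += bool(ok.all())
        assert hits >= 0.95 * n_rep
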