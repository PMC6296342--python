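"""Generator: determinism, configured moments, and the generating identity."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from methmod import GeneratorConfig, ValidationError, simulate_cohort
from methmod.simulate import (
    generate_cell_reference,
    generate_methylation,
    generate_phenotypes,
)


class TestPhenotypes:
    def test_moments_match_configuration_at_large_n(self):
        cfg = GeneratorConfig(n_samples=10_000, seed=5)
        pheno = generate_phenotypes(cfg)
        n = len(pheno)
        p = cfg.smoking_prevalence
        se_p = np.sqrt(p * (1 - p) / n)
        assert abs(pheno["smoking_status"].mean() - p) < 3 * se_p
        se_age = cfg.age_sd / np.sqrt(n)
        assert abs(pheno["age"].mean() - cfg.age_mean) < 3 * se_age
        # moderator: standard normal, configured correlation with sex
        assert abs(pheno["latent_mmthfr"].mean()) < 3 / np.sqrt(n)
        r = np.corrcoef(pheno["latent_mmthfr"], pheno["male"])[0, 1]
        assert abs(r - cfg.mmthfr_sex_corr) < 0.05
        # cell fractions: configured means, sum below 1
        means = pheno[["cd8t", "cd4t", "nk", "bcell", "mono"]].mean().to_numpy()
        assert np.allclose(means, cfg.cell_fraction_means, atol=0.01)
        assert (pheno[["cd8t", "cd4t", "nk", "bcell", "mono"]].sum(axis=1) <= 1).all()

    def test_empty_cohort_allowed(self):
        pheno = generate_phenotypes(GeneratorConfig(n_samples=0))
        assert len(pheno) == 0

    def test_same_seed_is_bitwise_identical(self):
        cfg = GeneratorConfig(n_samples=50, seed=9)
        a = generate_phenotypes(cfg)
        b = generate_phenotypes(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_consumption_monotone_in_smoking(self):
        pheno = generate_phenotypes(GeneratorConfig(n_samples=2000, seed=1))
        assert (pheno.loc[pheno.smoking_status == 0, "consumption"] == 0).all()
        assert pheno.loc[pheno.smoking_status == 1, "consumption"].mean() > 1.0
        assert pheno["consumption"].between(0, 6).all()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("smoking_prevalence", 1.5),
            ("precision_phi", -1.0),
            ("n_hyper", -2),
            ("mmthfr_sex_corr", 1.0),
            ("cell_fraction_means", (0.5, 0.5, 0.2, 0.1, 0.1)),
        ],
    )
    def test_invalid_config_names_the_field(self, field, value):
        cfg = GeneratorConfig(**{field: value})
        with pytest.raises(ValidationError, match=field):
            cfg.validate()


class TestCellReference:
    def test_single_celltype_degenerate(self):
        ref = generate_cell_reference(20, 1, seed=0)
        assert ref.values.shape == (20, 1)

    def test_deterministic(self):
        a = generate_cell_reference(30, 5, seed=4).values
        b = generate_cell_reference(30, 5, seed=4).values
        pd.testing.assert_frame_equal(a, b)

    def test_all_column_pairs_distinct(self):
        ref = generate_cell_reference(100, 5, seed=2).values.to_numpy()
        for i in range(5):
            for j in range(i + 1, 5):
                assert np.linalg.norm(ref[:, i] - ref[:, j]) > 0

    def test_zero_celltypes_rejected(self):
        with pytest.raises(ValidationError):
            generate_cell_reference(10, 0)


class TestMethylation:
    def test_values_strictly_inside_unit_interval(self, small_cohort):
        _, matrix, *_ = small_cohort
        vals = matrix.values.to_numpy()
        assert (vals > 0).all() and (vals < 1).all()

    def test_noiseless_mode_equals_inverse_logit_of_linear_predictor(self):
        cfg = GeneratorConfig(n_samples=40, n_hyper=3, n_hypo=3, n_null=2, seed=7)
        pheno = generate_phenotypes(cfg)
        matrix, truth = generate_methylation(cfg, pheno, noise=False)
        row = truth.loci.iloc[0]
        S = pheno["smoking_status"].to_numpy(float)
        M = pheno["latent_mmthfr"].to_numpy(float)
        eta = (
            row["b0"]
            + row["beta_smoking"] * S
            + row["beta_mmthfr"] * M
            + row["beta_interaction"] * S * M
            + row["beta_male"] * pheno["male"].to_numpy(float)
            + row["beta_age"] * (pheno["age"].to_numpy(float) - cfg.age_mean)
            + sum(
                row[f"cell_{c}"] * (pheno[c].to_numpy(float) - m)
                for c, m in zip(
                    ("cd8t", "cd4t", "nk", "bcell", "mono"), cfg.cell_fraction_means
                )
            )
        )
        np.testing.assert_allclose(
            matrix.values.loc[truth.loci.index[0]].to_numpy(), expit(eta), rtol=1e-12
        )

    def test_beta_moments_single_locus(self):
        # one locus at fixed mu=0.3, phi=50: mean of n draws within 3 SE
        n, mu, phi = 20_000, 0.3, 50.0
        rng = np.random.default_rng(3)
        draws = rng.beta(mu * phi, (1 - mu) * phi, size=n)
        se = np.sqrt(mu * (1 - mu) / (1 + phi)) / np.sqrt(n)
        assert abs(draws.mean() - mu) < 3 * se

    def test_difference_in_differences_recovers_interaction(self):
        # beta_SM=+0.5, M in {-1,+1}: logit-scale DiD of group means = 2*0.5
        rng = np.random.default_rng(8)
        n = 100_000
        S = rng.binomial(1, 0.5, n).astype(float)
        M = rng.choice([-1.0, 1.0], n)
        mu = expit(0.0 + 0.5 * S * M)
        y = rng.beta(mu * 200, (1 - mu) * 200)
        g = {}
        for s in (0, 1):
            for m in (-1.0, 1.0):
                g[(s, m)] = logit(y[(S == s) & (M == m)].mean())
        did = (g[(1, 1.0)] - g[(0, 1.0)]) - (g[(1, -1.0)] - g[(0, -1.0)])
        assert abs(did - 1.0) < 0.05

    def test_sign_pattern_by_construction(self, small_cohort):
        _, _, _, _, truth = small_cohort
        loci = truth.loci
        hyper = loci[loci["class"] == "hyper"]
        hypo = loci[loci["class"] == "hypo"]
        null = loci[loci["class"] == "null"]
        assert (hyper["beta_smoking"] > 0).all() and (hyper["beta_interaction"] < 0).all()
        assert (hypo["beta_smoking"] < 0).all() and (hypo["beta_interaction"] > 0).all()
        assert (null["beta_interaction"] == 0).all()

    def test_full_cohort_deterministic_under_seed(self):
        cfg = GeneratorConfig(n_samples=30, n_hyper=3, n_hypo=3, n_null=2, seed=21)
        m1, p1, r1, t1 = simulate_cohort(cfg)
        m2, p2, r2, t2 = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(t1.loci, t2.loci)

    def test_invalid_phi_rejected(self):
        cfg = GeneratorConfig(n_samples=10, precision_phi=0.0)
        with pytest.raises(ValidationError):
            pheno = generate_phenotypes(GeneratorConfig(n_samples=10))
            generate_methylation(cfg, pheno)

    def test_null_strata_exchangeable(self):
        # all effects zero: smoking x moderator group means indistinguishable
        cfg = GeneratorConfig(
            n_samples=4000,
            n_hyper=0,
            n_hypo=0,
            n_null=1,
            beta_smoking=0.0,
            beta_interaction=0.0,
            cell_effect_sd=0.0,
            nuisance_effect_scale=0.0,
            seed=6,
        )
        pheno = generate_phenotypes(cfg)
        matrix, _ = generate_methylation(cfg, pheno)
        y = matrix.values.iloc[0].to_numpy()
        S = pheno["smoking_status"].to_numpy()
        M = (pheno["latent_mmthfr"] > 0).to_numpy()
        means = [y[(S == s) & (M == m)].mean() for s in (0, 1) for m in (False, True)]
        assert np.ptp(means) < 6 * y.std() / np.sqrt(len(y) / 4)
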