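"""Per-locus scan, p-value adjustment, and interaction classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from methmod import (
    GeneratorConfig,
    ValidationError,
    adjust_pvalues,
    classify_interactions,
    fit_locus_pair,
    scan_loci,
)
from methmod.moderation import InteractionClassification, LocusScanRecord, ScanResult
from methmod.simulate import generate_methylation, generate_phenotypes


def _pheno(n, rng):
    cfg = GeneratorConfig(n_samples=n, seed=int(rng.integers(0, 2**31 - 1)))
    return generate_phenotypes(cfg)


def _locus(pheno, b_s, b_m, b_sm, phi, rng):
    S = pheno["smoking_status"].to_numpy(float)
    M = pheno["latent_mmthfr"].to_numpy(float)
    mu = expit(0.2 + b_s * S + b_m * M + b_sm * S * M)
    return rng.beta(mu * phi, (1 - mu) * phi)


class TestFitLocusPair:
    def test_interaction_sign_recovered(self, rng):
        # true b_SM = +0.6 at n=180: sign "+" recovered in >= 95% of reps
        hits, reps = 0, 40
        for _ in range(reps):
            pheno = _pheno(180, rng)
            y = _locus(pheno, -0.1, 0.0, 0.6, 50.0, rng)
            rec = fit_locus_pair(y, pheno, pheno["latent_mmthfr"])
            if rec.converged and rec.interaction_sign == "+":
                hits += 1
        assert hits / reps >= 0.95

    def test_constant_response_flagged_not_raised(self, rng):
        pheno = _pheno(60, rng)
        rec = fit_locus_pair(np.full(60, 0.5), pheno, pheno["latent_mmthfr"])
        assert not rec.converged and rec.direction is None

    def test_nested_models_agree_under_null_at_large_n(self, rng):
        # no true interaction, centered moderator: Model 1 and Model 2
        # smoking coefficients coincide asymptotically
        pheno = _pheno(5000, rng)
        mmthfr = pheno["latent_mmthfr"] - pheno["latent_mmthfr"].mean()
        y = _locus(pheno, 0.3, 0.1, 0.0, 50.0, rng)
        rec = fit_locus_pair(y, pheno, mmthfr)
        assert rec.converged
        assert abs(rec.model1["smoking"]["b"] - rec.model2["smoking"]["b"]) < 0.02

    def test_direction_class_follows_smoking_sign(self, rng):
        pheno = _pheno(300, rng)
        up = fit_locus_pair(_locus(pheno, 0.5, 0, 0, 80, rng), pheno, pheno["latent_mmthfr"])
        dn = fit_locus_pair(_locus(pheno, -0.5, 0, 0, 80, rng), pheno, pheno["latent_mmthfr"])
        assert up.direction == "hyper" and dn.direction == "hypo"


class TestScan:
    def test_power_and_size_on_mixed_panel(self, small_cohort):
        from methmod.indices import mmthfr_index
        from methmod.preprocess import squeeze_unit_interval

        cfg, matrix, pheno, _, truth = small_cohort
        matrix = matrix.with_values(squeeze_unit_interval(matrix.values, matrix.n_samples))
        mmthfr = mmthfr_index(matrix)
        scan = scan_loci(matrix, pheno, mmthfr, locus_list=cfg.locus_ids)
        frame = scan.to_frame().set_index("probe_id")
        effect = truth.loci.index[truth.loci["class"] != "null"]
        sig = frame.loc[effect, "int_p"] < 0.05
        assert sig.mean() > 0.5  # majority of effect loci detected

    def test_empty_locus_list(self, small_cohort):
        _, matrix, pheno, _, _ = small_cohort
        from methmod.indices import mmthfr_index

        scan = scan_loci(matrix, pheno, mmthfr_index(matrix), locus_list=[])
        assert len(scan) == 0

    def test_unknown_locus_rejected(self, small_cohort):
        _, matrix, pheno, _, _ = small_cohort
        from methmod.indices import mmthfr_index

        with pytest.raises(ValidationError):
            scan_loci(matrix, pheno, mmthfr_index(matrix), locus_list=["nope"])

    def test_scan_order_follows_input_order(self, small_cohort):
        cfg, matrix, pheno, _, _ = small_cohort
        from methmod.indices import mmthfr_index
        from methmod.preprocess import squeeze_unit_interval

        matrix = matrix.with_values(squeeze_unit_interval(matrix.values, matrix.n_samples))
        mmthfr = mmthfr_index(matrix)
        loci = cfg.locus_ids[:6]
        fwd = scan_loci(matrix, pheno, mmthfr, locus_list=loci)
        rev = scan_loci(matrix, pheno, mmthfr, locus_list=loci[::-1])
        assert [r.probe_id for r in fwd.records] == loci
        by_probe_fwd = {r.probe_id: r.model2["smoking_x_mmthfr"]["b"] for r in fwd.records}
        by_probe_rev = {r.probe_id: r.model2["smoking_x_mmthfr"]["b"] for r in rev.records}
        for probe in loci:
            assert by_probe_fwd[probe] == pytest.approx(by_probe_rev[probe], abs=1e-12)


class TestAdjustPvalues:
    def test_single_test_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues(np.array([0.03])), [0.03])

    def test_bonferroni_hand_worked(self):
        np.testing.assert_allclose(
            adjust_pvalues(np.array([0.01, 0.04]), "bonferroni"), [0.02, 0.08]
        )

    def test_bh_hand_worked_step_up(self):
        # (0.01, 0.02, 0.03, 0.04) -> all 0.04 by the step-up minima
        np.testing.assert_allclose(
            adjust_pvalues(np.array([0.01, 0.02, 0.03, 0.04]), "bh"),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_adjusted_never_below_nominal(self, rng):
        p = rng.uniform(0, 1, 50)
        for method in ("bonferroni", "bh"):
            assert (adjust_pvalues(p, method) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues(np.array([1.2]))


def _toy_scan(records):
    return ScanResult(records=records)


def _record(probe, direction, b_int, p, converged=True):
    rec = LocusScanRecord(probe_id=probe, converged=converged)
    if converged:
        rec.direction = direction
        rec.interaction_sign = "+" if b_int > 0 else "-"
        rec.interaction_p = p
        rec.interaction_p_bonferroni = min(1.0, p * 3)
        rec.interaction_p_bh = p
        rec.model2 = {"smoking_x_mmthfr": {"b": b_int, "p": p}}
    return rec


class TestClassification:
    def test_toy_rule_application(self):
        scan = _toy_scan(
            [
                _record("a", "hyper", -1.0, 0.01),
                _record("b", "hypo", +1.0, 0.04),
                _record("c", "hypo", +1.0, 0.20),
            ]
        )
        cls = classify_interactions(scan, alpha=0.05, tier="nominal")
        assert cls.counts[("hyper", "-")] == 1
        assert cls.counts[("hypo", "+")] == 1
        assert cls.n_classified == 2 and cls.n_excluded == 1

    def test_no_significant_interactions(self):
        scan = _toy_scan([_record("a", "hyper", -1.0, 0.9)])
        cls = classify_interactions(scan)
        assert cls.n_classified == 0

    def test_counts_partition_scanned(self):
        scan = _toy_scan(
            [
                _record("a", "hyper", -1.0, 0.01),
                _record("b", "hypo", 1.0, 0.5),
                _record("c", None, 0.0, 1.0, converged=False),
            ]
        )
        cls = classify_interactions(scan)
        assert cls.n_classified + cls.n_excluded == cls.n_scanned == 3

    def test_bonferroni_tier_is_subset_of_nominal(self):
        recs = [
            _record("a", "hyper", -1.0, 0.001),
            _record("b", "hypo", 1.0, 0.03),
            _record("c", "hypo", 1.0, 0.3),
        ]
        scan = _toy_scan(recs)
        nom = classify_interactions(scan, tier="nominal")
        bon = classify_interactions(scan, tier="bonferroni")
        for key in nom.members:
            assert set(bon.members[key]) <= set(nom.members[key])

    def test_sign_concordance_on_synthetic_cohort(self, small_cohort):
        from methmod.indices import mmthfr_index
        from methmod.preprocess import squeeze_unit_interval

        cfg, matrix, pheno, _, _ = small_cohort
        matrix = matrix.with_values(squeeze_unit_interval(matrix.values, matrix.n_samples))
        scan = scan_loci(matrix, pheno, mmthfr_index(matrix), locus_list=cfg.locus_ids)
        cls = classify_interactions(scan)
        assert cls.sign_concordant_fraction() > 0.9
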