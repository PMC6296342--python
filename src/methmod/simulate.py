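"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a middle-aged smoking/methylation
cohort: beta-distributed methylation in (0, 1); a binary smoking exposure;
a latent promoter-methylation moderator (mMTHFR) correlated with sex;
smoking main effects of both signs on the logit scale with interaction
effects of the opposite sign (hyper loci get negative interactions, hypo
loci positive ones — the dominant pattern the analysis is built to detect);
and leukocyte-composition confounding with realistic mean fractions.

Every draw flows through one ``numpy.random.Generator`` seeded from the
config, so a cohort is bitwise reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import CELL_TYPES, BetaMatrix, CellReference, ValidationError


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the source cohort's descriptives: n=180 samples,
    smoking prevalence 0.483, age 48.861 (SD 8.586) years, 37.2% male,
    moderator-sex correlation 0.412, and mean mononuclear-cell fractions
    (CD8T, CD4T, NK, B, Mono) = (0.137, 0.284, 0.071, 0.165, 0.144)
    summing to 0.801 (granulocytes are absent from the pellet). The locus
    mix 66 hyper / 205 hypo / 29 null mirrors the sign-concordant index
    sizes within a 300-locus panel. Effect magnitudes are on the logit
    scale of the beta-regression mean model.
    """

    n_samples: int = 180
    n_hyper: int = 66
    n_hypo: int = 205
    n_null: int = 29
    beta_smoking: float = 0.15
    beta_interaction: float = 0.25
    precision_phi: float = 50.0
    smoking_prevalence: float = 0.483
    age_mean: float = 48.861
    age_sd: float = 8.586
    male_fraction: float = 0.372
    mmthfr_sex_corr: float = 0.412
    cell_fraction_means: tuple = (0.137, 0.284, 0.071, 0.165, 0.144)
    cell_concentration: float = 50.0
    cell_effect_sd: float = 1.0
    nuisance_effect_scale: float = 1.0
    n_mmthfr_probes: int = 7
    n_reference_probes: int = 60
    seed: int = 0

    def validate(self) -> None:
        for name in ("smoking_prevalence", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"config field {name}={v} must lie in [0, 1]")
        if self.precision_phi <= 0:
            raise ValidationError("config field precision_phi must be > 0")
        if self.cell_concentration <= 0:
            raise ValidationError("config field cell_concentration must be > 0")
        for name in ("n_samples", "n_hyper", "n_hypo", "n_null", "n_mmthfr_probes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"config field {name} must be >= 0")
        if not -1.0 < self.mmthfr_sex_corr < 1.0:
            raise ValidationError("config field mmthfr_sex_corr must lie in (-1, 1)")
        m = np.asarray(self.cell_fraction_means, dtype=float)
        if (m < 0).any() or m.sum() > 1.0 + 1e-12:
            raise ValidationError(
                "config field cell_fraction_means must be nonnegative and sum to <= 1"
            )
        if self.age_sd < 0:
            raise ValidationError("config field age_sd must be >= 0")

    @property
    def n_loci(self) -> int:
        return self.n_hyper + self.n_hypo + self.n_null

    @property
    def locus_ids(self) -> list:
        return [f"locus_{i:04d}" for i in range(self.n_loci)]

    @property
    def mmthfr_probe_ids(self) -> list:
        return [f"MTHFR_{i:02d}" for i in range(self.n_mmthfr_probes)]

    @property
    def locus_classes(self) -> list:
        return (
            ["hyper"] * self.n_hyper + ["hypo"] * self.n_hypo + ["null"] * self.n_null
        )


@dataclass
class GroundTruth:
    """Generating coefficients per locus, plus the latent moderator per sample.

    ``loci`` columns: class, b0, beta_smoking, beta_mmthfr, beta_interaction,
    beta_male, beta_age, and one cell-offset column per cell type.
    """

    loci: pd.DataFrame
    latent_mmthfr: pd.Series


def generate_phenotypes(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a phenotype table for ``config.n_samples`` subjects.

    Smoking ~ Bernoulli(prevalence); age ~ Normal(mean, sd); diet uniform on
    {1..4}; male ~ Bernoulli(male_fraction); cell fractions Dirichlet with the
    configured means (a hidden remainder component absorbs 1 - sum(means));
    the latent moderator is standard normal with the configured correlation
    to the male indicator. Average cigarette consumption is a noisy monotone
    function of smoking status clipped into [0, 6].
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    smoking = rng.binomial(1, config.smoking_prevalence, size=n)
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    male = rng.binomial(1, config.male_fraction, size=n)
    diet = rng.integers(1, 5, size=n)

    # Latent moderator: exact population correlation rho with the male
    # indicator via its standardized score, orthogonal Gaussian remainder.
    rho = config.mmthfr_sex_corr
    p = config.male_fraction
    if n and 0.0 < p < 1.0:
        male_std = (male - p) / np.sqrt(p * (1.0 - p))
    else:
        male_std = np.zeros(n)
    latent = rho * male_std + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)

    # Consumption: smokers report around half-a-pack on the 0-6 ordinal
    # scale, non-smokers 0; monotone in status by construction.
    consumption = np.clip(smoking * rng.normal(3.0, 1.2, size=n), 0.0, 6.0)

    means = np.asarray(config.cell_fraction_means, dtype=float)
    remainder = 1.0 - means.sum()
    alpha = config.cell_concentration * np.append(means, remainder)
    if n:
        fractions = rng.dirichlet(alpha, size=n)[:, : len(means)]
    else:
        fractions = np.zeros((0, len(means)))

    df = pd.DataFrame(
        {
            "smoking_status": smoking,
            "consumption": consumption,
            "male": male,
            "age": age,
            "diet": diet,
            "latent_mmthfr": latent,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    for k, cell in enumerate(CELL_TYPES):
        df[cell] = fractions[:, k]
    return df


def generate_cell_reference(
    n_probes: int, n_celltypes: int = len(CELL_TYPES), seed: int = 0
) -> CellReference:
    """Generate a probe x cell-type reference of discriminating beta profiles.

    Columns are drawn independently and uniformly over (0.05, 0.95), so any
    two cell types differ at essentially every probe — the synthetic analogue
    of the sorted-cell reference used for constrained-projection
    deconvolution.
    """
    if n_celltypes < 1:
        raise ValidationError("n_celltypes must be >= 1")
    if n_probes < 1:
        raise ValidationError("n_probes must be >= 1")
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.05, 0.95, size=(n_probes, n_celltypes))
    if n_celltypes <= len(CELL_TYPES):
        cols = list(CELL_TYPES[:n_celltypes])
    else:
        cols = [f"cell{k}" for k in range(n_celltypes)]
    probes = [f"REF_{i:04d}" for i in range(n_probes)]
    return CellReference(pd.DataFrame(vals, index=probes, columns=cols))


def _draw_locus_coefficients(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = config.locus_classes
    n = len(classes)
    b0 = _logit(rng.uniform(0.2, 0.8, size=n))
    sign = np.array([+1.0 if c == "hyper" else -1.0 if c == "hypo" else 0.0 for c in classes])
    beta_s = sign * config.beta_smoking
    beta_sm = -sign * config.beta_interaction
    # Small moderator main effects of either sign; null loci have no
    # interaction but may still carry main effects of the moderator.
    scale = config.nuisance_effect_scale
    beta_m = rng.normal(0.0, 0.03, size=n) * scale
    beta_male = rng.normal(0.0, 0.05, size=n) * scale
    beta_age = rng.normal(0.0, 0.005, size=n) * scale
    cell = rng.normal(0.0, config.cell_effect_sd, size=(n, len(CELL_TYPES)))
    df = pd.DataFrame(
        {
            "class": classes,
            "b0": b0,
            "beta_smoking": beta_s,
            "beta_mmthfr": beta_m,
            "beta_interaction": beta_sm,
            "beta_male": beta_male,
            "beta_age": beta_age,
        },
        index=pd.Index(config.locus_ids, name="probe_id"),
    )
    for k, ct in enumerate(CELL_TYPES):
        df[f"cell_{ct}"] = cell[:, k]
    return df


def generate_methylation(
    config: GeneratorConfig,
    pheno: pd.DataFrame,
    reference: CellReference | None = None,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> tuple[BetaMatrix, GroundTruth]:
    """Generate the probe x sample beta matrix and its ground truth.

    For locus j and sample i the mean is
    ``mu_ij = expit(b0_j + bS_j*S_i + bM_j*M_i + bSM_j*S_i*M_i
    + bMale_j*male_i + bAge_j*(age_i - age_mean) + sum_k g_jk*(w_ik - wbar_k))``
    and the emitted value is Beta(mu*phi, (1-mu)*phi), or exactly ``mu`` when
    ``noise=False``. Cell-fraction offsets are centered at the configured
    means so the intercept keeps its baseline interpretation while cell
    composition genuinely confounds the moderator (both correlate with sex).

    The seven moderator probes are noisy monotone (logit-linear) transforms
    of the latent moderator, so their standardized mean recovers it. If a
    ``reference`` is given, its probes are appended as rows whose profiles
    are the reference mixed by each sample's true fractions (plus beta
    noise), making reference-based deconvolution exercisable end to end.
    """
    config.validate()
    if config.precision_phi <= 0:
        raise ValidationError("precision_phi must be > 0")
    if len(pheno) != config.n_samples:
        raise ValidationError(
            f"phenotype table has {len(pheno)} rows, config expects {config.n_samples}"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    phi = config.precision_phi
    n = config.n_samples

    truth_loci = _draw_locus_coefficients(config, rng)
    S = pheno["smoking_status"].to_numpy(dtype=float)
    M = pheno["latent_mmthfr"].to_numpy(dtype=float)
    male = pheno["male"].to_numpy(dtype=float)
    age_c = pheno["age"].to_numpy(dtype=float) - config.age_mean
    W = pheno[list(CELL_TYPES)].to_numpy(dtype=float)
    W_c = W - np.asarray(config.cell_fraction_means, dtype=float)

    eta = (
        truth_loci["b0"].to_numpy()[:, None]
        + truth_loci["beta_smoking"].to_numpy()[:, None] * S[None, :]
        + truth_loci["beta_mmthfr"].to_numpy()[:, None] * M[None, :]
        + truth_loci["beta_interaction"].to_numpy()[:, None] * (S * M)[None, :]
        + truth_loci["beta_male"].to_numpy()[:, None] * male[None, :]
        + truth_loci["beta_age"].to_numpy()[:, None] * age_c[None, :]
        + truth_loci[[f"cell_{ct}" for ct in CELL_TYPES]].to_numpy() @ W_c.T
    )
    mu = _expit(eta)

    def draw(mu_block):
        if not noise:
            return mu_block
        return rng.beta(mu_block * phi, (1.0 - mu_block) * phi)

    blocks = [pd.DataFrame(draw(mu), index=config.locus_ids, columns=pheno.index)]

    # Moderator probes: promoter-island CpGs are lowly methylated; each probe
    # is a logit-linear readout of the latent moderator with high precision.
    if config.n_mmthfr_probes:
        a_p = _logit(rng.uniform(0.10, 0.30, size=config.n_mmthfr_probes))
        b_p = rng.uniform(0.4, 0.7, size=config.n_mmthfr_probes)
        mu_m = _expit(a_p[:, None] + b_p[:, None] * M[None, :])
        vals = mu_m if not noise else rng.beta(mu_m * 200.0, (1.0 - mu_m) * 200.0)
        blocks.append(pd.DataFrame(vals, index=config.mmthfr_probe_ids, columns=pheno.index))

    if reference is not None:
        # marker rows are pure mixtures of the reference profiles by the true
        # fractions, so noiseless deconvolution recovers the fractions exactly
        R = reference.values.to_numpy(dtype=float)
        mix = np.clip(R @ W.T, 1e-4, 1 - 1e-4)
        vals = mix if not noise else rng.beta(mix * phi, (1.0 - mix) * phi)
        blocks.append(pd.DataFrame(vals, index=reference.probe_ids, columns=pheno.index))

    values = pd.concat(blocks)
    values.index.name = "probe_id"
    annotation = pd.DataFrame(
        {
            "gene": ["SYN"] * config.n_loci
            + ["MTHFR"] * config.n_mmthfr_probes
            + (["REF"] * len(reference.probe_ids) if reference is not None else []),
            "design_type": "II",
        },
        index=values.index,
    )
    matrix = BetaMatrix(values=values, annotation=annotation)
    truth = GroundTruth(loci=truth_loci, latent_mmthfr=pheno["latent_mmthfr"].copy())
    return matrix, truth


def generate_qc_matrices(
    matrix: BetaMatrix,
    rng: np.random.Generator,
    detection_fail_rate: float = 0.002,
    low_beadcount_rate: float = 0.002,
) -> BetaMatrix:
    """Attach plausible detection p-value and beadcount matrices.

    Almost all measurements are clean (p near 0, beadcounts ~ 3 + Poisson(12));
    a small fraction fail detection (p > 0.05) or fall below 3 beads, giving
    the QC filters something to act on.
    """
    shape = matrix.values.shape
    p = rng.uniform(0.0, 0.01, size=shape)
    fail = rng.random(shape) < detection_fail_rate
    p[fail] = rng.uniform(0.05, 1.0, size=int(fail.sum()))
    beads = 3 + rng.poisson(12.0, size=shape)
    low = rng.random(shape) < low_beadcount_rate
    beads[low] = rng.integers(0, 3, size=int(low.sum()))
    return BetaMatrix(
        values=matrix.values,
        detection_pvals=pd.DataFrame(p, index=matrix.values.index, columns=matrix.values.columns),
        beadcounts=pd.DataFrame(beads, index=matrix.values.index, columns=matrix.values.columns),
        annotation=matrix.annotation,
    )


def simulate_cohort(
    config: GeneratorConfig | None = None,
    with_qc_matrices: bool = False,
) -> tuple[BetaMatrix, pd.DataFrame, CellReference, GroundTruth]:
    """One-call cohort: phenotypes, reference, methylation, ground truth."""
    if config is None:
        config = GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    pheno = generate_phenotypes(config, rng)
    reference = generate_cell_reference(
        config.n_reference_probes, len(CELL_TYPES), seed=config.seed + 7
    )
    matrix, truth = generate_methylation(config, pheno, reference, rng)
    if with_qc_matrices:
        matrix = generate_qc_matrices(matrix, rng)
    return matrix, pheno, reference, truth
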