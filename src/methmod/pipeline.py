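"""End-to-end orchestration, file I/O, and the reproducible pipeline report.

Stage order: QC filters -> quantile normalization -> boundary squeeze ->
cell-type deconvolution (only when the phenotype table lacks fractions) ->
moderator index -> per-locus scan -> interaction classification ->
contingency / chi-square -> outcome indices -> index-level OLS models ->
simple slopes. Identical inputs, config, and seed produce a byte-identical
report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .celltypes import estimate_cell_fractions_matrix
from .consistency import contingency_from_classification, pearson_chi2, row_proportions
from .containers import (
    CELL_TYPES,
    BetaMatrix,
    CellReference,
    ValidationError,
    has_cell_fractions,
    validate_phenotypes,
)
from .index_models import moderated_index_regression, simple_slopes
from .indices import MTHFR_FIRST_EXON_CPGS, build_outcome_indices, mmthfr_index
from .moderation import classify_interactions, scan_loci
from .preprocess import filter_probes, filter_samples, quantile_normalize, squeeze_unit_interval

logger = logging.getLogger("methmod")

DEFAULT_CONFIG = {
    "alpha": 0.05,
    "tier": "nominal",  # nominal | bonferroni | bh
    "smoking_measure": "status",  # status | consumption
    "p_threshold": 0.05,
    "max_failed_fraction": 0.01,
    "beadcount_min": 3,
    "beadcount_fail_fraction": 0.05,
    "p_fail_fraction": 0.01,
    "stratify_by_design_type": True,
    "mmthfr_probes": None,  # None -> MTHFR annotation / default CpG set
    "locus_list": None,  # None -> all non-moderator, non-reference probes
    "seed": 0,
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _read_matrix_tsv(path: Path, what: str) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"missing {what} file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"failed to parse {what} file {path}: {exc}") from exc
    return df


def load_inputs(
    betas: str | Path,
    phenotypes: str | Path,
    detection_p: str | Path | None = None,
    beadcounts: str | Path | None = None,
    annotation: str | Path | None = None,
    reference: str | Path | None = None,
    locus_list: str | Path | None = None,
):
    """Load and cross-validate the pipeline inputs from disk.

    Returns ``(BetaMatrix, phenotype DataFrame, CellReference | None,
    locus list | None)``. Sample ids of the phenotype table must cover the
    beta matrix columns; a supplied locus list must be a subset of the
    probes.
    """
    values = _read_matrix_tsv(Path(betas), "beta matrix")
    det = _read_matrix_tsv(Path(detection_p), "detection p-value") if detection_p else None
    beads = _read_matrix_tsv(Path(beadcounts), "beadcount") if beadcounts else None
    ann = None
    if annotation:
        path = Path(annotation)
        if not path.exists():
            raise ValidationError(f"missing annotation file: {path}")
        ann = pd.read_csv(path, sep="\t", index_col=0)
    pheno_path = Path(phenotypes)
    if not pheno_path.exists():
        raise ValidationError(f"missing phenotype file: {pheno_path}")
    pheno = validate_phenotypes(pd.read_csv(pheno_path))
    missing = [s for s in values.columns if s not in pheno.index]
    if missing:
        raise ValidationError(f"samples present in betas but not phenotypes: {missing[:5]}")
    pheno = pheno.loc[list(values.columns)]
    matrix = BetaMatrix(values=values, detection_pvals=det, beadcounts=beads, annotation=ann)
    ref = None
    if reference:
        ref = CellReference(_read_matrix_tsv(Path(reference), "cell reference"))
    loci = None
    if locus_list:
        path = Path(locus_list)
        if not path.exists():
            raise ValidationError(f"missing locus list file: {path}")
        loci = [line.strip() for line in path.read_text().splitlines() if line.strip()]
        absent = [p for p in loci if p not in values.index]
        if absent:
            raise ValidationError(f"locus list entries absent from betas: {absent[:5]}")
    return matrix, pheno, ref, loci


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _round6(x):
    """Serialize floats at 6 significant digits, keep ints exact."""
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round6(v) for v in x]
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer)):
        return int(x)
    if isinstance(x, (float, np.floating)):
        if not np.isfinite(x):
            return None
        return float(f"{x:.6g}")
    return x


@dataclass
class PipelineReport:
    """Everything the run computed, JSON-serializable and deterministic."""

    config_hash: str
    qc: dict
    index_definitions: dict
    scan: dict
    contingency: dict
    index_models: dict
    simple_slopes: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return _round6(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "qc": self.qc,
                "index_definitions": self.index_definitions,
                "scan": self.scan,
                "contingency": self.contingency,
                "index_models": self.index_models,
                "simple_slopes": self.simple_slopes,
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def run_pipeline(
    matrix: BetaMatrix,
    pheno: pd.DataFrame,
    reference: CellReference | None = None,
    locus_list=None,
    config: dict | None = None,
) -> PipelineReport:
    """Run the full moderated-EWAS pipeline and assemble the report."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    stage = "configure"
    try:
        pheno = validate_phenotypes(pheno)

        stage = "qc"
        qc: dict = {}
        if matrix.detection_pvals is not None:
            matrix, rep = filter_samples(
                matrix, cfg["p_threshold"], cfg["max_failed_fraction"]
            )
            qc["sample_filter"] = rep.to_dict()
            pheno = pheno.loc[[s for s in pheno.index if s in matrix.values.columns]]
        if matrix.detection_pvals is not None or matrix.beadcounts is not None:
            matrix, rep = filter_probes(
                matrix,
                cfg["beadcount_min"],
                cfg["beadcount_fail_fraction"],
                cfg["p_threshold"],
                cfg["p_fail_fraction"],
            )
            qc["probe_filter"] = rep.to_dict()
        logger.info("QC done: %d probes x %d samples", matrix.n_probes, matrix.n_samples)

        stage = "normalize"
        matrix = quantile_normalize(matrix, cfg["stratify_by_design_type"])

        stage = "squeeze"
        matrix = matrix.with_values(
            squeeze_unit_interval(matrix.values, matrix.n_samples)
        )

        stage = "deconvolve"
        if not has_cell_fractions(pheno):
            if reference is None:
                raise ValidationError(
                    "phenotypes lack cell fractions and no reference was supplied"
                )
            fractions = estimate_cell_fractions_matrix(matrix, reference)
            pheno = pheno.join(fractions)
            logger.info("estimated cell fractions for %d samples", len(fractions))

        stage = "mmthfr_index"
        mmthfr = mmthfr_index(matrix, probes=cfg["mmthfr_probes"])
        mmthfr_probes = (
            tuple(cfg["mmthfr_probes"])
            if cfg["mmthfr_probes"]
            else tuple(
                p
                for p in matrix.probe_ids
                if str(p).startswith("MTHFR") or str(p) in MTHFR_FIRST_EXON_CPGS
            )
        )

        stage = "scan"
        if locus_list is None:
            locus_list = cfg["locus_list"]
        if locus_list is None:
            exclude = set(mmthfr_probes)
            if reference is not None:
                exclude |= set(reference.probe_ids)
            locus_list = [p for p in matrix.probe_ids if p not in exclude]
        else:
            surviving = set(matrix.probe_ids)
            dropped = [p for p in locus_list if p not in surviving]
            if dropped:
                logger.info("%d listed loci were removed by QC", len(dropped))
            locus_list = [p for p in locus_list if p in surviving]
        scan = scan_loci(
            matrix,
            pheno,
            mmthfr,
            locus_list=locus_list,
            smoking_measure=cfg["smoking_measure"],
            alpha=cfg["alpha"],
        )
        logger.info("scanned %d loci (%d converged)", len(scan), len(scan.converged_records))

        stage = "classify"
        classification = classify_interactions(scan, alpha=cfg["alpha"], tier=cfg["tier"])
        logger.info(
            "classified %d loci by direction x sign (excluded %d)",
            classification.n_classified,
            classification.n_excluded,
        )

        stage = "contingency"
        table = contingency_from_classification(classification)
        if table.grand_total > 0 and not (
            (table.row_totals == 0).any() or (table.col_totals == 0).any()
        ):
            stat, df, pval = pearson_chi2(table)
            props = row_proportions(table)
            chi2_block = {
                "statistic": stat,
                "df": df,
                "p": pval,
                "row_percent": props.tolist(),
            }
        else:
            chi2_block = {"statistic": None, "df": 1, "p": None, "row_percent": None}
        contingency = {
            "counts": table.counts.tolist(),
            "row_totals": table.row_totals.tolist(),
            "col_totals": table.col_totals.tolist(),
            "grand_total": table.grand_total,
            "sign_concordant_fraction": classification.sign_concordant_fraction(),
            **chi2_block,
        }

        stage = "outcome_indices"
        hypo_idx, hyper_idx, definitions = build_outcome_indices(matrix, classification)

        stage = "index_models"
        models: dict = {}
        slopes: dict = {}
        moderator_sd = float(pd.Series(mmthfr).std(ddof=1))
        for name, idx in (("hypo_index", hypo_idx), ("hyper_index", hyper_idx)):
            if idx is None:
                models[name] = None
                continue
            m1 = moderated_index_regression(
                idx, pheno, mmthfr, cfg["smoking_measure"], with_interaction=False
            )
            m2 = moderated_index_regression(
                idx, pheno, mmthfr, cfg["smoking_measure"], with_interaction=True
            )
            models[name] = {
                "model1": {"terms": m1.coef_table(), "r_squared": m1.r_squared, "n": m1.n_obs},
                "model2": {"terms": m2.coef_table(), "r_squared": m2.r_squared, "n": m2.n_obs},
            }
            ss = simple_slopes(m2, moderator_sd)
            slopes[name] = {
                "slope_low": ss.slope_low,
                "slope_high": ss.slope_high,
                "intercept_low": ss.intercept_low,
                "intercept_high": ss.intercept_high,
                "moderator_sd": ss.moderator_sd,
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    counts_by_tier = {
        tier: classify_interactions(scan, alpha=cfg["alpha"], tier=tier).counts
        for tier in ("nominal", "bonferroni", "bh")
    }
    report = PipelineReport(
        config_hash=_config_hash(cfg),
        qc=qc,
        index_definitions={
            "mmthfr": list(mmthfr_probes),
            "hypo_index": list(definitions["hypo_index"].probes)
            if definitions["hypo_index"]
            else None,
            "hyper_index": list(definitions["hyper_index"].probes)
            if definitions["hyper_index"]
            else None,
        },
        scan={
            "n_loci": len(scan),
            "n_converged": len(scan.converged_records),
            "alpha": cfg["alpha"],
            "tier": cfg["tier"],
            "counts": {
                tier: {f"{d}{s}": n for (d, s), n in counts.items()}
                for tier, counts in counts_by_tier.items()
            },
        },
        contingency=contingency,
        index_models=models,
        simple_slopes=slopes,
    )
    return report


def write_report(report: PipelineReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json())
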