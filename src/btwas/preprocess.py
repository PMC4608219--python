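"""Sample QC, quantile normalization, log2 transform, detection-rate filter.

The QC order is: sample filters first (RIN and missing-value exclusions),
then quantile normalization of the retained samples' raw intensities, then
log2. Transcripts are kept only if their detection rate — the proportion of
samples with detection p-value < 0.05 — is strictly above 50% in every
cohort.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import DEFAULT_COVARIATES, ExpressionStudy

logger = logging.getLogger(__name__)


def filter_samples(
    study: ExpressionStudy,
    min_rin: float = 7.0,
    required_covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> ExpressionStudy:
    """Drop samples with RIN below ``min_rin`` or missing BMI/covariates.

    Exclusion counts per reason are logged and stored under
    ``study.meta["exclusions"]`` on the returned study.

    Raises
    ------
    ValueError
        If no samples survive, naming the responsible filter.
    """
    if "rin" not in study.covariates.columns:
        raise ValueError("covariate table lacks a 'rin' column")
    missing_cols = [
        c for c in required_covariates if c not in study.covariates.columns
    ]
    if missing_cols:
        raise ValueError(f"covariate table lacks columns: {missing_cols}")

    rin_ok = study.covariates["rin"] >= min_rin
    bmi_ok = study.phenotype.notna()
    cov_ok = study.covariates[list(required_covariates)].notna().all(axis=1)

    exclusions = {
        "low_rin": int((~rin_ok).sum()),
        "missing_bmi": int((rin_ok & ~bmi_ok).sum()),
        "missing_covariates": int((rin_ok & bmi_ok & ~cov_ok).sum()),
    }
    keep = study.samples[rin_ok & bmi_ok & cov_ok]
    if len(keep) == 0:
        worst = max(exclusions, key=exclusions.get)
        raise ValueError(
            f"{study.cohort_id}: no samples remain after QC "
            f"(dominant filter: {worst})"
        )
    logger.info(
        "%s: retained %d/%d samples (excluded %s)",
        study.cohort_id, len(keep), study.n_samples, exclusions,
    )
    out = study.subset_samples(keep)
    out.meta["exclusions"] = exclusions
    out.meta["n_before_qc"] = study.n_samples
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the mean empirical distribution.

    After normalization each column's sorted values equal the across-column
    mean of order statistics. Ties within a column receive the mean of the
    reference quantiles of their tied ranks (the limma convention), which
    makes the operation idempotent.
    """
    if matrix.shape[1] < 2:
        warnings.warn(
            "quantile normalization with < 2 samples is a no-op",
            UserWarning,
            stacklevel=2,
        )
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        # fractional (tied) ranks interpolate between adjacent reference
        # order statistics, i.e. tied values share the mean reference value
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_transform(matrix: pd.DataFrame, floor: float = 1.0) -> pd.DataFrame:
    """Elementwise log2; entries <= 0 are clipped to ``floor`` with a warning."""
    values = matrix.to_numpy(dtype=float)
    bad = values <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} nonpositive entries clipped to {floor} "
            "before log2",
            UserWarning,
            stacklevel=2,
        )
        values = np.where(bad, floor, values)
    return pd.DataFrame(
        np.log2(values), index=matrix.index, columns=matrix.columns
    )


@dataclass
class DetectionSummary:
    """Per-probe detection rates per cohort and the combined pass flag."""

    rates: pd.DataFrame  # probe x cohort detection rates
    passed: pd.Series  # bool per probe: rate > threshold in every cohort
    threshold: float
    alpha: float


def detection_filter(
    studies: list[ExpressionStudy],
    threshold: float = 0.5,
    alpha: float = 0.05,
) -> tuple[pd.Index, DetectionSummary]:
    """Keep probes detected (p < ``alpha``) in > ``threshold`` of samples
    in *every* cohort; both inequalities are strict."""
    if not studies:
        raise ValueError("at least one cohort required")
    shared = studies[0].probes
    for s in studies[1:]:
        shared = shared.intersection(s.probes)
    if len(shared) == 0:
        raise ValueError("cohorts share no probes")
    rates = pd.DataFrame(index=shared)
    for s in studies:
        rates[s.cohort_id] = (
            (s.detection_p.loc[shared] < alpha).mean(axis=1)
        )
    passed = (rates > threshold).all(axis=1)
    kept = shared[passed]
    logger.info(
        "detection filter: %d/%d probes pass (> %.0f%% detected in all "
        "%d cohorts)", len(kept), len(shared), 100 * threshold, len(studies),
    )
    return kept, DetectionSummary(
        rates=rates, passed=passed, threshold=threshold, alpha=alpha
    )


def preprocess_study(
    study: ExpressionStudy,
    min_rin: float = 7.0,
    required_covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """QC then normalize one cohort; returns the study with its
    ``intensities`` replaced by quantile-normalized log2 expression."""
    qc = filter_samples(study, min_rin=min_rin,
                        required_covariates=required_covariates)
    expr = log2_transform(quantile_normalize(qc.intensities))
    out = ExpressionStudy(
        intensities=expr,
        detection_p=qc.detection_p,
        covariates=qc.covariates,
        phenotype=qc.phenotype,
        cohort_id=qc.cohort_id,
        meta=dict(qc.meta),
        log_scale=True,
    )
    return out, expr
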