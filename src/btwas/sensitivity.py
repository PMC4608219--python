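"""Sensitivity re-analysis under augmented covariate models.

The association and meta-analysis stages are re-run with extra covariates
(e.g. differential cell proportions or an insulin-resistance index) and the
agreement with the base model is summarized as squared Pearson correlations
(in percent) of the meta-level effect size, its standard error, and
-log10 p across shared probes.

The z-based meta-analysis carries no native effect size, so the meta-level
"beta" and "SE" are defined here as the n_i-weighted means of the per-cohort
estimates; both definitions are pluggable via ``meta_effect``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .assoc import run_cohort
from .data import DEFAULT_COVARIATES, ExpressionStudy
from .meta import combine_cohorts


def meta_effect(meta: pd.DataFrame) -> pd.DataFrame:
    """Attach ``beta_meta``/``se_meta``: n_i-weighted means of the
    per-cohort estimates."""
    beta_cols = [c for c in meta.columns if c.startswith("beta_")]
    cohorts = [c[len("beta_"):] for c in beta_cols]
    N = np.stack([meta[f"n_{c}"].to_numpy(dtype=float) for c in cohorts])
    B = np.stack([meta[f"beta_{c}"].to_numpy() for c in cohorts])
    S = np.stack([meta[f"se_{c}"].to_numpy() for c in cohorts])
    w = N / N.sum(axis=0)
    out = meta.copy()
    out["beta_meta"] = (w * B).sum(axis=0)
    out["se_meta"] = (w * S).sum(axis=0)
    return out


@dataclass
class ConcordanceReport:
    """Squared Pearson correlations (percent) between two meta-result sets."""

    model_a: str
    model_b: str
    r2_beta: float
    r2_se: float
    r2_neglog10p: float
    n_probes: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "model_pair": f"{self.model_a}|{self.model_b}",
                    "r2_beta": self.r2_beta,
                    "r2_se": self.r2_se,
                    "r2_neglog10p": self.r2_neglog10p,
                    "n_probes": self.n_probes,
                }
            ]
        )


def _r2_percent(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        raise ValueError("zero-variance vector in concordance computation")
    r, _ = pearsonr(u, v)
    return float(100.0 * r**2)


def concordance(
    a: pd.DataFrame,
    b: pd.DataFrame,
    label_a: str = "base",
    label_b: str = "augmented",
) -> ConcordanceReport:
    """R^2 (percent) for meta beta, SE and -log10 p over shared probes."""
    a = meta_effect(a) if "beta_meta" not in a.columns else a
    b = meta_effect(b) if "beta_meta" not in b.columns else b
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared probes")
    a, b = a.loc[shared], b.loc[shared]
    return ConcordanceReport(
        model_a=label_a,
        model_b=label_b,
        r2_beta=_r2_percent(a["beta_meta"].to_numpy(), b["beta_meta"].to_numpy()),
        r2_se=_r2_percent(a["se_meta"].to_numpy(), b["se_meta"].to_numpy()),
        r2_neglog10p=_r2_percent(
            -np.log10(a["p_meta"].to_numpy()), -np.log10(b["p_meta"].to_numpy())
        ),
        n_probes=len(shared),
    )


def run_sensitivity(
    studies: list[ExpressionStudy],
    probes,
    base_spec: tuple[str, ...] = DEFAULT_COVARIATES,
    added_covariates: tuple[str, ...] = (),
    base_meta: pd.DataFrame | None = None,
    q_threshold: float = 0.01,
    model_id: str = "augmented",
) -> tuple[pd.DataFrame, ConcordanceReport]:
    """Re-run association + meta-analysis with extra covariates and report
    concordance against the base model."""
    for study in studies:
        missing = [
            c for c in added_covariates if c not in study.covariates.columns
        ]
        if missing:
            raise ValueError(
                f"{study.cohort_id}: missing covariate columns {missing}"
            )
    spec = tuple(base_spec) + tuple(
        c for c in added_covariates if c not in base_spec
    )
    if base_meta is None:
        base_results = [
            run_cohort(s, probes, tuple(base_spec), model_id="base")
            for s in studies
        ]
        base_meta = combine_cohorts(base_results, q_threshold=q_threshold)
    aug_results = [
        run_cohort(s, probes, spec, model_id=model_id) for s in studies
    ]
    aug_meta = combine_cohorts(aug_results, q_threshold=q_threshold)
    report = concordance(base_meta, aug_meta, "base", model_id)
    return aug_meta, report
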