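"""Core data containers for two-cohort blood transcriptome association studies.

An :class:`ExpressionStudy` holds one cohort's raw probe intensities,
per-observation detection p-values, sample covariates and the BMI phenotype.
:class:`SimulationConfig` and :class:`GroundTruth` belong to the synthetic
study generator: the config fixes the design (cohort sizes, planted effect
structure, nuisance magnitudes) and the truth object carries the planted
per-probe effects so that downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Covariates of the primary adjustment model: age, sex, red and white blood
#: cell counts, hematocrit, platelet count, RNA integrity, amplification
#: plate, and blood-draw-to-preparation storage time.
DEFAULT_COVARIATES = (
    "age",
    "sex",
    "rbc",
    "wbc",
    "hematocrit",
    "platelets",
    "rin",
    "plate",
    "storage_time",
)

#: Relative differential blood-count fractions used by the sensitivity
#: re-analysis (cell-proportion adjustment).
CELL_PROPORTION_COVARIATES = (
    "lymphocytes",
    "neutrophils",
    "basophils",
    "eosinophils",
    "monocytes",
)


@dataclass
class SimulationConfig:
    """Design of a two-cohort synthetic study.

    Cohort-level defaults follow the two population cohorts the package
    emulates: 988 and 989 analyzed samples with BMI ~ N(28.9, 4.5^2) and
    N(27.3, 4.6^2) kg/m^2 respectively. The probe universe defaults to a
    desk-scale array of 8,000 probes mapping to 6,000 genes.

    Parameters
    ----------
    n_samples_per_cohort
        Analyzed samples per cohort.
    n_probes, n_genes
        Probe universe size and number of annotated genes (n_genes <= n_probes;
        surplus probes are assigned to random genes so some genes carry
        multiple probes).
    frac_positive, frac_negative
        Fractions of probes with planted positive / negative BMI effects.
    effect_size_sd
        Magnitude of the planted standardized effect: every planted probe's
        expression shifts by this many residual SDs per BMI SD.
    reticulocyte_block_size
        Number of probes loading on a shared latent factor positively
        correlated with BMI (r ~ 0.3), mimicking an erythrocyte-to-
        reticulocyte ratio shift rather than per-gene regulation.
    covariate_effect_scale
        SD of per-probe nuisance covariate coefficients (log2 units per
        covariate SD).
    detection_fail_frac
        Fraction of probes whose detection p-values behave like background
        (uniform), giving detection rates ~5% and failing the 50% filter.
    bmi_mean, bmi_sd
        Per-cohort Gaussian BMI parameters (kg/m^2).
    noise_sd
        Residual SD on the log2 expression scale.
    seed
        Seed for the single generator RNG; identical config + seed gives
        bitwise-identical studies.
    """

    n_samples_per_cohort: tuple[int, ...] = (988, 989)
    n_probes: int = 8000
    n_genes: int = 6000
    frac_positive: float = 0.03
    frac_negative: float = 0.05
    effect_size_sd: float = 0.3
    reticulocyte_block_size: int = 50
    covariate_effect_scale: float = 0.1
    detection_fail_frac: float = 0.5
    bmi_mean: tuple[float, ...] = (28.9, 27.3)
    bmi_sd: tuple[float, ...] = (4.5, 4.6)
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_samples_per_cohort) < 1:
            raise ValueError("at least one cohort required")
        if any(n <= 0 for n in self.n_samples_per_cohort):
            raise ValueError("cohort sample sizes must be positive")
        if self.n_probes <= 0 or self.n_genes <= 0:
            raise ValueError("n_probes and n_genes must be positive")
        if self.n_genes > self.n_probes:
            raise ValueError("n_genes must not exceed n_probes")
        for name in ("frac_positive", "frac_negative", "detection_fail_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frac_positive + self.frac_negative > 1.0:
            raise ValueError("frac_positive + frac_negative must not exceed 1")
        if len(self.bmi_mean) != len(self.n_samples_per_cohort) or len(
            self.bmi_sd
        ) != len(self.n_samples_per_cohort):
            raise ValueError("bmi_mean/bmi_sd must have one entry per cohort")
        if self.effect_size_sd < 0 or self.noise_sd < 0:
            raise ValueError("effect_size_sd and noise_sd must be nonnegative")
        if self.reticulocyte_block_size < 0:
            raise ValueError("reticulocyte_block_size must be nonnegative")
        if self.reticulocyte_block_size > self.n_probes:
            raise ValueError("reticulocyte_block_size exceeds n_probes")


@dataclass
class GroundTruth:
    """Planted truth of a synthetic study.

    Attributes
    ----------
    probes : pandas.DataFrame
        Indexed by probe id with columns ``gene``, ``beta_true`` (log2 units
        per kg/m^2; exactly 0 for null probes), ``retic_block`` (bool) and
        ``detect_fail`` (bool).
    genes : pandas.DataFrame
        Indexed by gene symbol with column ``direction`` in
        {"positive", "negative", "inconsistent", "null"}.
    enriched_sets : dict
        Gene-set name -> bool planted-enrichment flag (filled by
        :func:`btwas.syndata.generate_gene_sets`).
    """

    probes: pd.DataFrame
    genes: pd.DataFrame
    enriched_sets: dict[str, bool] = field(default_factory=dict)

    @property
    def annotation(self) -> pd.Series:
        """Probe -> gene symbol map shared by all cohorts."""
        return self.probes["gene"]


@dataclass
class ExpressionStudy:
    """One cohort's expression data with covariates and phenotype.

    ``intensities`` and ``detection_p`` are probe x sample DataFrames on the
    raw (nonnegative) intensity scale; ``covariates`` is a sample x covariate
    DataFrame; ``phenotype`` is the per-sample BMI series.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    covariates: pd.DataFrame
    phenotype: pd.Series
    cohort_id: str
    meta: dict = field(default_factory=dict)
    #: set after preprocessing, when ``intensities`` holds log2 expression
    #: (which may legitimately be negative)
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.intensities.shape != self.detection_p.shape:
            raise ValueError("intensities and detection_p shapes differ")
        if not self.intensities.columns.equals(self.detection_p.columns):
            raise ValueError("sample columns of intensities/detection_p differ")
        if not self.intensities.columns.equals(
            pd.Index(self.covariates.index)
        ):
            raise ValueError("covariate table does not match sample columns")
        if not self.phenotype.index.equals(self.covariates.index):
            raise ValueError("phenotype index does not match covariate table")
        vals = self.intensities.to_numpy()
        if not self.log_scale and np.isfinite(vals).all() and (vals < 0).any():
            raise ValueError("negative raw intensities")
        det = self.detection_p.to_numpy()
        if ((det < 0) | (det > 1)).any():
            raise ValueError("detection p-values outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def probes(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    def subset_samples(self, keep: pd.Index) -> "ExpressionStudy":
        """Restrict the study to the given samples (order preserved)."""
        return ExpressionStudy(
            intensities=self.intensities.loc[:, keep],
            detection_p=self.detection_p.loc[:, keep],
            covariates=self.covariates.loc[keep],
            phenotype=self.phenotype.loc[keep],
            cohort_id=self.cohort_id,
            meta=dict(self.meta),
            log_scale=self.log_scale,
        )
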