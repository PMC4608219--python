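import numpy as np
import pandas as pd
import pytest

from btwas.data import ExpressionStudy, SimulationConfig
from btwas.model import BMITranscriptomeModel
from btwas.syndata import generate_gene_sets, generate_study


def desk_config(**overrides) -> SimulationConfig:
    """Desk-scale two-cohort design used across the suite: 2 x 300 samples,
    2000 probes, 10% planted probes at standardized effect 0.3."""
    base = dict(
        n_samples_per_cohort=(300, 300),
        n_probes=2000,
        n_genes=1500,
        frac_positive=0.05,
        frac_negative=0.05,
        effect_size_sd=0.3,
        reticulocyte_block_size=0,
        covariate_effect_scale=0.1,
        detection_fail_frac=0.3,
        bmi_mean=(28.9, 27.3),
        bmi_sd=(4.5, 4.6),
        noise_sd=1.0,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def planted_sim():
    cfg = desk_config()
    studies, truth = generate_study(cfg)
    return cfg, studies, truth


@pytest.fixture(scope="session")
def fitted(planted_sim):
    _, studies, truth = planted_sim
    model = BMITranscriptomeModel(studies, truth.annotation)
    return model.fit(), truth


@pytest.fixture(scope="session")
def gene_sets(planted_sim):
    _, _, truth = planted_sim
    return generate_gene_sets(
        truth, n_sets=30, set_size_range=(10, 40), n_enriched=5, seed=101
    )


def tiny_study(
    n_probes=5, n_samples=8, seed=0, cohort_id="cohortX", rin=None
) -> ExpressionStudy:
    """Hand-sized raw study for QC/filter unit tests; pass a scalar ``rin``
    to pin every sample's RNA integrity (filter tests only — a constant RIN
    is collinear with the intercept in regression)."""
    rng = np.random.default_rng(seed)
    rin_col = (
        np.full(n_samples, float(rin)) if rin is not None
        else rng.uniform(7.2, 9.8, n_samples)
    )
    probes = pd.Index([f"P{i:03d}" for i in range(n_probes)], name="probe")
    samples = pd.Index([f"S{i:03d}" for i in range(n_samples)], name="sample")
    cov = pd.DataFrame(
        {
            "age": rng.normal(60, 8, n_samples),
            "sex": rng.integers(0, 2, n_samples),
            "rbc": rng.normal(4.5, 0.4, n_samples),
            "wbc": rng.normal(6.0, 1.5, n_samples),
            "hematocrit": rng.normal(0.41, 0.03, n_samples),
            "platelets": rng.normal(240, 60, n_samples),
            "rin": rin_col,
            "plate": ["plate00"] * n_samples,
            "storage_time": rng.uniform(1, 30, n_samples),
        },
        index=samples,
    )
    return ExpressionStudy(
        intensities=pd.DataFrame(
            rng.uniform(50, 5000, (n_probes, n_samples)),
            index=probes, columns=samples,
        ),
        detection_p=pd.DataFrame(
            rng.beta(0.2, 5.0, (n_probes, n_samples)),
            index=probes, columns=samples,
        ),
        covariates=cov,
        phenotype=pd.Series(
            rng.normal(28, 4.5, n_samples), index=samples, name="bmi"
        ),
        cohort_id=cohort_id,
    )
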