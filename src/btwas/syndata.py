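"""Synthetic two-cohort expression studies with known planted truth.

The generator emulates the statistical structure the association pipeline
assumes: two independently profiled cohorts sharing a probe universe, BMI
drawn from cohort-specific normal distributions, expression built on the
log2 scale as

    baseline + beta_true * BMI + nuisance covariate effects
             + reticulocyte-factor loading + Gaussian noise,

then mapped onto a positive raw-intensity scale by ``2**x`` so the
preprocessing stage's log2 transform inverts it. A configurable fraction of
probes carries background-level detection p-values and is meant to be removed
by the detection-rate filter. Planted effects are assigned gene-wise, so all
probes of a planted gene share the effect sign.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .data import (
    CELL_PROPORTION_COVARIATES,
    ExpressionStudy,
    GroundTruth,
    SimulationConfig,
)
from .enrich import GeneSetCollection

#: Correlation between the latent reticulocyte factor and standardized BMI.
RETIC_BMI_CORR = 0.3

#: Samples per amplification plate (96-well plates, round-robin assignment).
PLATE_SIZE = 96

# Cohort covariate moments (age years, fraction female, RBC 10^12/L,
# WBC 10^9/L, platelets 10^9/L, hematocrit L/L); first entry mirrors the
# older cohort, second the younger one. Extra cohorts reuse the first row.
_COHORT_MOMENTS = [
    dict(age=(70.4, 5.4), female=0.496, rbc=(4.50, 0.40), wbc=(6.00, 1.81),
         platelets=(244.7, 65.1), hematocrit=(0.41, 0.03)),
    dict(age=(50.1, 13.7), female=0.560, rbc=(4.63, 0.39), wbc=(5.72, 1.48),
         platelets=(225.7, 50.3), hematocrit=(0.42, 0.03)),
]

_CELL_PROP_MEANS = {
    "neutrophils": 0.58,
    "lymphocytes": 0.30,
    "monocytes": 0.08,
    "eosinophils": 0.025,
    "basophils": 0.005,
}


def _assign_genes(rng: np.random.Generator, n_probes: int, n_genes: int) -> np.ndarray:
    """Map probes to genes; every gene gets >= 1 probe, surplus at random."""
    gene_idx = np.arange(n_probes)
    gene_idx[:n_genes] = np.arange(n_genes)
    if n_probes > n_genes:
        gene_idx[n_genes:] = rng.integers(0, n_genes, size=n_probes - n_genes)
    else:
        # degenerate 1:1 map: fold the last probe onto gene 0 so at least
        # one gene carries two probes
        gene_idx[-1] = 0
    return gene_idx


def _plant_gene_blocks(
    rng: np.random.Generator,
    candidate_genes: np.ndarray,
    probes_of_gene: dict[int, np.ndarray],
    target_probes: int,
) -> tuple[list[int], np.ndarray]:
    """Pick whole genes (shuffled) until their probe count reaches the target."""
    order = rng.permutation(candidate_genes)
    chosen: list[int] = []
    probe_ids: list[np.ndarray] = []
    total = 0
    for g in order:
        if total >= target_probes:
            break
        chosen.append(int(g))
        probe_ids.append(probes_of_gene[int(g)])
        total += len(probes_of_gene[int(g)])
    probes = np.concatenate(probe_ids) if probe_ids else np.empty(0, dtype=int)
    return chosen, probes


def generate_study(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Simulate one :class:`ExpressionStudy` per cohort plus its ground truth.

    Fully deterministic given ``config.seed``. Planted probes shift by
    ``config.effect_size_sd`` residual SDs per BMI SD (sign per gene); the
    reticulocyte block loads on one latent factor with BMI correlation 0.3.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_probes, n_genes = config.n_probes, config.n_genes
    n_cohorts = len(config.n_samples_per_cohort)

    probe_ids = pd.Index([f"P{i:05d}" for i in range(n_probes)], name="probe")
    gene_names = np.array([f"G{i:04d}" for i in range(n_genes)])
    gene_idx = _assign_genes(rng, n_probes, n_genes)

    # detection-failing probes behave like background on every array
    n_fail = int(round(config.detection_fail_frac * n_probes))
    fail_mask = np.zeros(n_probes, dtype=bool)
    fail_mask[rng.choice(n_probes, size=n_fail, replace=False)] = True

    probes_of_gene = {
        int(g): np.flatnonzero(gene_idx == g) for g in np.unique(gene_idx)
    }
    # genes eligible for planting: all probes detectable, so a planted gene's
    # probes uniformly carry the planted sign
    eligible = np.array(
        [g for g, p in probes_of_gene.items() if not fail_mask[p].any()]
    )

    beta_std = np.zeros(n_probes)
    n_pos = int(round(config.frac_positive * n_probes))
    n_neg = int(round(config.frac_negative * n_probes))
    pos_genes, pos_probes = _plant_gene_blocks(
        rng, eligible, probes_of_gene, n_pos
    )
    remaining = np.array([g for g in eligible if g not in set(pos_genes)])
    neg_genes, neg_probes = _plant_gene_blocks(
        rng, remaining, probes_of_gene, n_neg
    )
    beta_std[pos_probes] = config.effect_size_sd
    beta_std[neg_probes] = -config.effect_size_sd

    # reticulocyte block: whole unplanted detectable genes loading on the
    # shared latent factor
    taken = set(pos_genes) | set(neg_genes)
    block_candidates = np.array([g for g in eligible if g not in taken])
    _, block_probes = _plant_gene_blocks(
        rng, block_candidates, probes_of_gene, config.reticulocyte_block_size
    )
    retic_mask = np.zeros(n_probes, dtype=bool)
    retic_mask[block_probes] = True
    loadings = np.zeros(n_probes)
    loadings[block_probes] = (
        rng.uniform(0.5, 1.0, size=len(block_probes)) * config.noise_sd
    )

    # per-kg/m^2 slopes; the standardized effect is referred to the mean
    # cohort BMI SD so both cohorts see comparable signal strength
    bmi_sd_ref = float(np.mean(config.bmi_sd))
    beta_true = beta_std * config.noise_sd / bmi_sd_ref
    # marginal slope induced through the latent factor for block probes
    beta_true = beta_true + loadings * RETIC_BMI_CORR / bmi_sd_ref

    baseline = np.where(
        fail_mask, rng.uniform(4.0, 6.0, n_probes), rng.uniform(7.0, 12.0, n_probes)
    )
    # nuisance coefficients on standardized covariates, shared across cohorts
    nuisance_cols = [
        "age", "sex", "rbc", "wbc", "hematocrit", "platelets", "rin",
        "storage_time",
    ]
    gamma = rng.normal(
        0.0, config.covariate_effect_scale, size=(n_probes, len(nuisance_cols))
    )

    studies: list[ExpressionStudy] = []
    for c in range(n_cohorts):
        n = config.n_samples_per_cohort[c]
        mom = _COHORT_MOMENTS[min(c, len(_COHORT_MOMENTS) - 1)]
        cohort = f"cohort{c + 1}"
        samples = pd.Index([f"{cohort}_S{i:04d}" for i in range(n)], name="sample")

        bmi = rng.normal(config.bmi_mean[c], config.bmi_sd[c], n)
        cov = pd.DataFrame(index=samples)
        cov["age"] = rng.normal(*mom["age"], n)
        cov["sex"] = (rng.random(n) < mom["female"]).astype(int)
        cov["rbc"] = rng.normal(*mom["rbc"], n)
        cov["wbc"] = rng.normal(*mom["wbc"], n)
        cov["hematocrit"] = rng.normal(*mom["hematocrit"], n)
        cov["platelets"] = rng.normal(*mom["platelets"], n)
        cov["rin"] = rng.uniform(7.0, 10.0, n)
        cov["plate"] = [f"plate{i // PLATE_SIZE:02d}" for i in range(n)]
        cov["storage_time"] = rng.uniform(1.0, 30.0, n)
        props = np.stack(
            [
                np.clip(
                    rng.normal(m, 0.15 * m, n), 1e-3, None
                )
                for m in (_CELL_PROP_MEANS[k] for k in CELL_PROPORTION_COVARIATES)
            ],
            axis=1,
        )
        props /= props.sum(axis=1, keepdims=True)
        for j, k in enumerate(CELL_PROPORTION_COVARIATES):
            cov[k] = props[:, j]
        # insulin resistance index, mildly BMI-coupled and right-skewed
        z_bmi = (bmi - config.bmi_mean[c]) / config.bmi_sd[c]
        cov["homa_ir"] = np.exp(0.6 + 0.25 * z_bmi + rng.normal(0.0, 0.6, n))

        z_cov = np.stack(
            [
                (cov[k] - cov[k].mean()) / (cov[k].std(ddof=0) or 1.0)
                for k in nuisance_cols
            ],
            axis=0,
        )  # covariate x sample
        retic_factor = RETIC_BMI_CORR * z_bmi + math.sqrt(
            1.0 - RETIC_BMI_CORR**2
        ) * rng.standard_normal(n)

        x = (
            baseline[:, None]
            + beta_true[:, None] * bmi[None, :]
            + gamma @ z_cov
            + loadings[:, None] * retic_factor[None, :]
        )
        # plate batch offsets, cohort-specific
        plates = cov["plate"].to_numpy()
        for p in np.unique(plates):
            offset = rng.normal(
                0.0, config.covariate_effect_scale / 2.0, n_probes
            )
            x[:, plates == p] += offset[:, None]
        if config.noise_sd > 0:
            x += rng.normal(0.0, config.noise_sd, size=x.shape)

        intensities = pd.DataFrame(
            np.exp2(x), index=probe_ids, columns=samples
        )
        det = np.where(
            fail_mask[:, None],
            rng.uniform(0.0, 1.0, size=x.shape),
            rng.beta(0.2, 5.0, size=x.shape),
        )
        detection = pd.DataFrame(det, index=probe_ids, columns=samples)
        studies.append(
            ExpressionStudy(
                intensities=intensities,
                detection_p=detection,
                covariates=cov,
                phenotype=pd.Series(bmi, index=samples, name="bmi"),
                cohort_id=cohort,
            )
        )

    probes_df = pd.DataFrame(
        {
            "gene": gene_names[gene_idx],
            "beta_true": beta_true,
            "retic_block": retic_mask,
            "detect_fail": fail_mask,
        },
        index=probe_ids,
    )
    genes_df = _gene_directions(probes_df)
    return studies, GroundTruth(probes=probes_df, genes=genes_df)


def _gene_directions(probes_df: pd.DataFrame) -> pd.DataFrame:
    def classify(betas: pd.Series) -> str:
        nz = betas[betas != 0.0]
        if nz.empty:
            return "null"
        if (nz > 0).all():
            return "positive"
        if (nz < 0).all():
            return "negative"
        return "inconsistent"

    direction = probes_df.groupby("gene")["beta_true"].apply(classify)
    out = direction.to_frame("direction")
    out["n_probes"] = probes_df.groupby("gene").size()
    out.index.name = "gene"
    return out


def generate_gene_sets(
    truth: GroundTruth,
    n_sets: int,
    set_size_range: tuple[int, int],
    n_enriched: int,
    seed: int,
    assoc_frac: float = 0.8,
) -> GeneSetCollection:
    """Build a named gene-set collection with planted enrichment.

    Enriched sets draw ``assoc_frac`` of their members from truly
    BMI-associated genes; null sets draw uniformly from all genes. The
    planted flags are recorded in ``truth.enriched_sets``.
    """
    if n_enriched > n_sets:
        raise ValueError("n_enriched must not exceed n_sets")
    lo, hi = set_size_range
    if lo > hi or lo < 1:
        raise ValueError("invalid set_size_range")
    all_genes = truth.genes.index.to_numpy()
    if hi > len(all_genes):
        raise ValueError("set sizes exceed number of genes")
    if not 0.0 <= assoc_frac <= 1.0:
        raise ValueError("assoc_frac must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    assoc = truth.genes.index[
        truth.genes["direction"].isin(["positive", "negative"])
    ].to_numpy()
    other = np.setdiff1d(all_genes, assoc)

    sets: dict[str, frozenset[str]] = {}
    truth.enriched_sets.clear()
    for i in range(n_sets):
        name = f"SET_{i:03d}"
        size = int(rng.integers(lo, hi + 1))
        enriched = i < n_enriched
        if enriched:
            k = min(max(int(np.ceil(assoc_frac * size)), 1), len(assoc), size)
            members = list(rng.choice(assoc, size=k, replace=False))
            pool = np.setdiff1d(other, members)
            if size - k > 0:
                members += list(rng.choice(pool, size=size - k, replace=False))
        else:
            members = list(rng.choice(all_genes, size=size, replace=False))
        sets[name] = frozenset(members)
        truth.enriched_sets[name] = enriched
    return GeneSetCollection(sets=sets, universe=frozenset(all_genes))
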