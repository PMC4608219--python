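"""Plain-text I/O: probe x sample TSV matrices, covariate tables, GMT sets.

Expression and detection matrices are written probes-as-rows with the probe
id in the first column; covariate tables are one sample per row with the BMI
phenotype included as a ``bmi`` column. All writers produce stable column
order so repeated runs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .data import ExpressionStudy, GroundTruth

FLOAT_FMT = "%.10g"


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe", float_format=FLOAT_FMT)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe"
    return df


def write_study(study: ExpressionStudy, outdir) -> dict[str, Path]:
    """Write one cohort as expression/detection/covariate TSVs; returns the
    file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cid = study.cohort_id
    paths = {
        "expression": outdir / f"{cid}_expression.tsv",
        "detection": outdir / f"{cid}_detection.tsv",
        "covariates": outdir / f"{cid}_covariates.tsv",
    }
    write_matrix(study.intensities, paths["expression"])
    write_matrix(study.detection_p, paths["detection"])
    cov = study.covariates.copy()
    cov.insert(0, "bmi", study.phenotype)
    cov.to_csv(paths["covariates"], sep="\t", index_label="sample",
               float_format=FLOAT_FMT)
    return paths


def read_study(
    expression_path, detection_path, covariates_path, cohort_id: str,
    log_scale: bool = False,
) -> ExpressionStudy:
    intensities = read_matrix(expression_path)
    detection = read_matrix(detection_path)
    cov = pd.read_csv(covariates_path, sep="\t", index_col=0)
    cov.index.name = "sample"
    if "bmi" not in cov.columns:
        raise ValueError(f"{covariates_path}: covariate table lacks 'bmi'")
    bmi = cov["bmi"]
    return ExpressionStudy(
        intensities=intensities,
        detection_p=detection,
        covariates=cov.drop(columns=["bmi"]),
        phenotype=bmi,
        cohort_id=cohort_id,
        log_scale=log_scale,
    )


def write_truth(truth: GroundTruth, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth_probes": outdir / "truth_probes.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
    }
    truth.probes.to_csv(paths["truth_probes"], sep="\t",
                        float_format=FLOAT_FMT)
    truth.genes.to_csv(paths["truth_genes"], sep="\t")
    if truth.enriched_sets:
        p = outdir / "truth_gene_sets.tsv"
        pd.Series(truth.enriched_sets, name="planted_enriched").to_csv(
            p, sep="\t", index_label="set"
        )
        paths["truth_gene_sets"] = p
    return paths


def read_annotation(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["gene"]


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
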