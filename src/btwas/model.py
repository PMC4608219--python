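"""Model/Results interface over the full association pipeline.

:class:`BMITranscriptomeModel` bundles the cohorts, annotation and analysis
settings; :meth:`~BMITranscriptomeModel.fit` runs sample QC, quantile
normalization, the detection filter, per-cohort regression and the
sample-size-weighted z-score meta-analysis, returning a
:class:`BMITranscriptomeResults` that carries probe- and gene-level tables
plus enrichment, graph and sensitivity methods.

Typical use::

    studies, truth = syndata.generate_study(SimulationConfig(seed=1))
    model = BMITranscriptomeModel(studies, truth.annotation)
    results = model.fit()
    print(results.summary())
    ora = results.enrich(collection)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import enrich as _enrich
from . import netgraph as _netgraph
from . import sensitivity as _sensitivity
from .assoc import run_cohort
from .data import DEFAULT_COVARIATES, ExpressionStudy
from .meta import collapse_genes, combine_cohorts, direction_summary
from .preprocess import detection_filter, preprocess_study


@dataclass
class BMITranscriptomeModel:
    """Two-cohort transcriptome-wide association model of BMI.

    Parameters
    ----------
    studies
        One raw :class:`ExpressionStudy` per cohort.
    annotation
        Probe -> gene symbol map shared across cohorts.
    covariates
        Adjustment model (default: age, sex, RBC, WBC, hematocrit,
        platelets, RIN, plate, storage time).
    min_rin, detection_threshold, detection_alpha, q_threshold
        QC and significance settings: samples need RIN >= 7, probes need a
        detection rate above 50% in every cohort, probe significance is
        BH q < 0.01.
    """

    studies: list[ExpressionStudy]
    annotation: pd.Series
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    min_rin: float = 7.0
    detection_threshold: float = 0.5
    detection_alpha: float = 0.05
    q_threshold: float = 0.01

    def fit(self) -> "BMITranscriptomeResults":
        prepped = []
        ledger = {}
        for study in self.studies:
            clean, _ = preprocess_study(
                study, min_rin=self.min_rin,
                required_covariates=self.covariates,
            )
            prepped.append(clean)
            ledger[clean.cohort_id] = {
                "n_before_qc": clean.meta.get("n_before_qc", study.n_samples),
                "n_analyzed": clean.n_samples,
                **clean.meta.get("exclusions", {}),
            }
        probes, det_summary = detection_filter(
            prepped, threshold=self.detection_threshold,
            alpha=self.detection_alpha,
        )
        cohort_results = [
            run_cohort(s, probes, self.covariates) for s in prepped
        ]
        meta = combine_cohorts(cohort_results, q_threshold=self.q_threshold)
        genes = collapse_genes(meta, self.annotation, self.q_threshold)
        return BMITranscriptomeResults(
            model=self,
            studies=prepped,
            probe_results=meta,
            gene_results=genes,
            cohort_results=cohort_results,
            detection_summary=det_summary,
            sample_ledger=pd.DataFrame(ledger).T,
        )


@dataclass
class BMITranscriptomeResults:
    """Fitted pipeline results.

    ``probe_results`` has one row per filtered probe (per-cohort beta/se/p,
    z_meta, p_meta, q, direction); ``gene_results`` one row per significant
    gene (min-p representative probe, direction class).
    """

    model: BMITranscriptomeModel
    studies: list[ExpressionStudy]
    probe_results: pd.DataFrame
    gene_results: pd.DataFrame
    cohort_results: list[pd.DataFrame] = field(repr=False, default_factory=list)
    detection_summary: object = None
    sample_ledger: pd.DataFrame | None = None

    @property
    def n_individuals(self) -> int:
        """Total analyzed samples across cohorts (the meta-analysis n)."""
        return int(sum(s.n_samples for s in self.studies))

    @property
    def n_probes_tested(self) -> int:
        return len(self.probe_results)

    @property
    def n_significant_probes(self) -> int:
        return int(self.probe_results["significant"].sum())

    def direction_summary(self) -> pd.DataFrame:
        """Gene counts and percentages per direction class."""
        return direction_summary(self.gene_results)

    def gene_directions(self) -> pd.Series:
        return self.gene_results["direction_class"]

    def genes_by_stratum(self) -> dict[str, list[str]]:
        """Significant gene lists for ORA: all, positive, negative."""
        g = self.gene_results
        return {
            "all": list(g.index),
            "positive": list(g.index[g["direction_class"] == "positive"]),
            "negative": list(g.index[g["direction_class"] == "negative"]),
        }

    def _restricted_collection(
        self, collection: _enrich.GeneSetCollection
    ) -> _enrich.GeneSetCollection:
        array_genes = set(
            self.model.annotation.reindex(self.probe_results.index)
            .dropna()
            .unique()
        )
        return collection.restrict(array_genes)

    def enrich(
        self,
        collection: _enrich.GeneSetCollection,
        alpha: float = 0.05,
        permutations: int = 0,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Direction-stratified ORA against the collection restricted to
        array-represented genes; optional permutation FDR on the 'all'
        stratum (``permutations`` = number of random input lists B)."""
        restricted = self._restricted_collection(collection)
        ora = _enrich.run_ora(self.genes_by_stratum(), restricted, alpha=alpha)
        if permutations:
            n_input = len(
                frozenset(self.genes_by_stratum()["all"])
                & restricted.universe
            )
            ora = _enrich.permutation_fdr(
                ora, restricted, n_input=n_input, B=permutations, seed=seed
            )
        return ora

    def enrichment_report(
        self,
        collection: _enrich.GeneSetCollection,
        ora: pd.DataFrame | None = None,
        **kwargs,
    ) -> pd.DataFrame:
        restricted = self._restricted_collection(collection)
        if ora is None:
            ora = self.enrich(collection, **kwargs)
        return _enrich.table2_report(ora, restricted, self.gene_directions())

    def overlap_graph(
        self,
        collection: _enrich.GeneSetCollection,
        percentile: float = 90.0,
        signatures: dict[str, str] | None = None,
    ):
        """Jaccard overlap graph of the collection's sets over their
        significantly associated transcripts."""
        restricted = self._restricted_collection(collection)
        memberships = _netgraph.memberships_from_results(
            restricted,
            self.probe_results,
            self.model.annotation,
            q_threshold=self.model.q_threshold,
        )
        return _netgraph.build_graph(
            memberships, percentile=percentile, signatures=signatures
        )

    def sensitivity(
        self, added_covariates: tuple[str, ...], model_id: str = "augmented"
    ) -> tuple[pd.DataFrame, _sensitivity.ConcordanceReport]:
        """Re-fit with extra covariates; returns the augmented meta results
        and the concordance report against this fit."""
        return _sensitivity.run_sensitivity(
            self.studies,
            self.probe_results.index,
            base_spec=self.model.covariates,
            added_covariates=added_covariates,
            base_meta=self.probe_results,
            q_threshold=self.model.q_threshold,
            model_id=model_id,
        )

    def summary(self) -> str:
        lines = [
            "BMI transcriptome-wide association (two-cohort meta-analysis)",
            "=" * 62,
            f"Individuals analyzed: {self.n_individuals} "
            f"({' + '.join(str(s.n_samples) for s in self.studies)})",
            f"Probes passing detection filter: {self.n_probes_tested}",
            f"Significant probes (q < {self.model.q_threshold}): "
            f"{self.n_significant_probes}",
            f"Significant genes: {len(self.gene_results)}",
            "",
            "Direction of association (gene level):",
        ]
        if len(self.gene_results):
            for cls, row in self.direction_summary().iterrows():
                lines.append(
                    f"  {cls:>12s}: {int(row['count']):5d} ({row['percent']}%)"
                )
        else:
            lines.append("  (no significant genes)")
        return "\n".join(lines)
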