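"""Sample-size-weighted z-score meta-analysis, FDR, and gene collapsing.

Per-cohort two-sided p-values are converted to signed z-scores
(z = sign(beta) * Phi^-1(1 - p/2)) and combined with Stouffer weights
w_i = sqrt(n_i). Benjamini-Hochberg step-up q-values control the FDR across
the filtered probe set; probes significant at q < 0.01 are collapsed to
genes by minimum p, with a gene-level direction class of positive, negative
or inconsistent according to the signs of its significant probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats


def z_from_p_beta(p: np.ndarray | float, beta: np.ndarray | float) -> np.ndarray | float:
    """Signed z: sign(beta) * Phi^-1(1 - p/2) for a two-sided p."""
    p = np.asarray(p, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    z = np.sign(beta) * stats.norm.isf(p / 2.0)
    return z if z.ndim else float(z)


def z_from_assoc(r) -> float:
    """Signed z-score of one per-cohort association record."""
    return float(z_from_p_beta(r.p, r.beta))


def stouffer(z: list[float] | np.ndarray, n: list[int] | np.ndarray) -> tuple[float, float]:
    """Combine signed z-scores with weights sqrt(n_i).

    Returns ``(z_meta, p_meta)`` with
    z_meta = sum(sqrt(n_i) z_i) / sqrt(sum n_i) and a two-sided p.
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if z.shape != n.shape or z.size == 0:
        raise ValueError("z and n must be nonempty and of equal length")
    if np.any(n <= 0):
        raise ValueError("sample sizes must be positive")
    w = np.sqrt(n)
    z_meta = float(np.sum(w * z) / np.sqrt(np.sum(n)))
    p_meta = float(2.0 * stats.norm.sf(abs(z_meta)))
    return z_meta, max(p_meta, 0.0)


def bh_adjust(p: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} min(1, m p_(j) / j) on the sorted p-values; tied
    p-values share a q.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class MetaProbeResult:
    """Combined evidence for one probe."""

    probe: str
    z_by_cohort: dict[str, float]
    n_by_cohort: dict[str, int]
    z_meta: float
    p_meta: float
    q: float
    significant: bool
    direction: int  # sign(z_meta)


def combine_cohorts(
    cohort_results: list[pd.DataFrame],
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Meta-analyze per-cohort association tables (as from ``run_cohort``).

    Returns a probe-indexed frame with per-cohort beta/se/p columns, the
    combined ``z_meta``, ``p_meta``, BH ``q``, ``significant`` flag and
    ``direction``. Probes must be present in every cohort.
    """
    if not cohort_results:
        raise ValueError("no cohort results supplied")
    shared = cohort_results[0].index
    for df in cohort_results[1:]:
        shared = shared.intersection(df.index)
    if len(shared) == 0:
        raise ValueError("cohorts share no probes")

    out = pd.DataFrame(index=shared)
    zs, ns = [], []
    for df in cohort_results:
        df = df.loc[shared]
        cid = df["cohort"].iloc[0]
        out[f"beta_{cid}"] = df["beta"]
        out[f"se_{cid}"] = df["se"]
        out[f"p_{cid}"] = df["p"]
        out[f"n_{cid}"] = df["n"]
        zs.append(z_from_p_beta(df["p"].to_numpy(), df["beta"].to_numpy()))
        ns.append(df["n"].to_numpy(dtype=float))
    Z = np.stack(zs)  # cohorts x probes
    N = np.stack(ns)
    W = np.sqrt(N)
    z_meta = (W * Z).sum(axis=0) / np.sqrt(N.sum(axis=0))
    p_meta = np.maximum(2.0 * stats.norm.sf(np.abs(z_meta)), 1e-300)
    out["z_meta"] = z_meta
    out["p_meta"] = p_meta
    out["q"] = bh_adjust(p_meta)
    out["significant"] = out["q"] < q_threshold
    out["direction"] = np.sign(z_meta).astype(int)
    out["n_total"] = N.sum(axis=0).astype(int)
    out.index.name = "probe"
    return out


def collapse_genes(
    meta: pd.DataFrame,
    annotation: pd.Series,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """One record per gene with >= 1 significant probe.

    The representative probe is the gene's minimum-``p_meta`` probe (ties
    broken by lexicographically smallest probe id); the direction class is
    positive/negative if all the gene's significant probes share that sign,
    inconsistent otherwise. Unannotated probes are dropped.
    """
    ann = annotation.reindex(meta.index)
    annotated = meta.loc[ann.notna()].copy()
    annotated["gene"] = ann.dropna()
    sig = annotated[annotated["q"] < q_threshold]
    records = []
    for gene, grp in sig.groupby("gene", sort=True):
        # min-p representative; ties broken by smallest probe id
        grp = grp.sort_index(kind="mergesort").sort_values(
            "p_meta", kind="mergesort"
        )
        rep = grp.iloc[0]
        signs = set(np.sign(grp["z_meta"]).astype(int))
        signs.discard(0)
        if signs == {1}:
            cls = "positive"
        elif signs == {-1}:
            cls = "negative"
        else:
            cls = "inconsistent"
        records.append(
            {
                "gene": gene,
                "probe": grp.index[0],
                "p_meta": float(rep["p_meta"]),
                "q": float(rep["q"]),
                "z_meta": float(rep["z_meta"]),
                "direction_class": cls,
                "n_probes_significant": len(grp),
                "n_probes_total": int((annotated["gene"] == gene).sum()),
            }
        )
    cols = [
        "gene", "probe", "p_meta", "q", "z_meta", "direction_class",
        "n_probes_significant", "n_probes_total",
    ]
    return pd.DataFrame(records, columns=cols).set_index("gene")


def _round_half_up(x: float, decimals: int = 1) -> float:
    return float(
        Decimal(repr(x)).quantize(
            Decimal("0." + "0" * decimals), rounding=ROUND_HALF_UP
        )
    )


def direction_summary(genes: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Counts and one-decimal percentages per direction class.

    Accepts a collapsed gene table (using ``direction_class``) or a Series
    of class labels. Percentages are rounded half-up to one decimal.
    """
    if isinstance(genes, pd.DataFrame):
        labels = genes["direction_class"]
    else:
        labels = genes
    if len(labels) == 0:
        raise ValueError("no genes to summarize")
    counts = labels.value_counts()
    total = int(counts.sum())
    rows = []
    for cls in ("positive", "negative", "inconsistent"):
        c = int(counts.get(cls, 0))
        rows.append(
            {
                "class": cls,
                "count": c,
                "percent": _round_half_up(100.0 * c / total, 1),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def summary_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Direction summary straight from class counts (no gene table)."""
    labels = pd.Series(
        np.repeat(list(counts.keys()), list(counts.values()))
    )
    return direction_summary(labels)
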