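"""Direction-stratified gene-set over-representation analysis.

Over-representation of an input gene list in each gene set is scored by a
right-tailed Fisher's exact (hypergeometric) test against the reference
universe — the genes represented on the array and present in the collection.
BH q-values are computed within each direction stratum (all / positively /
negatively associated genes); the enrichment ratio is the overlap divided by
the set size. A permutation analysis resamples uniform random input lists of
matched size to attach an empirical false-positive rate to each set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, spearmanr

from .meta import bh_adjust

STRATA = ("all", "positive", "negative")


@dataclass
class GeneSetCollection:
    """Named gene sets over a reference universe of gene symbols."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def restrict(self, array_genes: set[str] | frozenset[str]) -> "GeneSetCollection":
        """Restrict the universe (and every set) to array-represented genes;
        sets left empty are dropped."""
        new_universe = frozenset(self.universe & set(array_genes))
        new_sets = {}
        for name, members in self.sets.items():
            kept = frozenset(members & new_universe)
            if kept:
                new_sets[name] = kept
        if not new_sets:
            raise ValueError("no gene sets remain after universe restriction")
        return GeneSetCollection(sets=new_sets, universe=new_universe)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, frozenset[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                name, _desc, *genes = fields
                genes = [g for g in genes if g]
                if not genes:
                    raise ValueError(f"gene set {name!r} has no members")
                sets[name] = frozenset(genes)
        universe = frozenset().union(*sets.values())
        return cls(sets=sets, universe=universe)

    def to_gmt(self, path, descriptions: dict[str, str] | None = None) -> None:
        descriptions = descriptions or {}
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                desc = descriptions.get(name, "na")
                genes = "\t".join(sorted(self.sets[name]))
                fh.write(f"{name}\t{desc}\t{genes}\n")


def fisher_right_tail(x: int, K: int, n: int, N: int) -> float:
    """Right-tail Fisher's exact p: P(overlap >= x) under the
    hypergeometric(N, K, n) null.

    ``x`` observed overlap, ``K`` set size, ``n`` input-list size,
    ``N`` universe size.
    """
    if not (0 <= x <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"invalid Fisher bounds: x={x}, K={K}, n={n}, N={N}"
        )
    if x == 0:
        return 1.0
    return float(hypergeom.sf(x - 1, N, K, n))


@dataclass
class EnrichmentRecord:
    """Over-representation of one gene set in one direction stratum."""

    set_name: str
    stratum: str
    N: int
    K: int
    n: int
    x: int
    p: float
    q: float = float("nan")
    ratio: float = 0.0
    permutation_fdr: float = float("nan")
    not_applicable: bool = False
    degenerate: bool = False
    overlap_genes: frozenset[str] = field(default_factory=frozenset)


def run_ora(
    genes_by_stratum: dict[str, list[str] | set[str]],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """ORA of each stratum's gene list against every set in the collection.

    Input genes are intersected with the universe first. BH adjustment runs
    within each stratum across sets; an empty stratum yields not-applicable
    records (x = 0, p/q = NaN), and an input list equal to the whole universe
    yields degenerate records (overlap forced, p = 1).
    """
    N = len(collection.universe)
    if N == 0:
        raise ValueError("empty reference universe")
    rows: list[EnrichmentRecord] = []
    for stratum, genes in genes_by_stratum.items():
        inp = frozenset(genes) & collection.universe
        n = len(inp)
        recs = []
        for name in sorted(collection.sets):
            members = collection.sets[name]
            K = len(members)
            overlap = members & inp
            x = len(overlap)
            if n == 0:
                rec = EnrichmentRecord(
                    set_name=name, stratum=stratum, N=N, K=K, n=0, x=0,
                    p=float("nan"), ratio=0.0, not_applicable=True,
                )
            else:
                p = fisher_right_tail(x, K, n, N)
                rec = EnrichmentRecord(
                    set_name=name, stratum=stratum, N=N, K=K, n=n, x=x,
                    p=p, ratio=x / K, degenerate=(n == N),
                    overlap_genes=frozenset(overlap),
                )
            recs.append(rec)
        valid = [r for r in recs if not r.not_applicable]
        if valid:
            qs = bh_adjust([r.p for r in valid])
            for r, q in zip(valid, qs):
                r.q = float(q)
        rows.extend(recs)
    df = pd.DataFrame(
        [
            {
                "set": r.set_name, "stratum": r.stratum, "N": r.N, "K": r.K,
                "n": r.n, "x": r.x, "p": r.p, "q": r.q, "ratio": r.ratio,
                "significant": (not np.isnan(r.q)) and r.q < alpha,
                "not_applicable": r.not_applicable,
                "degenerate": r.degenerate,
            }
            for r in rows
        ]
    )
    return df.set_index(["set", "stratum"])


def permutation_fdr(
    observed: pd.DataFrame,
    collection: GeneSetCollection,
    n_input: int,
    B: int = 5000,
    seed: int = 0,
    stratum: str = "all",
) -> pd.DataFrame:
    """Empirical per-set false-positive rate from random input lists.

    For each of ``B`` replicates a uniform random gene list of size
    ``n_input`` is drawn from the universe and every set's Fisher p is
    recomputed; the per-set empirical FDR is
    ``(1 + #{b : p_b <= p_observed}) / (B + 1)``. The result is the
    ``observed`` frame with a filled ``permutation_fdr`` column for the
    chosen stratum.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    N = len(collection.universe)
    if n_input > N:
        raise ValueError("n_input exceeds universe size")
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(collection.universe))
    names = sorted(collection.sets)
    membership = np.stack(
        [np.isin(genes, sorted(collection.sets[s])) for s in names]
    )  # sets x genes
    K = membership.sum(axis=1)

    counts = np.zeros((B, len(names)), dtype=np.int64)
    for b in range(B):
        idx = rng.choice(N, size=n_input, replace=False)
        counts[b] = membership[:, idx].sum(axis=1)
    # p_b for all sets and replicates at once
    p_perm = hypergeom.sf(counts - 1, N, K[None, :], n_input)
    p_perm[counts == 0] = 1.0

    obs = observed.copy()
    if "permutation_fdr" not in obs.columns:
        obs["permutation_fdr"] = np.nan
    sub = obs.xs(stratum, level="stratum", drop_level=False)
    p_obs = sub["p"].to_numpy()
    name_pos = {s: i for i, s in enumerate(names)}
    fdr = np.full(len(sub), np.nan)
    for i, (set_name, _) in enumerate(sub.index):
        j = name_pos[set_name]
        if np.isnan(p_obs[i]):
            continue
        hits = int((p_perm[:, j] <= p_obs[i] + 1e-15).sum())
        fdr[i] = (1 + hits) / (B + 1)
    obs.loc[sub.index, "permutation_fdr"] = fdr
    return obs


def permutation_rank_agreement(
    observed: pd.DataFrame, stratum: str = "all"
) -> float:
    """Spearman correlation between Fisher p and permutation FDR across sets."""
    sub = observed.xs(stratum, level="stratum")
    ok = sub[["p", "permutation_fdr"]].dropna()
    rho, _ = spearmanr(ok["p"], ok["permutation_fdr"])
    return float(rho)


def direction_composition(
    set_name: str,
    collection: GeneSetCollection,
    gene_directions: pd.Series,
) -> tuple[float, float, float]:
    """Fractions (positive, negative, not significant) of a set's
    array-represented genes.

    ``gene_directions`` maps significant genes to their direction class;
    genes of the set absent from it count as not significant. Inconsistent
    genes also fall into the not-significant bucket for this composition.
    """
    if set_name not in collection.sets:
        raise KeyError(f"unknown gene set {set_name!r}")
    members = sorted(collection.sets[set_name])
    if not members:
        raise ValueError("empty gene set")
    labels = gene_directions.reindex(members)
    n = len(members)
    pos = float((labels == "positive").sum()) / n
    neg = float((labels == "negative").sum()) / n
    return pos, neg, 1.0 - pos - neg


def table2_report(
    ora: pd.DataFrame,
    collection: GeneSetCollection,
    gene_directions: pd.Series,
) -> pd.DataFrame:
    """Per-set report: FDR and gene counts per stratum, ratio, permutation FDR
    (the layout of the headline enrichment table, 'N. A.' for empty strata)."""
    rows = []
    for name in sorted(collection.sets):
        row: dict[str, object] = {"set": name}
        for stratum in STRATA:
            rec = ora.loc[(name, stratum)]
            row[f"fdr_{stratum}"] = (
                "N. A." if bool(rec["not_applicable"]) else float(rec["q"])
            )
            row[f"genes_{stratum}"] = int(rec["x"])
        rec_all = ora.loc[(name, "all")]
        row["ratio"] = float(rec_all["ratio"])
        row["permutation_fdr"] = (
            float(rec_all["permutation_fdr"])
            if "permutation_fdr" in ora.columns
            and not np.isnan(rec_all.get("permutation_fdr", np.nan))
            else np.nan
        )
        pos, neg, ns = direction_composition(name, collection, gene_directions)
        row["frac_positive"] = pos
        row["frac_negative"] = neg
        row["frac_not_significant"] = ns
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")
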