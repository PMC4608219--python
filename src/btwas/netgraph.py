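"""Pathway overlap graph from BMI-associated transcript memberships.

Nodes are gene sets sized by their count of associated transcripts; edges
connect pairs sharing at least one transcript whose Jaccard coefficient
(|A n B| / |A u B|) reaches the chosen percentile of the pairwise
coefficient distribution. The percentile threshold uses the round-up
nearest-rank convention, so at the default 90th percentile at most 10% of
pairs can carry an edge.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd


def jaccard(a: set | frozenset, b: set | frozenset) -> float:
    """|A n B| / |A u B|; error if both sets are empty."""
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(a & b) / union


def _upper_percentile_threshold(values: np.ndarray, percentile: float) -> float:
    """Smallest observed value with at most (100 - percentile)% of the
    sample at or above it (nearest-rank, rounding the retained count up).

    With heavily tied coefficient distributions a plain nearest-rank order
    statistic would let every tied pair through and overshoot the intended
    top-(100-q)% selection; this keeps the retained fraction bounded.
    """
    m = values.size
    if m == 0:
        return np.inf
    cap = int(np.ceil((1.0 - percentile / 100.0) * m))
    if cap >= m:
        return float(values.min())
    if cap == 0:
        return np.inf
    uniq = np.unique(values)  # ascending
    # count of values >= each unique value
    counts_ge = m - np.searchsorted(np.sort(values), uniq, side="left")
    ok = uniq[counts_ge <= cap]
    return float(ok[0]) if ok.size else np.inf


def build_graph(
    memberships: dict[str, set | frozenset],
    percentile: float = 90.0,
    include_zero_pairs: bool = True,
    signatures: dict[str, str] | None = None,
) -> nx.Graph:
    """Overlap graph over >= 2 sets of associated transcripts.

    The threshold is the nearest-rank (round-up) ``percentile`` of all
    pairwise Jaccard coefficients — including zero-overlap pairs unless
    ``include_zero_pairs`` is False. An edge requires a shared transcript
    and a coefficient at or above the threshold. Node attribute ``size`` is
    the set's transcript count; optional ``signature`` labels are attached
    verbatim.
    """
    if len(memberships) < 2:
        raise ValueError("need at least two sets to build an overlap graph")
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    names = sorted(memberships)
    pairs = list(combinations(names, 2))
    stats = []
    for a, b in pairs:
        sa, sb = memberships[a], memberships[b]
        shared = len(sa & sb)
        # two empty membership sets cannot share transcripts: score 0
        j = jaccard(sa, sb) if (sa or sb) else 0.0
        stats.append((a, b, j, shared))
    coeffs = np.array([s[2] for s in stats])
    pool = coeffs if include_zero_pairs else coeffs[coeffs > 0]
    threshold = _upper_percentile_threshold(pool, percentile)

    g = nx.Graph()
    signatures = signatures or {}
    for name in names:
        g.add_node(
            name,
            size=len(memberships[name]),
            signature=signatures.get(name, ""),
        )
    for a, b, j, shared in stats:
        if shared >= 1 and j >= threshold:
            g.add_edge(a, b, jaccard=j, shared_count=shared)
    g.graph["percentile"] = percentile
    g.graph["threshold"] = threshold if np.isfinite(threshold) else -1.0
    return g


def memberships_from_results(
    collection,
    meta: pd.DataFrame,
    annotation: pd.Series,
    q_threshold: float = 0.01,
) -> dict[str, frozenset]:
    """Per-set sets of significantly associated transcripts (q < threshold)
    mapping to the set's genes."""
    sig = meta[meta["q"] < q_threshold]
    ann = annotation.reindex(sig.index).dropna()
    probes_of_gene: dict[str, list[str]] = {}
    for probe, gene in ann.items():
        probes_of_gene.setdefault(gene, []).append(probe)
    out = {}
    for name, genes in collection.sets.items():
        probes: list[str] = []
        for gene in genes:
            probes.extend(probes_of_gene.get(gene, []))
        out[name] = frozenset(probes)
    return out


def edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {
            "source": a,
            "target": b,
            "jaccard": d["jaccard"],
            "shared_count": d["shared_count"],
        }
        for a, b, d in sorted(g.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "jaccard", "shared_count"])


def node_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        {"set": n, "size": d["size"], "signature": d["signature"]}
        for n, d in sorted(g.nodes(data=True))
    ]
    return pd.DataFrame(rows, columns=["set", "size", "signature"])


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
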