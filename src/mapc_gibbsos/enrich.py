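"""Hypergeometric TF enrichment of gene clusters.

For each TF j and cluster c, tests whether the cluster contains more
TF-j-bound genes than expected when drawing a random gene set of the same
size from the population:

    p = sum_{i=Nb}^{min(NB, Nc)} C(NB, i) C(N - NB, Nc - i) / C(N, Nc),

with N genes in the population, NB of them bound by the TF, Nc in the
cluster and Nb bound cluster genes.  p-values convert to bounded scores via
the standard-normal quantile Phi^{-1}(1 - p), capped at 4 by default, so an
enrichment at p <= 0.05 corresponds to a score >= 1.645.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "hypergeom_pvalue",
    "enrich_cluster",
    "enrich_all_clusters",
    "pvalue_to_score",
]


@dataclasses.dataclass
class EnrichmentResult:
    cluster_id: int
    tf_id: str
    n_cluster: int      # Nc
    n_hits: int         # Nb
    n_tf_targets: int   # NB
    n_total: int        # N
    p_value: float
    enriched: bool


def hypergeom_pvalue(N: int, NB: int, Nc: int, Nb: int) -> float:
    """Upper-tail hypergeometric probability P(hits >= Nb).

    Computed through the survival function for numerical stability; the
    literal binomial-coefficient sum is kept as a test oracle.
    """
    if not (0 <= Nb <= min(NB, Nc) and Nc <= N and NB <= N):
        raise ValueError(
            f"impossible counts: N={N}, NB={NB}, Nc={Nc}, Nb={Nb}")
    return float(stats.hypergeom.sf(Nb - 1, N, NB, Nc))


def enrich_cluster(
    cluster: np.ndarray | list,
    W: pd.DataFrame,
    threshold: float = 0.05,
    cluster_id: int = 0,
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """Test every TF for enrichment in one cluster of genes.

    ``cluster`` holds row positions (ints) or gene ids (matching W's index).
    Results are sorted by ascending p-value, ties broken by TF id.  With
    ``fdr`` the enriched flag applies the threshold to Benjamini-Hochberg
    adjusted p-values across the cluster's TFs (raw p-values are still
    reported); off by default.
    """
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    cluster = np.asarray(cluster)
    if cluster.dtype.kind in "iu":
        sub = W.iloc[cluster]
    else:
        sub = W.loc[cluster]
    N = W.shape[0]
    Nc = sub.shape[0]
    NB_all = W.to_numpy().sum(axis=0)
    Nb_all = sub.to_numpy().sum(axis=0)

    pvals = np.array([hypergeom_pvalue(N, int(NB), Nc, int(Nb))
                      for NB, Nb in zip(NB_all, Nb_all)])
    decide = stats.false_discovery_control(pvals) if fdr else pvals
    results = [
        EnrichmentResult(
            cluster_id=cluster_id, tf_id=tf, n_cluster=Nc,
            n_hits=int(Nb), n_tf_targets=int(NB), n_total=N,
            p_value=float(p), enriched=bool(q <= threshold),
        )
        for tf, NB, Nb, p, q in zip(W.columns, NB_all, Nb_all, pvals, decide)
    ]
    results.sort(key=lambda r: (r.p_value, r.tf_id))
    return results


def enrich_all_clusters(
    assignment,
    W: pd.DataFrame,
    threshold: float = 0.05,
) -> pd.DataFrame:
    """Enrichment table for every cluster of a ClusterAssignment."""
    rows = []
    for cid in np.unique(assignment.labels):
        members = assignment.members(cid)
        for r in enrich_cluster(members, W, threshold, cluster_id=int(cid)):
            rows.append(dataclasses.asdict(r))
    out = pd.DataFrame(rows)
    out["score"] = [pvalue_to_score(p) for p in out["p_value"]]
    return out


def pvalue_to_score(p: float, cap: float = 4.0) -> float:
    """Map a p-value to the standard-normal quantile Phi^{-1}(1-p).

    Monotone decreasing in p and clipped at ``cap`` to tame extreme values;
    p = 0 returns the cap.
    """
    if p < 0 or p > 1:
        raise ValueError(f"p-value out of range: {p}")
    if p == 0:
        return cap
    return float(min(stats.norm.ppf(1.0 - p), cap))
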