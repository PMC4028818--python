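"""Motif-guided affinity propagation clustering (mAPC).

Genes are clustered with a similarity that blends co-expression and
co-regulation evidence:

    s(i,j) = -(1 - lambda) * ||x_i - x_j||^2 + lambda * s_reg(i,j),

where ``s_reg(i,j)`` is the inner product of the binary motif-binding rows
of genes i and j (the number of TFs with candidate sites in both promoters).
At ``lambda = 0`` this reduces to classical affinity propagation on
expression alone; at ``lambda = 1`` clustering depends only on the binding
pattern.  Affinity propagation itself follows the standard
responsibility/availability message-passing scheme with damping; the
diagonal "preference" controls how many exemplars (clusters) emerge.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "expression_similarity",
    "coregulation_similarity",
    "combined_similarity",
    "resolve_preference",
    "affinity_propagation",
    "cluster_genes",
]


@dataclasses.dataclass
class ClusterAssignment:
    """Result of one affinity-propagation run."""

    labels: np.ndarray       # (n,) cluster id per gene, 0..n_clusters-1
    exemplars: np.ndarray    # (n_clusters,) index of each cluster's exemplar
    n_iterations: int
    converged: bool
    gene_ids: list[str] | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)

    def to_frame(self) -> pd.DataFrame:
        ids = self.gene_ids or [str(i) for i in range(len(self.labels))]
        return pd.DataFrame({
            "gene_id": ids,
            "cluster_id": self.labels,
            "exemplar_flag": np.isin(np.arange(len(self.labels)),
                                     self.exemplars).astype(int),
        })


def expression_similarity(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Negative squared Euclidean distance between expression rows."""
    values = np.asarray(X, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if np.isnan(values).any():
        raise ValueError("expression matrix contains NaN")
    return -squareform(pdist(values, metric="sqeuclidean"))


def coregulation_similarity(W: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Shared-TF count between genes: s_reg(k,t) = sum_j w(k,j) w(t,j).

    The diagonal holds each gene's own binding degree; downstream it is
    overwritten by the affinity-propagation preference.
    """
    values = np.asarray(W)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("binding matrix must be binary")
    values = values.astype(float)
    return values @ values.T


def combined_similarity(
    X: pd.DataFrame | np.ndarray,
    W: pd.DataFrame | np.ndarray,
    lam: float = 0.5,
    normalize: bool = True,
) -> np.ndarray:
    """Blend expression and co-regulation similarity with weight ``lam``.

    With ``normalize`` on (default) each term is divided by the standard
    deviation of its off-diagonal entries before weighting, making ``lam``
    comparable across datasets; with it off the literal weighted sum is
    returned.  Degenerate terms with zero spread are left unscaled.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if isinstance(X, pd.DataFrame) and isinstance(W, pd.DataFrame):
        if not X.index.equals(W.index):
            raise ValueError("expression and binding gene indices differ")
    elif np.asarray(X).shape[0] != np.asarray(W).shape[0]:
        raise ValueError("expression and binding gene counts differ")

    s_expr = expression_similarity(X)
    s_reg = coregulation_similarity(W)
    if normalize:
        off = ~np.eye(len(s_expr), dtype=bool)
        for term in (s_expr, s_reg):
            sd = term[off].std()
            if sd > 0:
                term /= sd
    return (1.0 - lam) * s_expr + lam * s_reg


def resolve_preference(S: np.ndarray, preference) -> np.ndarray:
    """Turn a preference spec into a per-point vector.

    Accepts a scalar, a vector, ``("quantile", q)``, or one of
    ``"median"`` / ``"min"`` / ``"low"`` of the off-diagonal similarities;
    ``"low"`` is min - 4*(max - min), well below every pairwise similarity,
    for recovering a small number of large clusters.
    """
    n = S.shape[0]
    off = S[~np.eye(n, dtype=bool)]
    if isinstance(preference, str):
        if preference == "median":
            value = float(np.median(off))
        elif preference == "min":
            value = float(off.min())
        elif preference == "low":
            value = float(off.min() - 4.0 * (off.max() - off.min()))
        else:
            raise ValueError(f"unknown preference '{preference}'")
        return np.full(n, value)
    if isinstance(preference, tuple) and preference[0] == "quantile":
        return np.full(n, float(np.quantile(off, preference[1])))
    pref = np.asarray(preference, dtype=float)
    if pref.ndim == 0:
        return np.full(n, float(pref))
    if pref.shape != (n,):
        raise ValueError("per-point preference has wrong length")
    return pref


def affinity_propagation(
    S: np.ndarray,
    preference="median",
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 50,
    tie_noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
    gene_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Standard affinity propagation on a similarity matrix.

    Messages::

        r(i,k) <- s(i,k) - max_{k' != k} [a(i,k') + s(i,k')]
        a(i,k) <- min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
        a(k,k) <- sum_{i' != k} max(0, r(i',k))

    with damped updates; exemplars are the points with r(k,k)+a(k,k) > 0,
    and every point joins its most similar exemplar.  The run converges when
    the exemplar set is stable for ``conv_iter`` iterations; otherwise the
    last assignment is returned with ``converged=False``.  Deterministic
    unless ``tie_noise > 0`` (seeded symmetric jitter for degenerate ties).
    """
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must be in [0.5, 1)")
    S = np.array(S, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("similarity matrix must be square")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")

    S = S.copy()
    S[np.diag_indices_from(S)] = resolve_preference(S, preference)
    if tie_noise > 0:
        jitter = rng if isinstance(rng, np.random.Generator) \
            else np.random.default_rng(rng)
        noise = jitter.standard_normal((n, n)) * tie_noise
        S += (noise + noise.T) / 2.0

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    stable = 0
    exemplars = np.array([], dtype=int)
    it = 0
    converged = False

    for it in range(1, max_iter + 1):
        # responsibilities
        AS = A + S
        first = AS.max(axis=1)
        arg_first = AS.argmax(axis=1)
        AS[idx, arg_first] = -np.inf
        second = AS.max(axis=1)
        R_new = S - first[:, None]
        R_new[idx, arg_first] = S[idx, arg_first] - second
        R = damping * R + (1.0 - damping) * R_new

        # availabilities
        Rp = np.maximum(R, 0.0)
        Rp[np.diag_indices_from(Rp)] = R.diagonal()
        col = Rp.sum(axis=0)
        A_new = np.minimum(0.0, col[None, :] - Rp)
        # diagonal: sum over i' != k of max(0, r(i',k))
        A_new[np.diag_indices_from(A_new)] = col - R.diagonal()
        A = damping * A + (1.0 - damping) * A_new

        new_exemplars = np.flatnonzero(R.diagonal() + A.diagonal() > 0)
        if new_exemplars.size and np.array_equal(new_exemplars, exemplars):
            stable += 1
            if stable >= conv_iter:
                converged = True
                exemplars = new_exemplars
                break
        else:
            stable = 0
        exemplars = new_exemplars

    if exemplars.size == 0:
        # degenerate run: fall back to the single best self-evidence point
        exemplars = np.array([int((R.diagonal() + A.diagonal()).argmax())])
        logger.warning("affinity propagation found no exemplars; "
                       "falling back to one cluster")
    if not converged:
        logger.warning("affinity propagation did not converge in %d "
                       "iterations", max_iter)

    labels_ex = S[:, exemplars].argmax(axis=1)
    labels_ex[exemplars] = np.arange(exemplars.size)  # exemplars own cluster
    return ClusterAssignment(labels=labels_ex, exemplars=exemplars,
                             n_iterations=it, converged=converged,
                             gene_ids=gene_ids)


def cluster_genes(
    X: pd.DataFrame,
    W: pd.DataFrame,
    lam: float = 0.5,
    normalize: bool = True,
    preference="median",
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 50,
    tie_noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> ClusterAssignment:
    """Full mAPC path: combined similarity then affinity propagation."""
    S = combined_similarity(X, W, lam=lam, normalize=normalize)
    gene_ids = list(X.index) if isinstance(X, pd.DataFrame) else None
    return affinity_propagation(S, preference=preference, damping=damping,
                                max_iter=max_iter, conv_iter=conv_iter,
                                tie_noise=tie_noise, rng=rng,
                                gene_ids=gene_ids)
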