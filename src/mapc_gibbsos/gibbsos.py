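"""Gibbs sampler on the outlier-sum statistic (GibbsOS).

Separates true TF target genes ("foreground") from spurious candidates in a
binary binding matrix contaminated with false positives.  Under the linear
model X = A S + noise, the expression of any foreground gene lies in the row
space of the TF activities S, which is spanned by the expression of one
well-chosen "seed" target per TF.  Given seeds Theta = [theta_1..theta_M],
regressing another candidate y of TF j on the seed expression matrix F gives
a t-statistic for the coefficient of TF j's seed; summing the t-statistics
that exceed a Student-t threshold over all other candidates of TF j yields
the outlier-sum (OS) score of the seed choice:

    OS(theta_j) = sum_{k != i} |t_jk| * 1{|t_jk| >= t_{alpha/2, K-M-1}}.

Normalizing OS over the candidates of TF j gives a conditional distribution
p(theta_j | theta_{-j}); sweeping TFs in fixed order and sampling each seed
from its conditional is a Gibbs chain whose post-burn-in seed frequencies
approximate the marginal probability that each candidate is a true target.

The per-candidate t-statistics are computed through Frisch-Waugh-Lovell
residualization (one least-squares solve per TF per sweep plus a Gram
matrix), which is algebraically identical to fitting each candidate's OLS
model separately; :func:`regress` keeps the literal normal-equations route.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "CandidatePool",
    "SamplingTrace",
    "regress",
    "outlier_sum",
    "conditional_weights",
    "gibbs_sample",
    "score_genes",
    "gene_level_scores",
    "run_gibbsos",
]

#: |t| reported for perfect fits (MSE = 0) instead of infinity
T_SENTINEL = 1e6
_EPS = 1e-12


@dataclasses.dataclass
class RegressionFit:
    beta_hat: np.ndarray     # coefficients of the M seed columns
    intercept: float
    mse: float
    t_stats: np.ndarray      # one t per seed column
    dof: int
    rank_deficient: bool = False


@dataclasses.dataclass
class CandidatePool:
    """Per-TF candidate target genes (row positions into the expression)."""

    tf_indices: np.ndarray          # column positions of the TFs
    candidates: list[np.ndarray]    # candidates[j]: gene rows with w=1

    @property
    def n_tfs(self) -> int:
        return len(self.tf_indices)

    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.candidates])

    @classmethod
    def from_binding(cls, W: pd.DataFrame | np.ndarray,
                     genes: np.ndarray | None = None,
                     tfs: np.ndarray | None = None) -> "CandidatePool":
        """Build pools from a binding matrix, dropping candidate-less TFs."""
        values = np.asarray(W)
        genes = np.arange(values.shape[0]) if genes is None \
            else np.asarray(genes)
        tfs = np.arange(values.shape[1]) if tfs is None else np.asarray(tfs)
        kept, cands = [], []
        for j in tfs:
            cand = genes[values[genes, j] == 1]
            if cand.size:
                kept.append(j)
                cands.append(cand)
        if len(kept) < len(tfs):
            logger.debug("dropped %d TFs with no candidates in the pool",
                         len(tfs) - len(kept))
        return cls(tf_indices=np.array(kept, dtype=int), candidates=cands)


@dataclasses.dataclass
class SamplingTrace:
    """Record of sampled seeds; yields per-(TF, gene) marginal frequencies."""

    pool: CandidatePool
    seeds: np.ndarray        # (n_recorded, n_tfs) gene rows, post burn-in
    burn_in: int
    n_iter: int

    def frequency(self) -> list[dict[int, float]]:
        """Per TF: {gene row: fraction of recorded sweeps as seed}."""
        out = []
        n = self.seeds.shape[0]
        for j in range(self.pool.n_tfs):
            genes, counts = np.unique(self.seeds[:, j], return_counts=True)
            out.append({int(g): c / n for g, c in zip(genes, counts)})
        return out


def regress(y: np.ndarray, F: np.ndarray,
            include_intercept: bool = True) -> RegressionFit:
    """Ordinary least squares of one gene on the seed expression matrix.

    ``F`` is K samples x M seeds.  Returns coefficient estimates, the mean
    squared error on K - M - 1 degrees of freedom, and per-coefficient
    t-statistics t_m = beta_m / sqrt(MSE * C_mm) with C = (F^T F)^{-1}.
    Perfect fits (MSE = 0) report |t| = 1e6 for nonzero coefficients.  A
    rank-deficient normal matrix falls back to the pseudo-inverse and is
    flagged.
    """
    y = np.asarray(y, dtype=float).ravel()
    F = np.asarray(F, dtype=float)
    if F.ndim != 2:
        raise ValueError("F must be 2-D (samples x seeds)")
    K, M = F.shape
    if y.shape[0] != K:
        raise ValueError("y and F disagree on sample count")
    dof = K - M - 1 if include_intercept else K - M
    if dof < 1:
        raise ValueError(
            f"K={K} samples cannot support M={M} seeds "
            f"(needs K > M + {1 if include_intercept else 0} + 1)")

    D = np.column_stack([np.ones(K), F]) if include_intercept else F
    G = D.T @ D
    rank_deficient = False
    try:
        C = np.linalg.inv(G)
        if not np.all(np.isfinite(C)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        C = np.linalg.pinv(G)
        rank_deficient = True
        logger.debug("rank-deficient seed design; using pseudo-inverse")
    beta = C @ D.T @ y
    rss = float(y @ y - y @ D @ C @ D.T @ y)
    rss = max(rss, 0.0)
    mse = rss / dof

    diag = np.clip(np.diag(C), _EPS, None)
    scale = y @ y + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(mse * diag)
    if mse <= _EPS * scale:
        t = np.where(np.abs(beta) > np.sqrt(_EPS * scale),
                     np.sign(beta) * T_SENTINEL, 0.0)
    t = np.clip(t, -T_SENTINEL, T_SENTINEL)

    if include_intercept:
        return RegressionFit(beta_hat=beta[1:], intercept=float(beta[0]),
                             mse=mse, t_stats=t[1:], dof=dof,
                             rank_deficient=rank_deficient)
    return RegressionFit(beta_hat=beta, intercept=0.0, mse=mse, t_stats=t,
                         dof=dof, rank_deficient=rank_deficient)


def outlier_sum(t_stats, alpha: float, dof: int,
                signed: bool = False) -> float:
    """Sum of t-statistics beyond the Student-t alpha/2 threshold.

    Default (two-sided) convention: OS = sum |t_k| over |t_k| >= tau with
    tau the upper alpha/2 quantile on ``dof`` degrees of freedom, so
    negative associations count.  ``signed=True`` gives the literal one-side
    reading OS = sum t_k over t_k >= tau.
    """
    if dof < 1:
        raise ValueError("dof must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = np.asarray(t_stats, dtype=float)
    if t.size == 0:
        return 0.0
    tau = stats.t.ppf(1.0 - alpha / 2.0, dof)
    if signed:
        return float(t[t >= tau].sum())
    a = np.abs(t)
    return float(a[a >= tau].sum())


def _conditional_os_fast(X: np.ndarray, cand: np.ndarray,
                         other_seeds: np.ndarray, n_design_tfs: int,
                         alpha: float, signed: bool) -> np.ndarray:
    """OS score of every candidate seed of one TF, via FWL residualization.

    For candidate i and target k (both in ``cand``), the t-statistic of
    candidate i's coefficient when regressing x_k on [1, other seeds, x_i]
    equals  G_ik * sqrt(dof) / sqrt(n_i * n_k - G_ik^2)  where G is the Gram
    matrix of the candidate expression residualized against the intercept
    and the other seeds.  ``n_design_tfs`` is the seed-column count M of the
    full design, giving dof = K - M - 1.
    """
    K = X.shape[1]
    dof = K - n_design_tfs - 1
    if dof < 1:
        raise ValueError(f"K={K} samples cannot support {n_design_tfs} seeds")
    Z = np.column_stack([np.ones(K)] +
                        ([X[other_seeds].T] if other_seeds.size else []))
    E = X[cand].T                                   # K x K_j
    coef, *_ = np.linalg.lstsq(Z, E, rcond=None)
    Et = E - Z @ coef
    G = Et.T @ Et
    n = np.diag(G).copy()

    denom2 = np.outer(n, n) - G * G
    scale = np.outer(n, n) + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        T = G * np.sqrt(dof) / np.sqrt(np.clip(denom2, _EPS, None))
    perfect = denom2 <= _EPS * scale
    T = np.where(perfect, np.where(np.abs(G) > _EPS * np.sqrt(scale),
                                   np.sign(G) * T_SENTINEL, 0.0), T)
    T = np.clip(T, -T_SENTINEL, T_SENTINEL)
    np.fill_diagonal(T, 0.0)

    tau = stats.t.ppf(1.0 - alpha / 2.0, dof)
    if signed:
        contrib = np.where(T >= tau, T, 0.0)
    else:
        A = np.abs(T)
        contrib = np.where(A >= tau, A, 0.0)
    np.fill_diagonal(contrib, 0.0)
    return contrib.sum(axis=1)     # row i: OS of choosing candidate i


def conditional_weights(j: int, seeds: np.ndarray, X: np.ndarray | pd.DataFrame,
                        pool: CandidatePool, alpha: float = 0.05,
                        signed: bool = False) -> np.ndarray:
    """Conditional seed distribution for TF j given the other TFs' seeds.

    For each candidate of TF j: place it as TF j's seed, regress every other
    candidate of TF j on the full seed design, and sum the outlier
    t-contributions.  The OS values are normalized to a probability vector;
    if every OS is zero the distribution falls back to uniform (keeps the
    chain irreducible).
    """
    X = np.asarray(X, dtype=float)
    cand = pool.candidates[j]
    if cand.size == 1:
        return np.ones(1)
    others = np.delete(np.arange(pool.n_tfs), j)
    os_vals = _conditional_os_fast(X, cand, seeds[others], pool.n_tfs,
                                   alpha, signed)
    total = os_vals.sum()
    if total <= 0:
        return np.full(cand.size, 1.0 / cand.size)
    return os_vals / total


def conditional_weights_bruteforce(j, seeds, X, pool, alpha=0.05,
                                   signed=False) -> np.ndarray:
    """Literal route: one explicit OLS fit per (candidate, target) pair.

    Kept as the slow reference implementation of
    :func:`conditional_weights`; the sampler never calls it.
    """
    X = np.asarray(X, dtype=float)
    cand = pool.candidates[j]
    if cand.size == 1:
        return np.ones(1)
    os_vals = np.empty(cand.size)
    theta = seeds.copy()
    for i, gi in enumerate(cand):
        theta[j] = gi
        F = X[theta].T
        ts = [regress(X[gk], F).t_stats[j] for gk in cand if gk != gi]
        fit_dof = X.shape[1] - pool.n_tfs - 1
        os_vals[i] = outlier_sum(ts, alpha, fit_dof, signed=signed)
    total = os_vals.sum()
    if total <= 0:
        return np.full(cand.size, 1.0 / cand.size)
    return os_vals / total


def gibbs_sample(X: np.ndarray | pd.DataFrame, pool: CandidatePool,
                 n_iter: int = 500, burn_in: int = 100, alpha: float = 0.05,
                 rng: np.random.Generator | int | None = None,
                 signed: bool = False) -> SamplingTrace:
    """Run the Gibbs chain over seed assignments.

    Seeds initialize uniformly at random from each TF's candidates; each
    sweep resamples every TF in fixed order from its conditional.  Seeds
    from the ``n_iter - burn_in`` post-burn-in sweeps are recorded.
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    X = np.asarray(X, dtype=float)
    if any(c.size == 0 for c in pool.candidates):
        raise ValueError("every TF passed to the sampler needs >= 1 candidate")
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    M = pool.n_tfs
    seeds = np.array([rng.choice(c) for c in pool.candidates])
    recorded = np.empty((n_iter - burn_in, M), dtype=int)
    for t in range(n_iter):
        for j in range(M):
            w = conditional_weights(j, seeds, X, pool, alpha, signed)
            seeds[j] = rng.choice(pool.candidates[j], p=w)
        if t >= burn_in:
            recorded[t - burn_in] = seeds
    return SamplingTrace(pool=pool, seeds=recorded, burn_in=burn_in,
                         n_iter=n_iter)


def score_genes(trace: SamplingTrace) -> pd.DataFrame:
    """Marginal seed frequencies, and a per-gene score = max over TFs.

    Returns a tidy frame (tf, gene, frequency).  Use
    :func:`gene_level_scores` on it for ranking genes.
    """
    if trace.seeds.shape[0] < 1:
        raise ValueError("trace has no post-burn-in samples")
    rows = []
    for j, freqs in enumerate(trace.frequency()):
        tf = int(trace.pool.tf_indices[j])
        for g, f in sorted(freqs.items()):
            rows.append((tf, g, f))
    return pd.DataFrame(rows, columns=["tf", "gene", "frequency"])


def gene_level_scores(freq_table: pd.DataFrame, genes: np.ndarray) -> np.ndarray:
    """Ranking score per gene: max sampling frequency across TFs (0 if absent)."""
    best = freq_table.groupby("gene")["frequency"].max()
    return np.array([float(best.get(g, 0.0)) for g in genes])


def run_gibbsos(X: pd.DataFrame | np.ndarray, W: pd.DataFrame | np.ndarray,
                genes: np.ndarray | None = None,
                tfs: np.ndarray | None = None,
                n_iter: int = 500, burn_in: int = 100, alpha: float = 0.05,
                rng: np.random.Generator | int | None = None,
                signed: bool = False) -> pd.DataFrame:
    """High-level GibbsOS run on a gene subset (or the whole pool).

    The seed regression needs K > M + 2, so when the TF set is larger than
    K - 2 the TFs are partitioned (seeded, near-equal) into batches of at
    most K - 2 and an independent chain runs per batch; frequencies from all
    batches concatenate into one (tf, gene, frequency) table.  This is what
    makes very small sample sizes and TF pools larger than the sample count
    analyzable at all, at the cost of ignoring cross-batch confounding.
    """
    Xv = np.asarray(X, dtype=float)
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    pool = CandidatePool.from_binding(W, genes=genes, tfs=tfs)
    if pool.n_tfs == 0:
        return pd.DataFrame(columns=["tf", "gene", "frequency"])
    K = Xv.shape[1]
    cap = max(K - 2, 1)
    if pool.n_tfs <= cap:
        batches = [np.arange(pool.n_tfs)]
    else:
        n_batches = int(np.ceil(pool.n_tfs / cap))
        order = rng.permutation(pool.n_tfs)
        batches = np.array_split(order, n_batches)
        logger.info("TF set of %d exceeds regression capacity %d at K=%d; "
                    "running %d batched chains", pool.n_tfs, cap, K,
                    n_batches)
    tables = []
    for batch in batches:
        sub = CandidatePool(tf_indices=pool.tf_indices[batch],
                            candidates=[pool.candidates[j] for j in batch])
        trace = gibbs_sample(Xv, sub, n_iter=n_iter, burn_in=burn_in,
                             alpha=alpha, rng=rng, signed=signed)
        tables.append(score_genes(trace))
    return pd.concat(tables, ignore_index=True)
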