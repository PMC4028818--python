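"""End-to-end orchestration: preselection, two-step run, bootstrap scoring.

The full workflow on a real dataset is: (1) optionally preselect
differentially expressed genes between two sample groups by t-test and split
them into up-/down-regulated sets; (2) cluster the genes with motif-guided
affinity propagation; (3) test TF enrichment per cluster; (4) refine each
cluster's target genes with GibbsOS restricted to the cluster's enriched
TFs; (5) optionally assess the stability of the identified TFs by
bootstrap resampling of samples (stratified within groups), reporting the
fraction of resamples in which each TF is identified.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import gibbsos, mapc
from .enrich import enrich_all_clusters, pvalue_to_score

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "BootstrapReport",
    "select_differential_genes",
    "run_two_step",
    "bootstrap_confidence",
]


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of the two-step pipeline, serializable to YAML/JSON."""

    lam: float = 0.5
    normalize: bool = True
    preference: object = "median"
    damping: float = 0.9
    max_iter: int = 1000
    conv_iter: int = 50
    enrich_threshold: float = 0.05
    gibbs_alpha: float = 0.05
    gibbs_iters: int = 500
    gibbs_burn_in: int = 100
    deg_p_threshold: float = 0.05
    #: pooled-variance t-test instead of Welch
    pooled_ttest: bool = False
    n_boot: int = 100
    #: a TF is "identified" when its enrichment score reaches
    #: the standard-normal quantile of this confidence level
    confidence_level: float = 0.9
    score_cap: float = 4.0
    seed: int | None = None

    def validate(self) -> None:
        for name in ("enrich_threshold", "gibbs_alpha", "deg_p_threshold",
                     "confidence_level"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @property
    def score_threshold(self) -> float:
        """Identification cut-off: 1.645 at the default 0.9 confidence.

        The convention is score = Phi^{-1}(1 - p); a 0.9 confidence level is
        read as enrichment at p <= 0.05, i.e. score >= Phi^{-1}(0.95).
        """
        alpha = (1.0 - self.confidence_level) / 2.0
        return float(stats.norm.ppf(1.0 - alpha))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclasses.dataclass
class BootstrapReport:
    """Per-TF identification frequencies over bootstrap resamples."""

    confidence: pd.Series          # TF -> fraction of resamples identified
    score_distribution: pd.DataFrame  # tidy: resample, tf_id, score
    n_boot: int


def select_differential_genes(
    X: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    p_threshold: float = 0.05,
    pooled: bool = False,
) -> tuple[list[str], list[str]]:
    """Two-sample t-test per gene; returns (up, down) gene-id sets.

    ``groups`` assigns each sample (column of X) to one of exactly two
    labels; the first label in sorted order is the reference "case" group.
    Genes at p < threshold split by sign of (case mean - control mean) into
    up-regulated and down-regulated lists.  Zero-variance genes in both
    groups are excluded (p treated as 1).
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"need exactly two groups, got {levels.size}")
    mask_a = groups == levels[0]
    if mask_a.sum() < 2 or (~mask_a).sum() < 2:
        raise ValueError("both groups need >= 2 samples")
    a = X.loc[:, mask_a].to_numpy()
    b = X.loc[:, ~mask_a].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=pooled)
    p = np.where(np.isnan(p), 1.0, p)
    diff = a.mean(axis=1) - b.mean(axis=1)
    selected = p < p_threshold
    up = [g for g, s, d in zip(X.index, selected, diff) if s and d > 0]
    down = [g for g, s, d in zip(X.index, selected, diff) if s and d <= 0]
    return up, down


def run_two_step(
    X: pd.DataFrame,
    W: pd.DataFrame,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | int | None = None,
    out_dir: str | Path | None = None,
):
    """mAPC -> per-cluster enrichment -> per-cluster GibbsOS.

    Returns (ClusterAssignment, enrichment table, per-cluster score table
    with columns cluster_id/tf/gene/gene_id/frequency).  Clusters with no
    enriched TF are skipped for sampling and logged.  Fully seeded; when
    ``out_dir`` is given all intermediates are written as TSV.
    """
    config = config or PipelineConfig()
    config.validate()
    if rng is None:
        rng = config.seed
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    if not X.index.equals(W.index):
        raise ValueError("expression and binding must share the gene index")
    logger.info("two-step run: %d genes, %d samples, %d TFs (config %s)",
                X.shape[0], X.shape[1], W.shape[1], config.config_hash())

    assignment = mapc.cluster_genes(
        X, W, lam=config.lam, normalize=config.normalize,
        preference=config.preference, damping=config.damping,
        max_iter=config.max_iter, conv_iter=config.conv_iter)
    logger.info("mAPC: %d clusters (converged=%s)", assignment.n_clusters,
                assignment.converged)
    enrichment = enrich_all_clusters(assignment, W,
                                     threshold=config.enrich_threshold)

    tf_pos = {tf: j for j, tf in enumerate(W.columns)}
    tables = []
    for cid in np.unique(assignment.labels):
        members = assignment.members(cid)
        sub = enrichment[(enrichment.cluster_id == cid) & enrichment.enriched]
        enriched_tfs = np.array([tf_pos[tf] for tf in sub.tf_id])
        if enriched_tfs.size == 0:
            logger.warning("cluster %d: no enriched TF, sampling skipped",
                           cid)
            continue
        table = gibbsos.run_gibbsos(
            X, W, genes=members, tfs=enriched_tfs,
            n_iter=config.gibbs_iters, burn_in=config.gibbs_burn_in,
            alpha=config.gibbs_alpha, rng=rng)
        table.insert(0, "cluster_id", int(cid))
        tables.append(table)
    scores = (pd.concat(tables, ignore_index=True) if tables
              else pd.DataFrame(columns=["cluster_id", "tf", "gene",
                                         "frequency"]))
    scores["gene_id"] = [X.index[g] for g in scores.gene]
    scores["tf_id"] = [W.columns[j] for j in scores.tf]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t",
                                     index=False)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), default=str, indent=1))
    return assignment, enrichment, scores


def identified_tfs(enrichment: pd.DataFrame, threshold_score: float,
                   cap: float = 4.0) -> pd.Series:
    """Best (max over clusters) enrichment score per TF, as a Series."""
    scores = enrichment.assign(
        score=[pvalue_to_score(p, cap) for p in enrichment.p_value])
    return scores.groupby("tf_id")["score"].max()


def bootstrap_confidence(
    X: pd.DataFrame,
    W: pd.DataFrame,
    groups: pd.Series | np.ndarray | None = None,
    config: PipelineConfig | None = None,
    rng: np.random.Generator | int | None = None,
    resample: bool = True,
) -> BootstrapReport:
    """Stability of identified TFs under sample resampling.

    Each of ``n_boot`` resamples draws samples with replacement (stratified
    within groups when ``groups`` is given, preserving group sizes for the
    t-test), reruns gene preselection (if grouped) and the two-step
    pipeline, and marks a TF "identified" when its best cluster enrichment
    score reaches the confidence threshold.  The confidence score of a TF is
    its identification frequency; per-resample scores are kept for
    distribution summaries.  A degenerate resample (any all-identical
    sample group) is redrawn with a fresh draw.
    """
    config = config or PipelineConfig()
    config.validate()
    if rng is None:
        rng = config.seed
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    n_samples = X.shape[1]
    groups = None if groups is None else np.asarray(groups)

    counts: dict[str, int] = {tf: 0 for tf in W.columns}
    score_rows = []
    for b in range(config.n_boot):
        for _attempt in range(100):
            if not resample:
                cols = np.arange(n_samples)
            elif groups is None:
                cols = rng.integers(0, n_samples, n_samples)
            else:
                cols = np.concatenate([
                    rng.choice(np.flatnonzero(groups == lv),
                               size=(groups == lv).sum(), replace=True)
                    for lv in np.unique(groups)])
            Xb = X.iloc[:, cols]
            Xb.columns = [f"bs{j}" for j in range(len(cols))]
            gb = groups[cols] if groups is not None else None
            if gb is not None:
                degenerate = any(
                    np.allclose(Xb.loc[:, gb == lv].to_numpy().std(axis=1), 0)
                    for lv in np.unique(gb))
                if degenerate:
                    logger.warning("degenerate resample %d; redrawing", b)
                    continue
            break
        if gb is not None:
            up, down = select_differential_genes(
                Xb, gb, config.deg_p_threshold, pooled=config.pooled_ttest)
            keep = up + down
            if len(keep) < 3:
                logger.warning("resample %d selected <3 genes; skipped as "
                               "unidentifiable", b)
                keep = list(X.index)
            Xb = Xb.loc[keep]
            Wb = W.loc[keep]
        else:
            Wb = W
        _, enrichment, _ = run_two_step(Xb, Wb, config, rng)
        best = identified_tfs(enrichment, config.score_threshold,
                              config.score_cap)
        for tf, score in best.items():
            score_rows.append({"resample": b, "tf_id": tf, "score": score})
            if score >= config.score_threshold:
                counts[tf] += 1

    confidence = pd.Series({tf: c / config.n_boot
                            for tf, c in counts.items()}).sort_index()
    return BootstrapReport(confidence=confidence,
                           score_distribution=pd.DataFrame(score_rows),
                           n_boot=config.n_boot)
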