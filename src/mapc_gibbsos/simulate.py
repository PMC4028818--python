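"""Synthetic benchmark generator for modular gene regulatory networks.

Generates binary motif-binding matrices with modularized structure, latent
Gaussian transcription-factor (TF) activities, and log-scale expression data
under the bipartite linear model

    X = A S + Gamma,

where ``X`` (N genes x K samples) is expression, ``A`` (N x M) holds
regulation strengths whose support is the true binding pattern, ``S``
(M x K) holds TF activities, and ``Gamma`` is additive Gaussian noise at a
requested signal-to-noise ratio.  "Foreground" genes follow the model;
"background" genes are pure Gaussian noise rescaled to the same variance.
False-positive binding connections are injected at a configurable ratio
to the number of true foreground connections, emulating the contamination
of motif-scanning data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulationData",
    "generate_binding",
    "inject_false_positives",
    "generate_expression",
    "simulate_dataset",
    "write_dataset",
]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the synthetic benchmark.

    Defaults reproduce the standard setup: 300 genes (100 foreground in two
    modules of 50, 200 background), 80 TFs, 20 samples, SNR 5 dB, false
    positives equal in number to true positives (fp_ratio 1.0).
    """

    n_foreground: int = 100
    n_background: int = 200
    n_tfs: int = 80
    n_samples: int = 20
    n_modules: int = 2
    snr_db: float = 5.0
    fp_ratio: float = 1.0
    #: number of module TFs each foreground gene binds (fixed degree)
    binding_degree: int = 5
    #: TFs owned by each foreground module; None = a share proportional to
    #: group gene counts (background pseudo-modules hold more genes, so
    #: they own proportionally more of the remaining TFs), which balances
    #: per-TF candidate pool sizes across true and decoy TFs.
    tfs_per_module: int | None = None
    #: background pseudo-modules mirroring the foreground scheme;
    #: None = n_modules
    n_bg_modules: int | None = None
    #: decoy binding degree of background genes; None = binding_degree + 1,
    #: so decoy candidate pools are at least as large as true ones and the
    #: sampling-frequency scores of unregulated genes stay conservative
    bg_binding_degree: int | None = None
    #: where injected false positives may land: "all" rows (spurious motif
    #: matches hit unregulated genes too) or "foreground" rows only
    fp_rows: str = "all"
    #: distribution of nonzero regulation strengths: "uniform" draws
    #: activation strengths U(0.5, 1.5); "normal" draws N(0, 1)
    strength_dist: str = "uniform"
    seed: int | None = None

    @property
    def resolved_n_bg_modules(self) -> int:
        return self.n_modules if self.n_bg_modules is None \
            else self.n_bg_modules

    def resolved_tfs_per_module(self) -> int:
        if self.tfs_per_module is not None:
            return self.tfs_per_module
        # TF share proportional to the gene count behind each group
        per_gene = self.n_tfs / (self.n_foreground + self.n_background)
        fg_module_genes = self.n_foreground // self.n_modules
        return max(int(round(per_gene * fg_module_genes)),
                   self.binding_degree)

    def resolved_bg_share(self) -> int:
        """TFs owned by each background pseudo-module."""
        rest = self.n_tfs - self.n_modules * self.resolved_tfs_per_module()
        return rest // self.resolved_n_bg_modules

    def resolved_bg_degree(self) -> int:
        if self.bg_binding_degree is not None:
            return self.bg_binding_degree
        return min(self.binding_degree + 1, self.resolved_bg_share())

    def validate(self) -> None:
        for name in ("n_foreground", "n_background", "n_tfs", "n_samples",
                     "n_modules", "binding_degree"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_modules > self.n_foreground:
            raise ValueError("n_modules cannot exceed n_foreground")
        if self.fp_ratio < 0:
            raise ValueError("fp_ratio must be >= 0")
        if self.strength_dist not in ("uniform", "normal"):
            raise ValueError(f"unknown strength_dist '{self.strength_dist}'")
        if self.resolved_n_bg_modules <= 0:
            raise ValueError("n_bg_modules must be > 0")
        if self.n_foreground % self.n_modules != 0:
            raise ValueError(
                f"n_foreground={self.n_foreground} not divisible by "
                f"n_modules={self.n_modules}: module sizes must be integral")
        if self.n_background % self.resolved_n_bg_modules != 0:
            raise ValueError(
                f"n_background={self.n_background} not divisible by "
                f"n_bg_modules={self.resolved_n_bg_modules}: pseudo-module "
                "sizes must be integral")
        tpm = self.resolved_tfs_per_module()
        if tpm < self.binding_degree:
            raise ValueError(
                f"tfs_per_module={tpm} too small for binding_degree="
                f"{self.binding_degree}")
        if self.resolved_bg_share() < 1:
            raise ValueError(
                f"n_tfs={self.n_tfs} cannot host {self.n_modules} foreground "
                f"TF groups of {tpm} plus background groups")
        if self.resolved_bg_degree() > self.resolved_bg_share():
            raise ValueError(
                f"bg_binding_degree={self.resolved_bg_degree()} exceeds the "
                f"background TF share {self.resolved_bg_share()}")

    @property
    def n_genes(self) -> int:
        return self.n_foreground + self.n_background

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{j:03d}" for j in range(self.n_tfs)]


@dataclasses.dataclass
class SimulationTruth:
    """Ground truth underlying one simulated dataset.

    ``true_binding`` is the full pre-false-positive binding matrix, including
    the background genes' decoy motif pattern; ``regulation_strengths`` (A)
    is nonzero only on foreground rows, so its support equals the foreground
    part of ``true_binding`` — background expression never passes through the
    linear model.
    """

    true_binding: np.ndarray            # (N, M) binary, pre-FP
    foreground_mask: np.ndarray         # (N,) bool
    module_labels: np.ndarray           # (N,) int; -1 for background genes
    active_tfs_per_module: list[np.ndarray]
    regulation_strengths: np.ndarray | None = None   # A, (N, M)
    tf_activities: np.ndarray | None = None          # S, (M, K)
    noise: np.ndarray | None = None                  # Gamma, (N, K)

    def partition_labels(self) -> np.ndarray:
        """Ground-truth partition for clustering evaluation.

        Foreground modules are distinct classes; all background genes form
        one class (labelled n_modules).
        """
        labels = self.module_labels.copy()
        labels[~self.foreground_mask] = int(self.module_labels.max()) + 1
        return labels


@dataclasses.dataclass
class SimulationData:
    """A complete simulated dataset: expression, observed binding, truth."""

    expression: pd.DataFrame   # genes x samples
    binding: pd.DataFrame      # genes x TFs, 0/1, after FP injection
    truth: SimulationTruth
    config: SimulationConfig


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_binding(
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate the modular binary binding matrix and partial ground truth.

    Foreground genes are split into ``n_modules`` equal modules, each
    owning ``tfs_per_module`` TFs; background genes are split into
    pseudo-modules mirroring the foreground scheme on the remaining TFs, so
    the decoy binding has the same modular shape as the true one and every
    TF has targets.  Foreground genes bind exactly ``binding_degree`` of
    their module's TFs; background genes bind ``bg_binding_degree`` of
    their pseudo-module's TFs (default binding_degree + 1, keeping decoy
    candidate pools at least as large as true ones).  The returned matrix
    is the pre-false-positive truth.
    """
    config.validate()
    rng = _as_rng(rng)
    N, M = config.n_genes, config.n_tfs
    tpm = config.resolved_tfs_per_module()
    n_bg_mod = config.resolved_n_bg_modules
    bg_share = config.resolved_bg_share()
    bg_degree = config.resolved_bg_degree()

    tf_perm = rng.permutation(M)
    tf_groups = [tf_perm[g * tpm:(g + 1) * tpm]
                 for g in range(config.n_modules)]
    pos = config.n_modules * tpm
    for _ in range(n_bg_mod):
        tf_groups.append(tf_perm[pos:pos + bg_share])
        pos += bg_share

    W = np.zeros((N, M), dtype=np.int8)
    module_labels = np.full(N, -1, dtype=int)
    fg_per_mod = config.n_foreground // config.n_modules
    bg_per_mod = config.n_background // n_bg_mod

    for i in range(N):
        if i < config.n_foreground:
            grp = i // fg_per_mod
            module_labels[i] = grp
            degree = config.binding_degree
        else:
            grp = config.n_modules + (i - config.n_foreground) // bg_per_mod
            degree = bg_degree
        tfs = rng.choice(tf_groups[grp], size=degree, replace=False)
        W[i, tfs] = 1

    foreground_mask = np.zeros(N, dtype=bool)
    foreground_mask[:config.n_foreground] = True
    truth = SimulationTruth(
        true_binding=W.copy(),
        foreground_mask=foreground_mask,
        module_labels=module_labels,
        active_tfs_per_module=[np.sort(tf_groups[m])
                               for m in range(config.n_modules)],
    )
    binding = pd.DataFrame(W, index=config.gene_ids, columns=config.tf_ids)
    return binding, truth


def inject_false_positives(
    W: pd.DataFrame,
    truth: SimulationTruth,
    fp_ratio: float,
    rng: np.random.Generator | int | None = None,
    rows: str = "all",
) -> pd.DataFrame:
    """Add spurious binding connections to the motif matrix.

    The number injected is round(fp_ratio * TP) where TP counts the
    true-positive entries within foreground-gene rows (the ratio's
    reference).  Placements are uniform over currently-zero cells of every
    row (``rows="all"``, default): spurious motif matches hit regulated and
    unregulated genes alike, which is what lets unregulated genes be
    falsely clustered with true targets.  ``rows="foreground"`` restricts
    placement to foreground rows.  Existing connections are never removed.
    """
    if fp_ratio < 0:
        raise ValueError("fp_ratio must be >= 0")
    if rows not in ("all", "foreground"):
        raise ValueError(f"unknown rows mode '{rows}'")
    values = W.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("binding matrix must be binary")
    rng = _as_rng(rng)
    out = values.copy()
    fg = truth.foreground_mask
    tp = int(values[fg].sum())
    n_fp = int(round(fp_ratio * tp))
    if n_fp == 0:
        return W.copy()
    rows_idx = np.arange(out.shape[0]) if rows == "all" else np.flatnonzero(fg)
    zr, zc = np.nonzero(out[rows_idx] == 0)
    if n_fp > zr.size:
        raise ValueError(
            f"cannot place {n_fp} false positives: only {zr.size} empty "
            "cells available")
    pick = rng.choice(zr.size, size=n_fp, replace=False)
    out[rows_idx[zr[pick]], zc[pick]] = 1
    return pd.DataFrame(out, index=W.index, columns=W.columns)


def generate_expression(
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Synthesize log-scale expression X = A S + Gamma.

    TF activities S are iid standard normal.  Regulation strengths A are
    drawn on the support of the foreground true binding: by default
    activation strengths U(0.5, 1.5), so co-regulated genes share expression
    patterns; ``strength_dist="normal"`` draws signed N(0, 1) strengths
    instead.  Noise is
    iid Gaussian rescaled so the empirical SNR of the foreground block equals
    ``config.snr_db`` (use ``snr_db=inf`` for noise-free data).  Background
    rows are standard normal rescaled so that the empirical variance of the
    background block equals that of the foreground block.

    Fills in ``truth.regulation_strengths``, ``tf_activities`` and ``noise``.
    """
    rng = _as_rng(rng)
    N, M, K = config.n_genes, config.n_tfs, config.n_samples
    fg = truth.foreground_mask

    S = rng.standard_normal((M, K))
    A = np.zeros((N, M))
    support = (truth.true_binding == 1) & fg[:, None]
    n_nz = int(support.sum())
    if config.strength_dist == "uniform":
        A[support] = rng.uniform(0.5, 1.5, n_nz)
    else:
        A[support] = rng.standard_normal(n_nz)

    signal = A @ S
    sig_var = float(signal[fg].var())
    if sig_var == 0:
        raise ValueError("zero-variance signal: cannot set an SNR")

    X = np.empty((N, K))
    noise = np.zeros((N, K))
    if np.isinf(config.snr_db):
        X[fg] = signal[fg]
    else:
        raw = rng.standard_normal((int(fg.sum()), K))
        target_var = sig_var / (10.0 ** (config.snr_db / 10.0))
        raw *= np.sqrt(target_var / raw.var())
        noise[fg] = raw
        X[fg] = signal[fg] + raw

    bg_raw = rng.standard_normal((int((~fg).sum()), K))
    # amplitude matched so background and foreground rows have equal variance
    bg_raw *= np.sqrt(X[fg].var() / bg_raw.var())
    X[~fg] = bg_raw

    truth.regulation_strengths = A
    truth.tf_activities = S
    truth.noise = noise
    return pd.DataFrame(X, index=config.gene_ids,
                        columns=[f"S{k:03d}" for k in range(K)])


def simulate_dataset(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulationData:
    """Run the full generator: binding, false positives, expression."""
    config = config or SimulationConfig()
    if rng is None:
        rng = config.seed
    rng = _as_rng(rng)
    W0, truth = generate_binding(config, rng)
    W = inject_false_positives(W0, truth, config.fp_ratio, rng,
                               rows=config.fp_rows)
    X = generate_expression(truth, config, rng)
    return SimulationData(expression=X, binding=W, truth=truth, config=config)


def write_dataset(data: SimulationData, out_dir: str | Path) -> None:
    """Write expression/binding TSVs and a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.expression.to_csv(out / "expression.tsv", sep="\t")
    data.binding.to_csv(out / "binding.tsv", sep="\t")
    truth = data.truth
    sidecar = {
        "config": dataclasses.asdict(data.config),
        "foreground_mask": truth.foreground_mask.astype(int).tolist(),
        "module_labels": truth.module_labels.tolist(),
        "active_tfs_per_module": [a.tolist()
                                  for a in truth.active_tfs_per_module],
        "true_binding": truth.true_binding.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(sidecar))
    logger.info("wrote simulated dataset to %s", out)
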