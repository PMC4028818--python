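# mapc-gibbsos

Two-step identification of modular gene regulatory networks from gene
expression and motif-binding data.

Transcription factors (TFs) regulate genes in co-operating groups, but the
two genome-scale data sources that could reveal this structure are both
unreliable: microarray/RNA expression is noisy, and promoter motif
scanning produces many false-positive TF–gene connections.  This package
implements an integrated approach for users who have an expression matrix
(genes × samples) and a binary candidate binding matrix (genes × TFs) and
want the modular regulatory network behind them:

1. **mAPC** — motif-guided affinity propagation clustering.  Genes are
   clustered with the blended similarity
   `s(i,j) = −(1−λ)‖x_i−x_j‖² + λ·Σ_m w(i,m)w(j,m)`,
   so co-expression and shared motif evidence jointly define co-regulated
   modules; each cluster's TFs are found by hypergeometric enrichment of
   its members among each TF's candidate targets.
2. **GibbsOS** — a Gibbs sampler on the outlier-sum statistic.  Under the
   bipartite model `X = A·S + Γ`, one true target per TF ("seed" genes)
   spans the TF-activity space, so other true targets regress on the seed
   expression with significant coefficients.  The outlier sum
   `OS(θ_j) = Σ_{k≠i} |t_jk|·1{|t_jk| ≥ t_{α/2,K−M−1}}` scores each seed
   choice, and sampling seeds from the normalized OS conditionals yields
   per-gene frequencies — the probability of being a genuine target —
   which prune the false-positive connections inside each cluster.

A bundled simulator generates benchmark datasets with known ground truth
(modular binding, Gaussian TF activities, log-linear expression at a
chosen signal-to-noise ratio, false positives injected at a chosen ratio)
and a study runner reproduces the full evaluation grid (clustering ARI,
TF-identification AUC, target-gene AUC against a pool-wide GibbsOS
baseline).  See `docs/methods.md` for the model, parameter meanings and
design choices.

## Worked example

```python
import numpy as np
from mapc_gibbsos import (SimulationConfig, simulate_dataset,
                          PipelineConfig, run_two_step,
                          adjusted_rand_index, roc_auc)
from mapc_gibbsos.evaluate import match_clusters_to_modules
from mapc_gibbsos.gibbsos import gene_level_scores

data = simulate_dataset(SimulationConfig(snr_db=5.0, fp_ratio=1.0, seed=11))
assignment, enrichment, scores = run_two_step(
    data.expression, data.binding, PipelineConfig(preference="low"), rng=11)

print(f"{assignment.n_clusters} clusters, sizes "
      f"{np.bincount(assignment.labels).tolist()}")
print("ARI vs ground truth: "
      f"{adjusted_rand_index(assignment.labels, data.truth.partition_labels()):.3f}")
for m, cid in match_clusters_to_modules(assignment, data.truth).items():
    members = assignment.members(cid)
    s = gene_level_scores(scores[scores.cluster_id == cid], members)
    fg = data.truth.foreground_mask[members]
    best = enrichment[enrichment.cluster_id == cid].nsmallest(1, "p_value")
    print(f"module {m} -> cluster {cid}: {len(members)} genes, "
          f"top TF {best.tf_id.iloc[0]} (p={best.p_value.iloc[0]:.2e}), "
          f"target-gene AUC {roc_auc(s, fg):.3f}")
```

prints

```
5 clusters, sizes [47, 60, 70, 59, 64]
ARI vs ground truth: 0.268
module 0 -> cluster 0: 47 genes, top TF TF074 (p=1.16e-15), target-gene AUC 0.956
module 1 -> cluster 1: 60 genes, top TF TF004 (p=3.71e-15), target-gene AUC 0.652
```

Read: at 5 dB SNR with as many false as true binding connections, the
combined similarity recovers both foreground modules as clean clusters
(the remaining clusters hold unregulated background genes); each module's
most-enriched TF is overwhelmingly significant; and ranking cluster genes
by their Gibbs sampling frequency separates true targets from
falsely-connected members (AUC 0.96 / 0.65 for the two modules here —
cluster composition makes the second module harder in this draw).

The same stages are available from the shell:

```sh
mapc-gibbsos simulate --snr-db 5 --fp-ratio 1.0 --seed 11 --out sim/
mapc-gibbsos cluster --expr sim/expression.tsv --binding sim/binding.tsv \
    --preference low --out clusters.tsv
mapc-gibbsos enrich --clusters clusters.tsv --binding sim/binding.tsv \
    --out enrichment.tsv
mapc-gibbsos sample --expr sim/expression.tsv --binding sim/binding.tsv \
    --clusters clusters.tsv --enrichment enrichment.tsv --out scores.tsv
```

plus `run` (end-to-end, with optional two-group t-test preselection),
`bootstrap` (TF confidence over resamples) and `evaluate` (the full
simulation study).

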