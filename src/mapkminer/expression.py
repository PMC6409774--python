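"""Expression analysis downstream of quantification: log2 fold changes
versus within-tissue controls, row standardization, k-means and
correlation/average-linkage hierarchical clustering, heatmap clipping.

The design emulated is pooled (replicate-free) libraries over two tissues
(leaf, root) x four conditions (control, SA, NaCl, Peg), so no
count-model inference is attempted: log2FC with a pseudocount is the
effect measure and thresholds on it are reporting filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

TISSUES = ("leaf", "root")
TREATMENTS = ("control", "SA", "NaCl", "Peg")


class DesignError(ValueError):
    pass


@dataclass
class QuantTable:
    """Genes x samples TPM matrix with (tissue, treatment) sample metadata."""

    tpm: pd.DataFrame                        # genes x samples
    samples: pd.DataFrame                    # index sample, cols tissue/treatment

    def __post_init__(self) -> None:
        missing = set(self.tpm.columns) - set(self.samples.index)
        if missing:
            raise DesignError(f"samples without metadata: {sorted(missing)}")
        if not np.isfinite(self.tpm.to_numpy()).all():
            raise DesignError("TPM values must be finite")
        if (self.tpm.to_numpy() < 0).any():
            raise DesignError("TPM values must be nonnegative")
        for tissue in self.samples["tissue"].unique():
            ctrl = self.control_sample(tissue, required=False)
            if ctrl is None:
                raise DesignError(f"tissue {tissue!r} has no control sample")

    def control_sample(self, tissue: str, required: bool = True) -> str | None:
        sel = self.samples[(self.samples["tissue"] == tissue)
                           & (self.samples["treatment"] == "control")]
        if len(sel) > 1:
            raise DesignError(f"tissue {tissue!r} has multiple controls")
        if sel.empty:
            if required:
                raise DesignError(f"tissue {tissue!r} has no control sample")
            return None
        return sel.index[0]

    @classmethod
    def from_tsv(cls, tpm_path, design_path) -> "QuantTable":
        tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
        samples = pd.read_csv(design_path, sep="\t", index_col=0)
        return cls(tpm=tpm, samples=samples)

    def to_tsv(self, tpm_path, design_path) -> None:
        self.tpm.to_csv(tpm_path, sep="\t")
        self.samples.to_csv(design_path, sep="\t")


def log2fc(q: QuantTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene log2((TPM_trt + pc) / (TPM_ctrl + pc)) against the matched
    within-tissue control; columns are "tissue:treatment" contrasts.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = {}
    for tissue in self_order(q.samples["tissue"]):
        ctrl = q.control_sample(tissue)
        base = q.tpm[ctrl] + pseudocount
        for sample, meta in q.samples.iterrows():
            if meta["tissue"] != tissue or meta["treatment"] == "control":
                continue
            out[f"{tissue}:{meta['treatment']}"] = np.log2(
                (q.tpm[sample] + pseudocount) / base)
    return pd.DataFrame(out, index=q.tpm.index)


def self_order(series: pd.Series) -> list[str]:
    seen: list[str] = []
    for v in series:
        if v not in seen:
            seen.append(v)
    return seen


def standardize(m: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, list[str]]:
    """Center each gene row to mean 0 and scale to unit standard deviation
    (sample SD by default).  Zero-variance rows are dropped and returned as
    a warning list.
    """
    if m.shape[1] < 2:
        raise ValueError("standardization needs >= 2 columns")
    vals = m.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    keep = sd[:, 0] > 0
    dropped = list(m.index[~keep])
    z = (vals[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=m.index[keep], columns=m.columns), dropped


@dataclass
class ClusterResult:
    method: str                              # kmeans | hclust
    k: int
    labels: pd.Series | None = None          # gene -> 1..k
    merge_heights: np.ndarray | None = None
    linkage_matrix: np.ndarray | None = None
    wcss: float | None = None
    seed: int | None = None


def _kmeans_once(x: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int = 300) -> tuple[np.ndarray, float]:
    n = x.shape[0]
    # k-means++ seeding
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(((x[:, None, :] - np.array(centers)[None]) ** 2).sum(-1), axis=1)
        if d2.sum() <= 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / d2.sum())])
    centers = np.array(centers)
    prev_wcss = np.inf
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None]) ** 2).sum(-1)
        labels = d2.argmin(axis=1)
        wcss = float(d2[np.arange(n), labels].sum())
        # Lloyd iterations can only decrease the objective
        assert wcss <= prev_wcss + 1e-9, "k-means objective increased"
        if prev_wcss - wcss < 1e-12:
            break
        prev_wcss = wcss
        for c in range(k):
            mask = labels == c
            if mask.any():
                centers[c] = x[mask].mean(axis=0)
            else:                             # re-seed an empty cluster
                centers[c] = x[rng.integers(n)]
    return labels, wcss


def kmeans_cluster(m: pd.DataFrame, k: int = 4, seed: int = 0,
                   restarts: int = 50) -> ClusterResult:
    """Best of ``restarts`` seeded kmeans++/Lloyd runs by within-cluster
    sum of squares; deterministic under a fixed seed.
    """
    if k < 1 or k > m.shape[0]:
        raise ValueError(f"k={k} incompatible with {m.shape[0]} rows")
    x = m.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best_labels, best_wcss = None, np.inf
    for _ in range(restarts):
        labels, wcss = _kmeans_once(x, k, rng)
        if wcss < best_wcss - 1e-12:
            best_labels, best_wcss = labels, wcss
    return ClusterResult(method="kmeans", k=k,
                         labels=pd.Series(best_labels + 1, index=m.index),
                         wcss=best_wcss, seed=seed)


def hclust_correlation_average(m: pd.DataFrame, k: int = 4) -> ClusterResult:
    """Agglomerative average linkage on 1 - Pearson correlation between
    gene rows.  Zero-variance rows must be removed beforehand.
    """
    if m.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    vals = m.to_numpy(dtype=float)
    zero_var = [str(g) for g, v in zip(m.index, vals) if np.std(v) == 0]
    if zero_var:
        raise ValueError(f"zero-variance rows must be removed first: {zero_var}")
    d = pdist(vals, metric="correlation")
    z = linkage(d, method="average")
    heights = z[:, 2]
    if np.any(np.diff(heights) < -1e-9):
        raise RuntimeError("average-linkage merge heights decreased "
                           f"(heights={heights!r})")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(method="hclust", k=k,
                         labels=pd.Series(labels, index=m.index),
                         merge_heights=heights, linkage_matrix=z)


def heatmap_matrix(m: pd.DataFrame, z_cutoff: float = 4.0) -> pd.DataFrame:
    """Clip a standardized matrix to [-z_cutoff, +z_cutoff] for display."""
    return m.clip(lower=-z_cutoff, upper=z_cutoff)


def regulated(de: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Reporting filter: genes x contrasts boolean mask |log2FC| > threshold."""
    return de.abs() > threshold
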