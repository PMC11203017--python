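"""K-means clustering of the RSCU matrix over codon columns.

The genes x codons RSCU matrix is z-scaled per gene (row); the 59 informative
codons are then clustered as objects, each described by its vector of scaled
per-gene values.  K is chosen by mean silhouette, with the inertia (elbow)
curve exported for inspection, and cluster quality is scored against the
partition of codons by their third base.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

logger = logging.getLogger(__name__)


@dataclass
class RSCUMatrix:
    """Genes (rows) x codons (columns) RSCU values, optionally row-scaled."""

    values: pd.DataFrame
    scaled: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def codons(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusteringResult:
    k: int
    labels: dict[str, int]
    inertia_by_k: dict[int, float]
    silhouette_by_k: dict[int, float]
    chosen_k: int
    purity: float
    ari: float
    seed: int
    flags: list[str] = field(default_factory=list)


def impute_missing(matrix: RSCUMatrix) -> RSCUMatrix:
    """Replace missing RSCU entries (unobserved amino acids) by column means."""
    vals = matrix.values.copy()
    vals = vals.fillna(vals.mean(axis=0))
    return RSCUMatrix(values=vals, scaled=matrix.scaled)


def scale_rows(matrix: RSCUMatrix) -> RSCUMatrix:
    """Z-scale each row to mean 0 and (population) SD 1.

    Zero-variance rows are dropped with a warning; double scaling is an error.
    """
    if matrix.scaled:
        raise ValueError("matrix is already row-scaled")
    if matrix.values.shape[1] < 2:
        raise ValueError("need at least 2 codon columns to scale")
    if matrix.values.isna().any().any():
        raise ValueError("impute missing entries before scaling")
    vals = matrix.values
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance rows before scaling", n_dropped)
    vals = vals.loc[keep]
    scaled = vals.sub(vals.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return RSCUMatrix(values=scaled, scaled=True)


def prepare_matrix(raw: pd.DataFrame) -> RSCUMatrix:
    """Impute and row-scale a raw genes x codons RSCU table."""
    return scale_rows(impute_missing(RSCUMatrix(values=raw)))


def third_base_concordance(labels: Mapping[str, int]) -> tuple[float, float]:
    """Purity and adjusted Rand index of codon clusters vs third-base identity."""
    codons = sorted(labels)
    third = [c[2] for c in codons]
    assigned = [labels[c] for c in codons]
    purity = 0
    for cluster in set(assigned):
        bases = [t for t, a in zip(third, assigned) if a == cluster]
        purity += max(bases.count(b) for b in set(bases))
    ari = float(adjusted_rand_score(third, assigned))
    # ARI of the trivial one-cluster partition is defined as 0
    if len(set(assigned)) == 1 or len(set(third)) == 1:
        ari = 0.0
    return purity / len(codons), ari


def kmeans_scan(
    matrix: RSCUMatrix,
    k_range: Iterable[int] = range(2, 9),
    n_init: int = 25,
    seed: int = 0,
) -> ClusteringResult:
    """Cluster codon columns for each k; choose k by mean silhouette.

    Deterministic given the seed.  When the silhouette is undefined for every
    k (degenerate identical columns), the smallest k is chosen with a flag.
    """
    if not matrix.scaled:
        raise ValueError("kmeans_scan requires a row-scaled matrix")
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    X = matrix.values.to_numpy().T  # codons as objects
    n_obj = X.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 2 or ks[-1] > n_obj - 1:
        raise ValueError(f"k range must lie within [2, {n_obj - 1}]")

    inertia: dict[int, float] = {}
    silhouette: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    flags: list[str] = []
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        inertia[k] = float(km.inertia_)
        labels_by_k[k] = lab
        try:
            if len(set(lab)) < 2:
                raise ValueError("single cluster")
            sil = float(silhouette_score(X, lab))
            if not np.isfinite(sil):
                raise ValueError("non-finite silhouette")
            silhouette[k] = sil
        except ValueError:
            silhouette[k] = float("nan")

    finite = {k: s for k, s in silhouette.items() if np.isfinite(s)}
    if finite:
        best = max(finite.values())
        chosen_k = min(k for k, s in finite.items() if s == best)
    else:
        chosen_k = ks[0]
        flags.append("silhouette_undefined")
        logger.warning("silhouette undefined for all k; falling back to k=%d", chosen_k)

    labels = {c: int(l) for c, l in zip(matrix.codons, labels_by_k[chosen_k])}
    purity, ari = third_base_concordance(labels)
    return ClusteringResult(
        k=chosen_k,
        labels=labels,
        inertia_by_k=inertia,
        silhouette_by_k=silhouette,
        chosen_k=chosen_k,
        purity=purity,
        ari=ari,
        seed=seed,
        flags=flags,
    )


def write_cluster_outputs(result: ClusteringResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    labels = pd.DataFrame(
        [
            {"codon": c, "third_base": c[2], "cluster": lab}
            for c, lab in sorted(result.labels.items())
        ]
    )
    labels.to_csv(outdir / "cluster_labels.tsv", sep="\t", index=False)
    scan = pd.DataFrame(
        [
            {
                "k": k,
                "inertia": result.inertia_by_k[k],
                "silhouette": result.silhouette_by_k[k],
            }
            for k in sorted(result.inertia_by_k)
        ]
    )
    scan.to_csv(outdir / "cluster_scan.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        [
            {
                "chosen_k": result.chosen_k,
                "purity": result.purity,
                "ari": result.ari,
                "seed": result.seed,
                "flags": ";".join(result.flags),
            }
        ]
    )
    summary.to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)
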