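"""GO over-representation analysis (hypergeometric test, BH adjustment).

For a study set of n genes drawn from a background of N genes, a term
annotated to K background genes and observed in k study genes has
one-sided p = P[X >= k] for X ~ Hypergeometric(N, K, n).  P-values are
Benjamini-Hochberg adjusted across all tested terms; each term also gets a
rich factor (k / K) and an enrichment score (-log10 adjusted p).
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def bh_adjust(p_values: Sequence[float], method: str = "fdr_bh") -> list[float]:
    """Benjamini-Hochberg (default) or Bonferroni adjustment.

    Input order is preserved; all inputs must lie in (0, 1].
    """
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return []
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return list(multipletests(arr, method=method)[1])


def hypergeom_tail(k: int, n_bg: int, k_bg: int, n_study: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N=n_bg, K=k_bg, n=n_study)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, n_bg, k_bg, n_study))


def enrich(
    study: Iterable[str],
    background: Iterable[str],
    go_map: pd.DataFrame,
    min_term_size: int = 5,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Over-representation of GO terms in ``study`` against ``background``.

    ``go_map`` columns: gene_id, go_id and optionally go_class, go_name.
    Terms annotated to fewer than ``min_term_size`` background genes are not
    tested.  Results are sorted by adjusted p, then term id.
    """
    study = set(study)
    background = set(background)
    if not study:
        raise ValueError("empty study set")
    if not study <= background:
        extra = sorted(study - background)[:3]
        raise ValueError(f"study genes not in background: {extra}")
    if min_term_size < 1:
        raise ValueError("min_term_size must be >= 1")

    gm = go_map[go_map["gene_id"].isin(background)].drop_duplicates(
        subset=["gene_id", "go_id"]
    )
    n_bg = len(background)
    n_study = len(study)

    meta_cols = [c for c in ("go_class", "go_name") if c in gm.columns]
    meta = gm.drop_duplicates("go_id").set_index("go_id")[meta_cols] if meta_cols else None

    rows = []
    for go_id, sub in gm.groupby("go_id"):
        genes = set(sub["gene_id"])
        k_bg = len(genes)
        if k_bg < min_term_size:
            continue
        k = len(genes & study)
        p = hypergeom_tail(k, n_bg, k_bg, n_study)
        rows.append(
            {
                "go_id": go_id,
                "k": k,
                "K_bg": k_bg,
                "n": n_study,
                "N_bg": n_bg,
                "p": p,
                "rich_factor": k / k_bg,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["go_id", "go_class", "go_name", "k", "K_bg", "n", "N_bg",
                     "p", "p_adj", "rich_factor", "score"]
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"], method=method)
    df["score"] = -np.log10(df["p_adj"])
    if meta is not None:
        df = df.join(meta, on="go_id")
    else:
        df["go_class"], df["go_name"] = "", ""
    df = df.sort_values(["p_adj", "go_id"]).reset_index(drop=True)
    cols = ["go_id", "go_class", "go_name", "k", "K_bg", "n", "N_bg",
            "p", "p_adj", "rich_factor", "score"]
    return df[[c for c in cols if c in df.columns]]


def top_terms(results: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Dot/bar-plot data export for the n most significant terms."""
    cols = ["go_id", "go_class", "rich_factor", "score", "k"]
    return results.head(n)[[c for c in cols if c in results.columns]]


def write_enrichment(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
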