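"""Per-gene codon usage statistics: codon counts, RSCU, ENC, GC partition.

The effective number of codons (ENC) follows Wright's estimator: per amino
acid the codon homozygosity is F-hat = (n * sum(p_i^2) - 1) / (n - 1), class
means are taken over the 2-, 3-, 4- and 6-fold degenerate amino acids, and

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.

The expected ENC under pure compositional (no-selection) codon choice is the
classical null curve ENC* = 2 + s + 29 / (s^2 + (1-s)^2) with s = GC3.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .genetics import (
    CODON_TO_AA,
    DEGENERACY,
    DEGENERACY_CLASSES,
    INFORMATIVE_CODONS,
    SENSE_CODONS,
    SYN_FAMILIES,
)
from .seqio import CdsSet, CodingSequence


@dataclass
class CodonCountTable:
    gene_id: str
    counts: dict[str, int]
    n_codons: int


@dataclass
class CodonUsageProfile:
    gene_id: str
    n_codons: int
    rscu: dict[str, float]
    enc: float
    gc3s: float
    exp_enc: float
    enc_ratio: float
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3_gc12_ratio: float
    gc3_gc_ratio: float
    f_hat_by_class: dict[int, float]
    flags: list[str] = field(default_factory=list)


def count_codons(cds: CodingSequence) -> CodonCountTable:
    """Count in-frame sense codons; codons containing N are skipped."""
    if not cds.valid:
        raise ValueError(f"cannot count codons of invalid CDS {cds.id!r}")
    counts: dict[str, int] = {}
    n = 0
    for codon in cds.codons():
        if "N" in codon:
            continue
        counts[codon] = counts.get(codon, 0) + 1
        n += 1
    return CodonCountTable(gene_id=cds.id, counts=counts, n_codons=n)


def rscu(counts: CodonCountTable) -> dict[str, float]:
    """Relative synonymous codon usage for every sense codon.

    RSCU of codon j in a family of degeneracy d with total count m is
    count_j / (m / d).  Codons of amino acids never observed in the gene are
    reported as NaN (missing), not zero.
    """
    if counts.n_codons <= 0:
        raise ValueError(f"gene {counts.gene_id!r}: no countable codons")
    out: dict[str, float] = {}
    for aa, codons in SYN_FAMILIES.items():
        m = sum(counts.counts.get(c, 0) for c in codons)
        d = DEGENERACY[aa]
        for c in codons:
            out[c] = counts.counts.get(c, 0) * d / m if m > 0 else math.nan
    return out


def _f_hat(family_counts: list[int]) -> Optional[float]:
    """Wright's codon homozygosity for one amino acid; None when n < 2."""
    n = sum(family_counts)
    if n < 2:
        return None
    sum_p2 = sum((c / n) ** 2 for c in family_counts)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCountTable) -> tuple[float, dict[int, float], list[str]]:
    """Wright's effective number of codons.

    Returns (enc, class mean F-hats, flags).  Amino acids observed fewer than
    twice are excluded from their class mean.  An empty or zero 3-fold class
    (Ile) is imputed as (F2+F4)/2; if any other class mean is missing or
    non-positive the result is NaN with an ``enc_undefined`` flag.  The value
    is clipped to [20, 61], flagged when clipping occurred.
    """
    flags: list[str] = []
    class_f: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            f = _f_hat([counts.counts.get(c, 0) for c in SYN_FAMILIES[aa]])
            if f is not None:
                fs.append(f)
        if fs:
            class_f[k] = float(np.mean(fs))

    if class_f.get(3) is None or class_f.get(3, 0.0) <= 0.0:
        if 2 in class_f and 4 in class_f:
            class_f[3] = (class_f[2] + class_f[4]) / 2.0
            flags.append("class_imputed")

    if any(k not in class_f or class_f[k] <= 0.0 for k in (2, 3, 4, 6)):
        flags.append("enc_undefined")
        return math.nan, class_f, flags

    value = 2.0 + 9.0 / class_f[2] + 1.0 / class_f[3] + 5.0 / class_f[4] + 3.0 / class_f[6]
    if value < 20.0 or value > 61.0:
        flags.append("enc_clipped")
        value = min(max(value, 20.0), 61.0)
    return value, class_f, flags


def expected_enc(gc3: float) -> float:
    """Null-curve expected ENC given third-position G+C content."""
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError(f"gc3 must be in [0, 1], got {gc3}")
    s = gc3
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def gc_partition(cds: CodingSequence) -> tuple[float, float, float, float, float]:
    """(gc, gc1, gc2, gc3, gc12): G+C fraction overall and per codon position.

    Only unambiguous bases count; a position with no unambiguous bases is NaN.
    """
    if not cds.valid:
        raise ValueError(f"gc_partition requires a valid CDS ({cds.id!r})")
    gc_counts = [0, 0, 0]
    tot_counts = [0, 0, 0]
    for i, base in enumerate(cds.seq):
        if base == "N":
            continue
        pos = i % 3
        tot_counts[pos] += 1
        if base in "GC":
            gc_counts[pos] += 1
    per_pos = [
        gc_counts[p] / tot_counts[p] if tot_counts[p] else math.nan for p in range(3)
    ]
    total = sum(tot_counts)
    gc = sum(gc_counts) / total if total else math.nan
    gc12 = (per_pos[0] + per_pos[1]) / 2.0
    return gc, per_pos[0], per_pos[1], per_pos[2], gc12


def gc3_synonymous(counts: CodonCountTable) -> float:
    """G+C fraction at synonymously variable third positions (GC3s).

    Codons of single-codon amino acids (Met, Trp) are excluded; this is the
    composition variable of the ENC-plot null curve.
    """
    gc = total = 0
    for codon, c in counts.counts.items():
        if DEGENERACY[CODON_TO_AA[codon]] < 2:
            continue
        total += c
        if codon[2] in "GC":
            gc += c
    return gc / total if total else math.nan


def profile(cds: CodingSequence, short_gene_codons: int = 100) -> CodonUsageProfile:
    """All codon-usage statistics for one valid CDS."""
    counts = count_codons(cds)
    rscu_map = rscu(counts)
    enc_value, class_f, flags = enc(counts)
    gc, gc1, gc2, gc3, gc12 = gc_partition(cds)
    gc3s = gc3_synonymous(counts)
    exp = expected_enc(gc3s) if not math.isnan(gc3s) else math.nan
    if counts.n_codons < short_gene_codons:
        flags = flags + ["short_gene"]
    return CodonUsageProfile(
        gene_id=cds.id,
        n_codons=counts.n_codons,
        rscu=rscu_map,
        enc=enc_value,
        gc3s=gc3s,
        exp_enc=exp,
        enc_ratio=enc_value / exp if exp and not math.isnan(enc_value) else math.nan,
        gc=gc,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=gc12,
        gc3_gc12_ratio=gc3 / gc12 if gc12 else math.nan,
        gc3_gc_ratio=gc3 / gc if gc else math.nan,
        f_hat_by_class=class_f,
        flags=flags,
    )


PROFILE_COLUMNS = [
    "gene_id",
    "n_codons",
    "enc",
    "gc3s",
    "exp_enc",
    "enc_ratio",
    "gc",
    "gc1",
    "gc2",
    "gc3",
    "gc12",
    "gc3_gc12_ratio",
    "gc3_gc_ratio",
    "flags",
]


def profile_set(cds_set: CdsSet, short_gene_codons: int = 100) -> pd.DataFrame:
    """One row of usage statistics per valid gene."""
    rows = []
    for cds in cds_set:
        if not cds.valid:
            continue
        p = profile(cds, short_gene_codons=short_gene_codons)
        rows.append(
            {
                **{c: getattr(p, c) for c in PROFILE_COLUMNS if c != "flags"},
                "flags": ";".join(p.flags),
            }
        )
    if not rows:
        raise ValueError("no valid genes to profile")
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def rscu_matrix(cds_set: CdsSet, include_single_codon: bool = False) -> pd.DataFrame:
    """Genes x codons RSCU matrix (59 informative codons by default).

    Unobserved amino acids yield NaN entries; imputation is left to the
    clustering stage.
    """
    codons = SENSE_CODONS if include_single_codon else INFORMATIVE_CODONS
    rows, ids = [], []
    for cds in cds_set:
        if not cds.valid:
            continue
        r = rscu(count_codons(cds))
        rows.append([r[c] for c in codons])
        ids.append(cds.id)
    if not rows:
        raise ValueError("no valid genes")
    return pd.DataFrame(rows, index=ids, columns=list(codons))


def histogram_export(
    values: Mapping[str, "pd.Series | np.ndarray"] | pd.DataFrame,
    path: str | Path,
    bins: int = 50,
) -> pd.DataFrame:
    """Export histograms (bin edges and counts) of one or more value columns."""
    if isinstance(values, pd.DataFrame):
        values = {c: values[c] for c in values.columns}
    frames = []
    for name, vals in values.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        counts, edges = np.histogram(arr, bins=bins)
        frames.append(
            pd.DataFrame(
                {
                    "variable": name,
                    "bin_left": edges[:-1],
                    "bin_right": edges[1:],
                    "count": counts,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False)
    return out
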