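"""Nei-Gojobori (NG86) dN/dS estimation and selection-class labelling.

Site counting: each of a codon's nine single-base neighbours contributes 1/3
of a site, synonymous or nonsynonymous by whether the encoded amino acid
changes; changes that create a stop codon are excluded entirely, so such
positions contribute fractionally less than one site.

Difference counting: codons differing at k positions are compared by
averaging the synonymous / nonsynonymous step counts over all k! orderings
of single-base steps, discarding any pathway that passes through a stop
codon.

Distances are Jukes-Cantor corrected, d = -(3/4) ln(1 - (4/3) p), and
omega = dN/dS.  Pairs are labelled ultra-conserved (omega < 0.001),
purifying (omega < 1), neutral (|omega - 1| <= epsilon) or positive
(omega > 1 + epsilon).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .genetics import BASES, CODON_TO_AA, STOP_CODONS
from .homology import AlignedPair, PairSet

ULTRA_THRESHOLD = 0.001
NEUTRAL_EPSILON = 0.05


@dataclass
class SubstitutionEstimate:
    id_a: str
    id_b: str
    n_sites: float
    s_sites: float
    n_diff: float
    s_diff: float
    pn: float
    ps: float
    dn: float
    ds: float
    omega: float
    status: str  # ok | ds_zero | saturated | no_sites
    n_codon_columns: int = 0


def _check_sense(codon: str) -> None:
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} not allowed")
    if codon not in CODON_TO_AA:
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")


@lru_cache(maxsize=None)
def count_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one sense codon."""
    _check_sense(codon)
    aa = CODON_TO_AA[codon]
    s = n = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            if CODON_TO_AA[mutant] == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


@lru_cache(maxsize=None)
def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    Pathways through stop codons are excluded; if every pathway is excluded
    both counts are 0 (callers should then skip the column).
    """
    _check_sense(codon_a)
    _check_sense(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    s_total = n_total = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        current = codon_a
        s = n = 0.0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                s += 1.0
            else:
                n += 1.0
            current = nxt
        if ok:
            s_total += s
            n_total += n
            n_paths += 1
    if n_paths == 0:
        return 0.0, 0.0
    return s_total / n_paths, n_total / n_paths


def jukes_cantor(p: float) -> float:
    """JC-corrected distance; NaN when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _codon_columns(pair: AlignedPair) -> Iterable[tuple[str, str]]:
    ca, cb = pair.codon_alignment
    for i in range(0, len(ca), 3):
        a, b = ca[i : i + 3], cb[i : i + 3]
        if "-" in a or "-" in b or "N" in a or "N" in b:
            continue
        if a in STOP_CODONS or b in STOP_CODONS:
            continue
        yield a, b


def estimate_dnds(pair: AlignedPair) -> SubstitutionEstimate:
    """NG86 dN, dS and omega over the ungapped, unambiguous codon columns.

    Sites are averaged between the two sequences.  Codon columns whose every
    substitution pathway crosses a stop codon contribute nothing.
    """
    sa = na = sb = nb = 0.0
    sd = nd = 0.0
    n_cols = 0
    for a, b in _codon_columns(pair):
        ds_col = count_differences(a, b)
        if a != b and ds_col == (0.0, 0.0):
            continue  # all pathways blocked by stops
        s1, n1 = count_sites(a)
        s2, n2 = count_sites(b)
        sa += s1
        na += n1
        sb += s2
        nb += n2
        sd += ds_col[0]
        nd += ds_col[1]
        n_cols += 1

    if n_cols == 0:
        return SubstitutionEstimate(
            pair.id_a, pair.id_b, math.nan, math.nan, math.nan, math.nan,
            math.nan, math.nan, math.nan, math.nan, math.nan, "no_sites", 0,
        )
    s_sites = (sa + sb) / 2.0
    n_sites = (na + nb) / 2.0
    pn = nd / n_sites if n_sites > 0 else math.nan
    ps = sd / s_sites if s_sites > 0 else math.nan
    dn = jukes_cantor(pn) if not math.isnan(pn) else math.nan
    ds = jukes_cantor(ps) if not math.isnan(ps) else math.nan

    if (not math.isnan(pn) and pn >= 0.75) or (not math.isnan(ps) and ps >= 0.75):
        status, omega = "saturated", math.nan
    elif math.isnan(ds) or ds == 0.0:
        status, omega = "ds_zero", math.nan
    else:
        status, omega = "ok", dn / ds
    return SubstitutionEstimate(
        pair.id_a, pair.id_b, n_sites, s_sites, nd, sd, pn, ps, dn, ds,
        omega, status, n_cols,
    )


def estimate_pairset(pair_set: PairSet, comparison: str = "") -> pd.DataFrame:
    rows = []
    for p in pair_set.pairs:
        e = estimate_dnds(p)
        rows.append(
            {
                "id_a": e.id_a,
                "id_b": e.id_b,
                "comparison": comparison,
                "n_sites": e.n_sites,
                "s_sites": e.s_sites,
                "n_diff": e.n_diff,
                "s_diff": e.s_diff,
                "dn": e.dn,
                "ds": e.ds,
                "omega": e.omega,
                "status": e.status,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id_a", "id_b", "comparison", "n_sites", "s_sites",
            "n_diff", "s_diff", "dn", "ds", "omega", "status",
        ],
    )


def classify(
    estimates: pd.DataFrame,
    ultra_threshold: float = ULTRA_THRESHOLD,
    epsilon: float = NEUTRAL_EPSILON,
) -> pd.DataFrame:
    """Attach a selection-class label to each pair estimate.

    dn = 0 with ds > 0 is treated as omega = 0 (ultra-conserved); a pair with
    any non-ok status is labelled undefined.
    """
    out = estimates.copy()
    labels = []
    for row in out.itertuples(index=False):
        omega = row.omega
        if row.status != "ok":
            # ds_zero (incl. dn = ds = 0), saturated, no_sites
            labels.append("undefined")
            continue
        if row.dn == 0.0 and row.ds > 0.0:
            omega = 0.0
        # bounds are compared directly against 1 +/- epsilon (not via
        # abs(omega - 1)) so values equal to a bound classify consistently
        if omega < ultra_threshold:
            labels.append("ultra_conserved")
        elif omega > 1.0 + epsilon:
            labels.append("positive")
        elif omega >= 1.0 - epsilon:
            labels.append("neutral")
        else:
            labels.append("purifying")
    out["class"] = labels
    return out


def positive_gene_union(
    classified_by_comparison: dict[str, pd.DataFrame],
    focal_column: str = "id_a",
) -> set[str]:
    """Focal genes in at least one positively selected pair across comparisons."""
    genes: set[str] = set()
    for df in classified_by_comparison.values():
        pos = df[df["class"] == "positive"]
        genes.update(pos[focal_column].tolist())
    return genes


def gene_set_by_class(
    classified: pd.DataFrame, label: str, focal_column: str = "id_a"
) -> set[str]:
    return set(classified.loc[classified["class"] == label, focal_column])


def write_estimates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
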