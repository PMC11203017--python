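"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: translation goes through
Bio.Seq, tail probabilities through exact rational arithmetic, and every
quantity is computed directly from its definition.
"""
from __future__ import annotations

from fractions import Fraction
from itertools import permutations
from math import comb

from Bio.Seq import Seq

_BASES = "ACGT"


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def enc_oracle(counts: dict[str, int]) -> float:
    """Wright's ENC computed directly from raw codon counts."""
    by_aa: dict[str, dict[str, int]] = {}
    family_size: dict[str, set[str]] = {}
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                codon = b1 + b2 + b3
                aa = _translate(codon)
                if aa == "*":
                    continue
                family_size.setdefault(aa, set()).add(codon)
                if codon in counts and counts[codon] > 0:
                    by_aa.setdefault(aa, {})[codon] = counts[codon]

    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in family_size.items():
        size = len(fam)
        if size == 1:
            continue
        obs = by_aa.get(aa, {})
        n = sum(obs.values())
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in obs.values())
        f_by_class[size].append((n * sum_p2 - 1.0) / (n - 1.0))

    means: dict[int, float] = {}
    for k, fs in f_by_class.items():
        if fs:
            means[k] = sum(fs) / len(fs)
    if means.get(3) is None or means.get(3, 0.0) <= 0.0:
        if 2 in means and 4 in means:
            means[3] = (means[2] + means[4]) / 2.0
    if any(k not in means or means[k] <= 0.0 for k in (2, 3, 4, 6)):
        return float("nan")
    value = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(max(value, 20.0), 61.0)


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions by direct enumeration."""
    aa = _translate(codon)
    s = n = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            maa = _translate(mutant)
            if maa == "*":
                continue
            if maa == aa:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def ng86_diffs_oracle(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences by explicit enumeration."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = codon_a
        s = n = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if _translate(nxt) == "*":
                blocked = True
                break
            if _translate(nxt) == _translate(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        if not blocked:
            paths.append((s, n))
    if not paths:
        return 0.0, 0.0
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def hypergeom_tail_oracle(k: int, n_bg: int, k_bg: int, n_study: int) -> float:
    """P[X >= k] as an exact rational sum of hypergeometric probabilities."""
    if k <= 0:
        return 1.0
    total = Fraction(0)
    denom = comb(n_bg, n_study)
    for i in range(k, min(k_bg, n_study) + 1):
        total += Fraction(comb(k_bg, i) * comb(n_bg - k_bg, n_study - i), denom)
    return float(total)


def venn_recount(rows: list[tuple[bool, bool, bool]]) -> dict[str, int]:
    """Region counts over (nr, pfam, interpro) flags via set algebra."""
    nr = {i for i, r in enumerate(rows) if r[0]}
    pf = {i for i, r in enumerate(rows) if r[1]}
    ip = {i for i, r in enumerate(rows) if r[2]}
    universe = set(range(len(rows)))
    return {
        "nr_only": len(nr - pf - ip),
        "pfam_only": len(pf - nr - ip),
        "interpro_only": len(ip - nr - pf),
        "nr_pfam": len((nr & pf) - ip),
        "nr_interpro": len((nr & ip) - pf),
        "pfam_interpro": len((pf & ip) - nr),
        "nr_pfam_interpro": len(nr & pf & ip),
        "none": len(universe - nr - pf - ip),
    }


def longest_orf_oracle(transcript: str, min_len_nt: int) -> str | None:
    """Longest ATG-to-stop ORF by scanning every start on both strands."""
    stops = {"TAA", "TAG", "TGA"}
    comp = str.maketrans("ACGTN", "TGCAN")
    candidates = []  # (-len, strand_idx, start, seq)
    for strand_idx, seq in enumerate((transcript, transcript.translate(comp)[::-1])):
        for i in range(len(seq) - 2):
            if seq[i : i + 3] != "ATG":
                continue
            for j in range(i + 3, len(seq) - 2, 3):
                if seq[j : j + 3] in stops:
                    if j - i >= min_len_nt:
                        candidates.append((-(j - i), strand_idx, i, seq[i:j]))
                    break
    if not candidates:
        return None
    # nested ORFs share a stop; keep the earliest-start (longest) per frame,
    # then order like the implementation: length, strand, start
    return min(candidates)[3]
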