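"""Codon-aware pairwise alignment and paralog / ortholog pair calling.

Proteins are aligned globally (BLOSUM62, affine gaps), the alignment is
back-translated onto the codons, and pairs are filtered on alignment
coverage (aligned columns / shorter ungapped protein) and amino-acid
identity (identical columns / aligned columns).  Orthologs between two
species are paired by reciprocal best alignment score.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genetics import translate_codon
from .seqio import CdsSet, CodingSequence

DEFAULT_MIN_COVERAGE = 0.6
DEFAULT_MIN_IDENTITY = 0.75


@dataclass
class AlignedPair:
    id_a: str
    id_b: str
    species_a: str
    species_b: str
    protein_alignment: tuple[str, str]
    codon_alignment: tuple[str, str]
    coverage: float
    identity: float
    score: float


@dataclass
class PairSet:
    kind: str  # "paralog" | "ortholog"
    pairs: list[AlignedPair] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_genes(self) -> int:
        genes = set()
        for p in self.pairs:
            genes.add((p.species_a, p.id_a))
            genes.add((p.species_b, p.id_b))
        return len(genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id_a": p.id_a,
                    "id_b": p.id_b,
                    "species_a": p.species_a,
                    "species_b": p.species_b,
                    "coverage": p.coverage,
                    "identity": p.identity,
                    "score": p.score,
                }
                for p in self.pairs
            ],
            columns=[
                "id_a",
                "id_b",
                "species_a",
                "species_b",
                "coverage",
                "identity",
                "score",
            ],
        )


def translate(cds: CodingSequence) -> str:
    """Protein sequence of a valid CDS; codons containing N become X."""
    if not cds.valid:
        raise ValueError(f"cannot translate invalid CDS {cds.id!r}")
    return "".join(translate_codon(c) for c in cds.codons())


def _make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


_ALIGNER = _make_aligner()


def align_pair(
    a: CodingSequence,
    b: CodingSequence,
    species_a: str = "",
    species_b: str = "",
) -> AlignedPair:
    """Globally align two coding sequences at the protein level.

    The result is symmetric in its arguments: internally the pair is aligned
    in a canonical order so that coverage, identity and score do not depend
    on argument order.
    """
    swap = (species_b, b.id) < (species_a, a.id)
    first, second = (b, a) if swap else (a, b)
    prot1, prot2 = translate(first), translate(second)
    alignment = _ALIGNER.align(prot1, prot2)[0]
    g1, g2 = str(alignment[0]), str(alignment[1])

    cod1 = _back_translate(g1, first)
    cod2 = _back_translate(g2, second)

    aligned_cols = sum(1 for x, y in zip(g1, g2) if x != "-" and y != "-")
    identical = sum(1 for x, y in zip(g1, g2) if x == y and x != "-")
    shorter = min(len(prot1), len(prot2))
    coverage = aligned_cols / shorter if shorter else 0.0
    identity = identical / aligned_cols if aligned_cols else 0.0
    if swap:
        g1, g2, cod1, cod2 = g2, g1, cod2, cod1
    return AlignedPair(
        id_a=a.id,
        id_b=b.id,
        species_a=species_a,
        species_b=species_b,
        protein_alignment=(g1, g2),
        codon_alignment=(cod1, cod2),
        coverage=coverage,
        identity=identity,
        score=float(alignment.score),
    )


def _back_translate(gapped_protein: str, cds: CodingSequence) -> str:
    codons = cds.codons()
    out, i = [], 0
    for aa in gapped_protein:
        if aa == "-":
            out.append("---")
        else:
            out.append(codons[i])
            i += 1
    return "".join(out)


def passes_filters(
    coverage: float,
    identity: float,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> bool:
    """Strict-inequality homology filters: both values must exceed their cutoff."""
    return coverage > min_coverage and identity > min_identity


def find_paralog_pairs(
    cds_set: CdsSet,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> PairSet:
    """All within-species pairs with coverage and identity strictly above the cutoffs.

    Pairs are not forced disjoint; a gene may belong to several pairs.
    """
    valid = [s for s in cds_set if s.valid]
    pairs = []
    for a, b in combinations(valid, 2):
        ap = align_pair(a, b, cds_set.species, cds_set.species)
        if passes_filters(ap.coverage, ap.identity, min_coverage, min_identity):
            pairs.append(ap)
    return PairSet(kind="paralog", pairs=pairs)


def find_ortholog_pairs(
    set_a: CdsSet,
    set_b: CdsSet,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> PairSet:
    """Reciprocal-best-hit ortholog pairs between two species.

    (a, b) is retained iff b is a's best-scoring partner and vice versa
    (ties broken by lexicographic id) and the pair passes both filters.
    Each gene occurs in at most one pair.
    """
    va = [s for s in set_a if s.valid]
    vb = [s for s in set_b if s.valid]
    if not va or not vb:
        return PairSet(kind="ortholog")
    aligned: dict[tuple[str, str], AlignedPair] = {}
    for a in va:
        for b in vb:
            aligned[(a.id, b.id)] = align_pair(a, b, set_a.species, set_b.species)

    def best_partner(queries, targets, lookup):
        best = {}
        for q in queries:
            ranked = sorted(
                ((lookup(q.id, t.id).score, t.id) for t in targets),
                key=lambda st: (-st[0], st[1]),
            )
            best[q.id] = ranked[0][1]
        return best

    best_ab = best_partner(va, vb, lambda x, y: aligned[(x, y)])
    best_ba = best_partner(vb, va, lambda x, y: aligned[(y, x)])

    pairs = []
    for a_id, b_id in sorted(best_ab.items()):
        if best_ba.get(b_id) != a_id:
            continue
        ap = aligned[(a_id, b_id)]
        if passes_filters(ap.coverage, ap.identity, min_coverage, min_identity):
            pairs.append(ap)
    return PairSet(kind="ortholog", pairs=pairs)


def write_pairs(pair_set: PairSet, path: str | Path) -> None:
    pair_set.to_frame().to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path, kind: str = "paralog") -> pd.DataFrame:
    """Read a precomputed pairs TSV (interoperability with external tools)."""
    df = pd.read_csv(path, sep="\t")
    required = {"id_a", "id_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pairs table missing columns {sorted(missing)}")
    return df


def realign_pairs(
    pairs: pd.DataFrame, sets: dict[str, CdsSet], kind: str = "paralog"
) -> PairSet:
    """Build AlignedPairs for a precomputed (id_a, id_b[, species]) table."""
    out = []
    for row in pairs.itertuples(index=False):
        sp_a = getattr(row, "species_a", next(iter(sets)))
        sp_b = getattr(row, "species_b", next(iter(sets)))
        out.append(
            align_pair(sets[sp_a][row.id_a], sets[sp_b][row.id_b], sp_a, sp_b)
        )
    return PairSet(kind=kind, pairs=out)
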