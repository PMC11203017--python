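"""FASTA / table I/O, CDS validation, ORF extraction and assembly statistics."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import STOP_CODONS

logger = logging.getLogger(__name__)

_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")
_VALID_BASES = set("ACGTN")


@dataclass
class CodingSequence:
    """A nucleotide coding sequence with its validation state.

    ``seq`` holds the stored sequence (terminal stop stripped once validated);
    ``notes`` accumulates human-readable validation messages.
    """

    id: str
    seq: str
    valid: bool = True
    notes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        return len(self.seq) // 3

    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq) - 2, 3)]


@dataclass
class CdsSet:
    """An ordered, id-unique collection of coding sequences for one species."""

    species: str
    sequences: list[CodingSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id {dup!r} in set {self.species!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[CodingSequence]:
        return iter(self.sequences)

    def __getitem__(self, gene_id: str) -> CodingSequence:
        for s in self.sequences:
            if s.id == gene_id:
                return s
        raise KeyError(gene_id)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def valid_only(self) -> "CdsSet":
        return CdsSet(self.species, [s for s in self.sequences if s.valid])


@dataclass(frozen=True)
class AssemblyStats:
    n_seqs: int
    total_bp: int
    min_len: int
    max_len: int
    n50: int
    l50: int
    n90: int
    l90: int
    gc_percent: float


def _clean_sequence(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    ambiguous = bad & _IUPAC_AMBIGUOUS
    if ambiguous:
        logger.warning(
            "record %s: ambiguity codes %s mapped to N",
            rec_id,
            "".join(sorted(ambiguous)),
        )
        seq = "".join("N" if b in _IUPAC_AMBIGUOUS else b for b in seq)
        bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"record {rec_id!r}: non-nucleotide characters {''.join(sorted(bad))}"
        )
    return seq


def read_fasta(path: str | Path, species: Optional[str] = None) -> CdsSet:
    """Read a FASTA file into a :class:`CdsSet`.

    Sequences are uppercased and U is mapped to T.  IUPAC ambiguity codes
    other than N are mapped to N with a logged warning; any other character
    is an error, as are duplicate ids and an empty file.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out: list[CodingSequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(CodingSequence(id=rec.id, seq=_clean_sequence(str(rec.seq), rec.id)))
    return CdsSet(species=species or path.stem, sequences=out)


def write_fasta(cds_set: CdsSet | Iterable[CodingSequence], path: str | Path) -> None:
    """Write sequences as FASTA, wrapped at 60 columns."""
    seqs = cds_set.sequences if isinstance(cds_set, CdsSet) else list(cds_set)
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(Path(path)), "fasta")


def _validate_one(
    cds: CodingSequence, require_start: bool, min_codons: int
) -> CodingSequence:
    seq = cds.seq
    notes = list(cds.notes)
    problems: list[str] = []

    if len(seq) == 0 or len(seq) % 3 != 0:
        problems.append(f"length {len(seq)} not a positive multiple of 3")
    else:
        last = seq[-3:]
        if last in STOP_CODONS and "terminal stop codon stripped" not in notes:
            seq = seq[:-3]
            notes.append("terminal stop codon stripped")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        for idx, codon in enumerate(codons):
            if codon in STOP_CODONS:
                problems.append(f"internal stop codon at codon {idx + 1}")
                break
        if len(codons) < min_codons:
            problems.append(f"only {len(codons)} codons (< {min_codons})")
        if require_start and (not codons or codons[0] != "ATG"):
            problems.append("does not start with ATG")

    for p in problems:
        if p not in notes:
            notes.append(p)
    return replace(cds, seq=seq, valid=not problems, notes=notes)


def validate_cds(
    cds_set: CdsSet, require_start: bool = False, min_codons: int = 30
) -> CdsSet:
    """Validate every sequence; nothing is deleted, failures are flagged.

    A valid CDS has positive length divisible by 3, no in-frame internal stop,
    at least ``min_codons`` codons, and (optionally) an ATG start.  A terminal
    stop codon is stripped from the stored sequence and recorded in ``notes``.
    The operation is idempotent.
    """
    return CdsSet(
        species=cds_set.species,
        sequences=[_validate_one(s, require_start, min_codons) for s in cds_set],
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _orfs_in_strand(seq: str) -> Iterator[tuple[int, int]]:
    """Yield (start, end) of every ATG-to-stop ORF (stop excluded), 0-based half-open."""
    n = len(seq)
    for frame in range(3):
        start: Optional[int] = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    yield (start, pos)
                start = None
            elif codon == "ATG" and start is None:
                start = pos


def longest_orf(transcript: str, min_len_nt: int = 90) -> Optional[CodingSequence]:
    """Longest ATG-to-stop open reading frame on either strand.

    Returns the ORF sequence without its stop codon, or ``None`` when no ORF of
    at least ``min_len_nt`` nucleotides exists.  Ties favour the forward strand,
    then the smallest 0-based start coordinate.
    """
    transcript = transcript.upper().replace("U", "T")
    best: Optional[tuple[int, int, int, str]] = None  # (-len, strand, start, seq)
    for strand_idx, seq in enumerate(
        (transcript, transcript.translate(_COMPLEMENT)[::-1])
    ):
        for start, end in _orfs_in_strand(seq):
            length = end - start
            if length < min_len_nt:
                continue
            key = (-length, strand_idx, start)
            if best is None or key < best[:3]:
                best = (*key, seq[start:end])
    if best is None:
        return None
    strand = "+" if best[1] == 0 else "-"
    return CodingSequence(
        id="orf", seq=best[3], notes=[f"strand {strand}, start {best[2]} (0-based)"]
    )


def assembly_stats(cds_set: CdsSet) -> AssemblyStats:
    """Summary statistics of a sequence set (N50/L50, N90/L90, GC%).

    Nx is the length of the sequence at which the descending cumulative length
    first reaches x% of the total; Lx is the 1-based rank of that sequence.
    GC% is computed over unambiguous (A/C/G/T) bases only.
    """
    if len(cds_set) == 0:
        raise ValueError("assembly_stats requires at least one sequence")
    lengths = sorted((len(s) for s in cds_set), reverse=True)
    total = sum(lengths)

    def nx_lx(fraction: float) -> tuple[int, int]:
        target = fraction * total
        cum = 0
        for rank, length in enumerate(lengths, start=1):
            cum += length
            if cum >= target:
                return length, rank
        return lengths[-1], len(lengths)  # pragma: no cover

    n50, l50 = nx_lx(0.5)
    n90, l90 = nx_lx(0.9)
    gc = at = 0
    for s in cds_set:
        gc += s.seq.count("G") + s.seq.count("C")
        at += s.seq.count("A") + s.seq.count("T")
    gc_percent = 100.0 * gc / (gc + at) if (gc + at) else float("nan")
    return AssemblyStats(
        n_seqs=len(cds_set),
        total_bp=total,
        min_len=lengths[-1],
        max_len=lengths[0],
        n50=n50,
        l50=l50,
        n90=n90,
        l90=l90,
        gc_percent=gc_percent,
    )


ASSEMBLY_STATS_COLUMNS = [
    "n_seqs",
    "total_bp",
    "min_len",
    "max_len",
    "n50",
    "l50",
    "n90",
    "l90",
    "gc_percent",
]


def write_assembly_stats(stats: AssemblyStats, path: str | Path) -> None:
    """Write the statistics as a one-row TSV with a fixed column order."""
    row = {c: getattr(stats, c) for c in ASSEMBLY_STATS_COLUMNS}
    pd.DataFrame([row], columns=ASSEMBLY_STATS_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_validation_report(cds_set: CdsSet, path: str | Path) -> None:
    rows = [
        {
            "gene_id": s.id,
            "length": len(s),
            "valid": int(s.valid),
            "notes": "; ".join(s.notes),
        }
        for s in cds_set
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
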