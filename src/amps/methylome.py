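"""Genome and per-cytosine methylation I/O.

Coordinates are 0-based half-open internally; the Bismark-style cytosine
report uses 1-based positions and is converted on read/write.  A cytosine's
context (CG/CHG/CHH, H = A/C/T) is always recomputed from the genome; the
context column in a report file is advisory only.

Call rules: a cytosine needs strictly more than ``COVERAGE_MIN`` reads to be
called at all; with sufficient coverage it is *methylated* when its level
(methylated reads / total reads) is at least ``LEVEL_THRESHOLD``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: minimum read count that must be *exceeded* for a methylation call
COVERAGE_MIN = 10
#: methylation level at or above which a covered cytosine is called methylated
LEVEL_THRESHOLD = 0.5

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
UNKNOWN = "unknown"

CONTEXTS = ("CG", "CHG", "CHH")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: identifier plus an uppercase A/C/G/T/N string."""

    chrom_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for {self.chrom_id!r}")
        normalized = normalize_sequence(self.seq)
        if normalized != self.seq:
            object.__setattr__(self, "seq", normalized)

    def __len__(self) -> int:
        return len(self.seq)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map every non-ACGT letter to N."""
    seq = seq.upper()
    if set(seq) <= VALID_BASES:
        return seq
    return "".join(b if b in VALID_BASES else "N" for b in seq)


def read_fasta(path: str | Path) -> Dict[str, GenomeSequence]:
    """Read a (possibly wrapped, mixed-case) multi-record FASTA file."""
    genomes: Dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genomes:
            raise ValueError(f"duplicate FASTA record {record.id!r}")
        genomes[record.id] = GenomeSequence(record.id, str(record.seq))
    return genomes


def write_fasta(genomes: Mapping[str, GenomeSequence], path: str | Path,
                width: int = 70) -> None:
    records = [SeqRecord(Seq(g.seq), id=chrom, description="")
               for chrom, g in genomes.items()]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


def assign_context(genome: GenomeSequence, pos: int, strand: str) -> Optional[str]:
    """Context of the cytosine at ``pos`` on ``strand`` (0-based).

    Reads the two bases 3' of the cytosine on its own strand.  Returns
    ``"CG"``, ``"CHG"``, ``"CHH"`` or ``None`` when a needed base is N or
    lies beyond the chromosome end.  Raises ``ValueError`` when the base at
    ``pos`` on the given strand is not C.
    """
    seq = genome.seq
    n = len(seq)
    if not 0 <= pos < n:
        raise IndexError(f"position {pos} outside {genome.chrom_id} (len {n})")
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(
                f"base at {genome.chrom_id}:{pos}(+) is {seq[pos]!r}, not C")
        b1 = seq[pos + 1] if pos + 1 < n else None
        b2 = seq[pos + 2] if pos + 2 < n else None
    elif strand == "-":
        if seq[pos] != "G":
            raise ValueError(
                f"base at {genome.chrom_id}:{pos}(-) is "
                f"{complement(seq[pos])!r}, not C")
        b1 = complement(seq[pos - 1]) if pos - 1 >= 0 else None
        b2 = complement(seq[pos - 2]) if pos - 2 >= 0 else None
    else:
        raise ValueError(f"invalid strand {strand!r}")

    if b1 is None or b1 == "N":
        return None
    if b1 == "G":
        return "CG"
    if b2 is None or b2 == "N":
        return None
    return "CHG" if b2 == "G" else "CHH"


def call_status(meth_reads: int, total_reads: int) -> str:
    """Binary methylation call with an unknown state for low coverage."""
    if meth_reads < 0 or total_reads < 0:
        raise ValueError("read counts must be non-negative")
    if meth_reads > total_reads:
        raise ValueError(
            f"meth_reads ({meth_reads}) exceeds total_reads ({total_reads})")
    if total_reads <= COVERAGE_MIN:
        return UNKNOWN
    if meth_reads / total_reads >= LEVEL_THRESHOLD:
        return METHYLATED
    return UNMETHYLATED


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's position, strand, context, counts and derived call."""

    chrom: str
    pos: int  # 0-based
    strand: str
    context: str
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.meth_reads > self.total_reads:
            raise ValueError("meth_reads exceeds total_reads")
        if self.meth_reads < 0:
            raise ValueError("negative read count")
        if self.context not in CONTEXTS:
            raise ValueError(f"invalid context {self.context!r}")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def level(self) -> Optional[float]:
        if self.total_reads == 0:
            return None
        return self.meth_reads / self.total_reads

    @property
    def status(self) -> str:
        return call_status(self.meth_reads, self.total_reads)

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)


class MethylationCallSet:
    """Cytosine records indexed by (chrom, pos, strand), tied to a genome."""

    def __init__(self, genomes: Mapping[str, GenomeSequence],
                 records: Iterable[CytosineRecord] = ()) -> None:
        self.genomes = dict(genomes)
        self._records: Dict[Tuple[str, int, str], CytosineRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: CytosineRecord) -> None:
        if rec.key in self._records:
            raise ValueError(f"duplicate cytosine record at {rec.key}")
        if rec.chrom not in self.genomes:
            raise KeyError(f"unknown chromosome {rec.chrom!r}")
        self._records[rec.key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CytosineRecord]:
        return iter(self._records.values())

    def __contains__(self, key: Tuple[str, int, str]) -> bool:
        return key in self._records

    def get(self, chrom: str, pos: int, strand: str) -> Optional[CytosineRecord]:
        return self._records.get((chrom, pos, strand))

    def records(self, chrom: Optional[str] = None) -> Iterator[CytosineRecord]:
        for rec in self._records.values():
            if chrom is None or rec.chrom == chrom:
                yield rec

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationCallSet):
            return NotImplemented
        return self._records == other._records


def read_cytosine_report(path: str | Path,
                         genomes: Mapping[str, GenomeSequence]) -> MethylationCallSet:
    """Parse a Bismark-style cytosine report.

    Expected columns (whitespace-delimited): chrom, 1-based position, strand,
    methylated count, unmethylated count, context, trinucleotide.  The last
    two columns are optional and never trusted: context is recomputed from
    the genome, disagreements are logged, and cytosines whose context is
    undefined (N or chromosome edge 3' of the C) are dropped with a count.
    """
    callset = MethylationCallSet(genomes)
    n_dropped = 0
    n_context_mismatch = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
            chrom, pos1, strand, n_meth, n_unmeth = fields[:5]
            stated_context = fields[5] if len(fields) > 5 else None
            if chrom not in genomes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                pos = int(pos1) - 1
                meth_reads = int(n_meth)
                unmeth_reads = int(n_unmeth)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed counts") from exc
            genome = genomes[chrom]
            if not 0 <= pos < len(genome):
                raise ValueError(
                    f"{path}:{lineno}: position {pos1} beyond {chrom} length "
                    f"{len(genome)}")
            context = assign_context(genome, pos, strand)
            if context is None:
                n_dropped += 1
                continue
            if stated_context is not None and stated_context != context:
                n_context_mismatch += 1
            callset.add(CytosineRecord(chrom, pos, strand, context,
                                       meth_reads, meth_reads + unmeth_reads))
    if n_dropped:
        logger.info("dropped %d cytosines with undefined context from %s",
                    n_dropped, path)
    if n_context_mismatch:
        logger.warning("%d stated contexts disagreed with the genome in %s; "
                       "genome-derived contexts used", n_context_mismatch, path)
    return callset


def write_cytosine_report(callset: MethylationCallSet, path: str | Path) -> None:
    """Write a tab-delimited Bismark-style cytosine report (1-based)."""
    with open(path, "w") as handle:
        for rec in sorted(callset, key=lambda r: (r.chrom, r.pos, r.strand)):
            genome = callset.genomes[rec.chrom]
            tri = _trinucleotide(genome, rec.pos, rec.strand)
            handle.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{rec.strand}\t{rec.meth_reads}\t"
                f"{rec.total_reads - rec.meth_reads}\t{rec.context}\t{tri}\n")


def _trinucleotide(genome: GenomeSequence, pos: int, strand: str) -> str:
    seq, n = genome.seq, len(genome)
    if strand == "+":
        return seq[pos:pos + 3].ljust(3, "N")
    lo = max(pos - 2, 0)
    return reverse_complement(seq[lo:pos + 1]).ljust(3, "N")
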