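"""Per-chromosome binary annotation channels: gene (+), gene (-), repeat.

Gene intervals set bits in a strand-specific vector; repeat intervals set a
single strand-agnostic vector.  Overlaps OR together.  Intervals are stored
0-based half-open; the GFF3 and RepeatMasker readers convert from their
1-based inclusive conventions, BED is passed through.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np

from .methylome import GenomeSequence

#: default feature types routed to the gene channels
DEFAULT_GENE_TYPES = frozenset({"gene"})
REPEAT_TYPE = "repeat"

TRACK_NAMES = ("gene_fwd", "gene_rev", "repeat")


@dataclass(frozen=True)
class FeatureInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    feature_type: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")


class AnnotationTrackSet:
    """chrom -> {gene_fwd, gene_rev, repeat} uint8 bit vectors."""

    def __init__(self, vectors: Dict[str, Dict[str, np.ndarray]]) -> None:
        self.vectors = vectors

    @property
    def a(self) -> int:
        return len(TRACK_NAMES) if self.vectors else 0

    def chrom_tracks(self, chrom: str) -> Dict[str, np.ndarray]:
        return self.vectors[chrom]

    def matrix(self, chrom: str) -> np.ndarray:
        """(chrom_length, 3) uint8 matrix in gene_fwd/gene_rev/repeat order."""
        t = self.vectors[chrom]
        return np.stack([t[name] for name in TRACK_NAMES], axis=1)

    @classmethod
    def empty(cls, genomes: Mapping[str, GenomeSequence]) -> "AnnotationTrackSet":
        return cls({chrom: {name: np.zeros(len(g), dtype=np.uint8)
                            for name in TRACK_NAMES}
                    for chrom, g in genomes.items()})


def build_tracks(features: Iterable[FeatureInterval],
                 genomes: Mapping[str, GenomeSequence],
                 gene_types: frozenset | set = DEFAULT_GENE_TYPES,
                 ) -> AnnotationTrackSet:
    """Rasterize intervals onto per-chromosome bit vectors.

    Intervals whose ``feature_type`` is in ``gene_types`` go to the
    strand-specific gene channels (strand '.' contributes to both); intervals
    typed ``repeat`` go to the shared repeat channel.  Other types are
    ignored.
    """
    tracks = AnnotationTrackSet.empty(genomes)
    for feat in features:
        if feat.chrom not in genomes:
            raise KeyError(f"unknown chromosome {feat.chrom!r}")
        chrom_len = len(genomes[feat.chrom])
        if feat.end > chrom_len:
            raise ValueError(
                f"interval [{feat.start}, {feat.end}) beyond end of "
                f"{feat.chrom} (len {chrom_len})")
        vecs = tracks.vectors[feat.chrom]
        if feat.feature_type == REPEAT_TYPE:
            vecs["repeat"][feat.start:feat.end] = 1
        elif feat.feature_type in gene_types:
            if feat.strand in "+.":
                vecs["gene_fwd"][feat.start:feat.end] = 1
            if feat.strand in "-.":
                vecs["gene_rev"][feat.start:feat.end] = 1
    return tracks


def read_gff3(path: str | Path,
              feature_types: Sequence[str] | None = None) -> List[FeatureInterval]:
    """Read GFF3 (1-based inclusive) into 0-based half-open intervals."""
    intervals: List[FeatureInterval] = []
    keep = set(feature_types) if feature_types is not None else None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _source, ftype, start, end, _score, strand = fields[:7]
            if keep is not None and ftype not in keep:
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if strand not in "+-":
                strand = "."
            intervals.append(FeatureInterval(chrom, start0, end0, strand, ftype))
    return intervals


def read_bed(path: str | Path,
             feature_type: str = REPEAT_TYPE) -> List[FeatureInterval]:
    """Read BED (0-based half-open).  Strand from column 6 when present."""
    intervals: List[FeatureInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            intervals.append(FeatureInterval(chrom, start, end, strand, feature_type))
    return intervals


def read_repeatmasker(path: str | Path) -> List[FeatureInterval]:
    """Read RepeatMasker .out (1-based inclusive; 3 header lines; 'C' = minus)."""
    intervals: List[FeatureInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            fields = line.split()
            if not fields:
                continue
            # header lines start with the 'SW'/'score' banner
            if not fields[0].lstrip("-").isdigit():
                continue
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
            chrom = fields[4]
            try:
                start, end = int(fields[5]) - 1, int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            strand = "-" if fields[8] == "C" else "+"
            intervals.append(FeatureInterval(chrom, start, end, strand, REPEAT_TYPE))
    return intervals
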