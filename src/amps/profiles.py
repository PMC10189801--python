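"""Gene-body methylation metaprofiles.

Each gene contributes 15 bins laid out 5'->3' along its own strand: five
400 bp bins of upstream flank, five bins spanning one-fifth of the gene body
each (the division remainder goes to the last, 3'-most body bin), and five
400 bp bins of downstream flank.  Flank bins running past a chromosome end
are truncated and their actual length used.

Per gene i and bin r, ``m(r, i)`` is the ratio of methylated cytosines over
all called cytosines of the requested context in the bin (computed
separately on the gene's template and nontemplate strands; unknown-status
cytosines never count), and ``l(r, i)`` is the bin length in bp.  The
species profile aggregates ``M(r) = sum_i m(r,i) l(r,i) / sum_i l(r,i)``
over the genes whose bin contains at least one called cytosine.

The *nontemplate* orientation is the gene's annotated (mRNA-like) strand;
*template* is the transcribed, complementary strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .methylome import METHYLATED, UNKNOWN, MethylationCallSet
from .tracks import FeatureInterval

N_BINS = 15
FLANK_TOTAL = 2000
BINS_PER_REGION = 5
FLANK_BIN = FLANK_TOTAL // BINS_PER_REGION  # 400 bp

ORIENTATIONS = ("template", "nontemplate")


@dataclass
class GeneProfile:
    context: str
    orientation: str
    bins: np.ndarray  # (15,) M(r); NaN where no gene contributed
    genes_contributing: np.ndarray  # (15,) int
    G: int  # genes aggregated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "context": self.context,
            "orientation": self.orientation,
            "bin": np.arange(1, N_BINS + 1),
            "M": self.bins,
            "genes_contributing": self.genes_contributing,
        })


def gene_bins(gene: FeatureInterval, chrom_length: int,
              flank: int = FLANK_TOTAL,
              bins_per_region: int = BINS_PER_REGION
              ) -> List[Tuple[int, int]]:
    """The 15 genomic intervals of one gene in bin order (1..15, 5'->3').

    Intervals are 0-based half-open, truncated at chromosome ends; a fully
    truncated flank bin comes back as a zero-length ``(x, x)`` interval.
    """
    if gene.strand not in "+-":
        raise ValueError(f"gene on {gene.chrom} has no strand")
    gl = gene.end - gene.start
    if gl < bins_per_region:
        raise ValueError(
            f"gene [{gene.start}, {gene.end}) shorter than {bins_per_region} bp")
    flank_bin = flank // bins_per_region
    base = gl // bins_per_region
    offsets = [r * base for r in range(bins_per_region)] + [gl]

    intervals: List[Tuple[int, int]] = []
    if gene.strand == "+":
        for r in range(bins_per_region):  # upstream, far -> near
            lo = gene.start - flank + r * flank_bin
            intervals.append((max(lo, 0), max(lo + flank_bin, 0)))
        for r in range(bins_per_region):  # body, 5' -> 3'
            intervals.append((gene.start + offsets[r],
                              gene.start + offsets[r + 1]))
        for r in range(bins_per_region):  # downstream, near -> far
            lo = gene.end + r * flank_bin
            intervals.append((min(lo, chrom_length),
                              min(lo + flank_bin, chrom_length)))
    else:
        for r in range(bins_per_region):
            hi = gene.end + flank - r * flank_bin
            intervals.append((min(hi - flank_bin, chrom_length),
                              min(hi, chrom_length)))
        for r in range(bins_per_region):
            intervals.append((gene.end - offsets[r + 1],
                              gene.end - offsets[r]))
        for r in range(bins_per_region):
            hi = gene.start - r * flank_bin
            intervals.append((max(hi - flank_bin, 0), max(hi, 0)))
    return [(lo, min(hi, chrom_length)) for lo, hi in
            ((max(lo, 0), hi) for lo, hi in intervals)]


class _ContextIndex:
    """Sorted positions of called / methylated cytosines per (chrom, strand)."""

    def __init__(self, calls: MethylationCallSet, context: str) -> None:
        called: Dict[Tuple[str, str], List[int]] = {}
        meth: Dict[Tuple[str, str], List[int]] = {}
        levels: Dict[Tuple[str, str], List[Tuple[int, float]]] = {}
        for rec in calls:
            if rec.context != context or rec.status == UNKNOWN:
                continue
            key = (rec.chrom, rec.strand)
            called.setdefault(key, []).append(rec.pos)
            levels.setdefault(key, []).append((rec.pos, rec.level))
            if rec.status == METHYLATED:
                meth.setdefault(key, []).append(rec.pos)
        self.called = {k: np.array(sorted(v)) for k, v in called.items()}
        self.meth = {k: np.array(sorted(v)) for k, v in meth.items()}
        self.levels = {}
        for k, pairs in levels.items():
            pairs.sort()
            arr = np.array(pairs, dtype=np.float64)
            self.levels[k] = (arr[:, 0].astype(np.int64), arr[:, 1])

    def counts(self, chrom: str, strand: str, lo: int, hi: int
               ) -> Tuple[int, int]:
        key = (chrom, strand)
        pos = self.called.get(key)
        n_called = 0 if pos is None else int(
            np.searchsorted(pos, hi) - np.searchsorted(pos, lo))
        mpos = self.meth.get(key)
        n_meth = 0 if mpos is None else int(
            np.searchsorted(mpos, hi) - np.searchsorted(mpos, lo))
        return n_meth, n_called

    def level_sum(self, chrom: str, strand: str, lo: int, hi: int
                  ) -> Tuple[float, int]:
        key = (chrom, strand)
        if key not in self.levels:
            return 0.0, 0
        pos, lev = self.levels[key]
        i, j = np.searchsorted(pos, lo), np.searchsorted(pos, hi)
        return float(lev[i:j].sum()), int(j - i)


def gene_profile(calls: MethylationCallSet,
                 genes: Sequence[FeatureInterval],
                 context: str,
                 flank: int = FLANK_TOTAL,
                 bins_per_region: int = BINS_PER_REGION,
                 level_mode: str = "binary",
                 ) -> Dict[str, GeneProfile]:
    """Aggregate M(r) over genes for both strand orientations.

    ``level_mode="binary"`` (default) takes m(r, i) as the fraction of
    *called-methylated* cytosines; ``"mean"`` averages raw levels instead
    (offered as an alternative view, not the canonical definition).
    """
    if level_mode not in ("binary", "mean"):
        raise ValueError(f"unknown level_mode {level_mode!r}")
    n_bins = 3 * bins_per_region
    index = _ContextIndex(calls, context)
    num = {o: np.zeros(n_bins) for o in ORIENTATIONS}
    den = {o: np.zeros(n_bins) for o in ORIENTATIONS}
    n_genes = {o: np.zeros(n_bins, dtype=int) for o in ORIENTATIONS}

    for gene in genes:
        chrom_length = len(calls.genomes[gene.chrom])
        intervals = gene_bins(gene, chrom_length, flank, bins_per_region)
        strand_of = {"nontemplate": gene.strand,
                     "template": "-" if gene.strand == "+" else "+"}
        for orientation in ORIENTATIONS:
            strand = strand_of[orientation]
            for r, (lo, hi) in enumerate(intervals):
                if hi <= lo:
                    continue
                if level_mode == "binary":
                    n_meth, n_called = index.counts(gene.chrom, strand, lo, hi)
                    if n_called == 0:
                        continue
                    m = n_meth / n_called
                else:
                    total, n_called = index.level_sum(gene.chrom, strand, lo, hi)
                    if n_called == 0:
                        continue
                    m = total / n_called
                l = hi - lo
                num[orientation][r] += m * l
                den[orientation][r] += l
                n_genes[orientation][r] += 1

    out = {}
    for orientation in ORIENTATIONS:
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(den[orientation] > 0,
                         num[orientation] / np.maximum(den[orientation], 1e-300),
                         np.nan)
        out[orientation] = GeneProfile(context=context, orientation=orientation,
                                       bins=M,
                                       genes_contributing=n_genes[orientation],
                                       G=len(genes))
    return out


def profiles_table(calls: MethylationCallSet,
                   genes: Sequence[FeatureInterval],
                   contexts: Sequence[str] = ("CG", "CHG", "CHH"),
                   **kwargs) -> pd.DataFrame:
    """Long-format table over contexts and orientations (for TSV export)."""
    frames = []
    for context in contexts:
        for profile in gene_profile(calls, genes, context, **kwargs).values():
            frames.append(profile.to_frame())
    return pd.concat(frames, ignore_index=True)
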