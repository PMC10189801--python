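"""Synthetic genomes, annotations and methylomes with known structure.

Every cytosine's methylation probability follows a logistic model:

    p = sigmoid( logit(base_rate[context]) + gene_effect * in_gene
                 + repeat_effect * in_repeat + motif_effect * near_motif
                 + neighbor_weight * z )

where ``z`` is an AR(1) latent field over consecutive cytosine sites
(coefficient ``neighbor_correlation``) that induces spatial correlation of
methylation states.  The binary state is Bernoulli(p); reads are emitted as
``total ~ Poisson(coverage_lambda)`` and ``meth ~ Binomial(total, level)``
with ``level`` 0.9 for truly methylated and 0.1 for unmethylated sites, so
the >=0.5 call recovers the true state with high probability at the default
coverage.  Everything is reproducible bit-for-bit under the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .datasets import sequence_codes, _CODE_COMPLEMENT
from .methylome import (
    CytosineRecord,
    GenomeSequence,
    MethylationCallSet,
    write_cytosine_report,
    write_fasta,
)
from .tracks import FeatureInterval, build_tracks, AnnotationTrackSet

CONTEXT_CODES = {0: "CG", 1: "CHG", 2: "CHH"}

PROFILES = ("motif_driven", "annotation_driven", "neighbor_driven",
            "divergent_pair")


@dataclass
class SimulationConfig:
    genome_length: int = 200_000
    n_chroms: int = 1
    gc_fraction: float = 0.5
    gene_density: float = 0.0
    gene_length: Tuple[int, int] = (1500, 3000)
    repeat_density: float = 0.0
    repeat_length: Tuple[int, int] = (300, 800)
    planted_motif: Optional[str] = None
    motif_spacing: int = 200  # mean gap between planted instances
    motif_effect_window: int = 10  # +- bp around an instance
    context_base_rates: Dict[str, float] = field(
        default_factory=lambda: {"CG": 0.3, "CHG": 0.2, "CHH": 0.05})
    gene_effect: float = 0.0
    repeat_effect: float = 0.0
    motif_effect: float = 0.0
    neighbor_correlation: float = 0.0  # AR(1) coefficient
    neighbor_weight: float = 0.0
    level_methylated: float = 0.9
    level_unmethylated: float = 0.1
    coverage_lambda: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in list(self.context_base_rates.items()):
            if not 0.0 < p < 1.0:
                raise ValueError(f"base rate for {name} must be in (0, 1)")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.gene_density >= 0.95 or self.repeat_density >= 0.95:
            raise ValueError("feature density too high to place intervals")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not -1.0 < self.neighbor_correlation < 1.0:
            raise ValueError("neighbor_correlation must be in (-1, 1)")


@dataclass
class GroundTruth:
    """Per-cytosine truth table (one row per defined-context cytosine)."""

    table: pd.DataFrame  # chrom,pos,strand,context,p,state,in_gene,in_repeat,near_motif

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.8g")


@dataclass
class FixtureBundle:
    config: SimulationConfig
    genomes: Dict[str, GenomeSequence]
    features: List[FeatureInterval]
    calls: MethylationCallSet
    truth: GroundTruth
    motif_positions: Dict[str, np.ndarray]

    @property
    def genes(self) -> List[FeatureInterval]:
        return [f for f in self.features if f.feature_type == "gene"]

    @property
    def repeats(self) -> List[FeatureInterval]:
        return [f for f in self.features if f.feature_type == "repeat"]

    def annotation_tracks(self) -> AnnotationTrackSet:
        return build_tracks(self.features, self.genomes)

    def write(self, outdir: str | Path) -> Dict[str, Path]:
        """Write FASTA/GFF3/BED/report/truth/config; byte-stable under seed."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "genome.fa",
            "gff3": outdir / "genes.gff3",
            "repeats": outdir / "repeats.bed",
            "report": outdir / "cytosine_report.txt",
            "truth": outdir / "truth.tsv",
            "config": outdir / "sim_config.json",
        }
        write_fasta(self.genomes, paths["fasta"])
        write_gff3(self.genes, paths["gff3"])
        write_bed(self.repeats, paths["repeats"])
        write_cytosine_report(self.calls, paths["report"])
        self.truth.to_tsv(paths["truth"])
        with open(paths["config"], "w") as fh:
            json.dump(asdict(self.config), fh, indent=2, sort_keys=True)
        return paths


def write_gff3(genes: List[FeatureInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes):
            fh.write(f"{g.chrom}\tamps_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID=gene{i}\n")


def write_bed(intervals: List[FeatureInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, f in enumerate(intervals):
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\trepeat{i}\t0\t"
                     f"{f.strand if f.strand in '+-' else '.'}\n")


def _place_intervals(rng: np.random.Generator, chrom: str, length: int,
                     density: float, length_range: Tuple[int, int],
                     feature_type: str, stranded: bool) -> List[FeatureInterval]:
    """Non-overlapping intervals by an exponential-gap walk along the
    chromosome, hitting the requested density in expectation."""
    if density <= 0:
        return []
    mean_len = sum(length_range) / 2
    mean_gap = mean_len * (1 - density) / density
    out: List[FeatureInterval] = []
    pos = int(rng.exponential(mean_gap / 2))
    while True:
        flen = int(rng.integers(length_range[0], length_range[1] + 1))
        if pos + flen > length:
            break
        strand = ("+" if rng.random() < 0.5 else "-") if stranded else "."
        out.append(FeatureInterval(chrom, pos, pos + flen, strand, feature_type))
        pos += flen + 1 + int(rng.exponential(mean_gap))
    return out


def simulate_genome(config: SimulationConfig
                    ) -> Tuple[Dict[str, GenomeSequence],
                               List[FeatureInterval],
                               Dict[str, np.ndarray]]:
    """i.i.d. genome at the configured GC, gene/repeat intervals, and planted
    motif instances (written into the sequence at recorded positions)."""
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    genomes: Dict[str, GenomeSequence] = {}
    features: List[FeatureInterval] = []
    motif_positions: Dict[str, np.ndarray] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        length = config.genome_length
        seq = rng.choice(bases, size=length, p=probs)
        features.extend(_place_intervals(
            rng, chrom, length, config.gene_density, config.gene_length,
            "gene", stranded=True))
        features.extend(_place_intervals(
            rng, chrom, length, config.repeat_density, config.repeat_length,
            "repeat", stranded=False))
        starts: List[int] = []
        if config.planted_motif:
            motif = np.frombuffer(config.planted_motif.encode(), dtype=np.uint8)
            pos = int(rng.exponential(config.motif_spacing)) + 50
            while pos + len(motif) <= length - 50:
                seq[pos:pos + len(motif)] = motif
                starts.append(pos)
                pos += len(motif) + int(rng.exponential(config.motif_spacing))
        motif_positions[chrom] = np.array(starts, dtype=np.int64)
        genomes[chrom] = GenomeSequence(chrom, seq.tobytes().decode("ascii"))
    return genomes, features, motif_positions


def cytosine_sites(genome: GenomeSequence
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All cytosines with a defined context on either strand.

    Returns position, strand ('+'/'-' as 0/1) and context code arrays,
    sorted by position.
    """
    codes = sequence_codes(genome)
    padded = np.concatenate([[4, 4], codes, [4, 4]])

    def classify(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
        h1 = (b1 != 2) & (b1 != 4)
        h2 = (b2 != 2) & (b2 != 4)
        ctx = np.full(len(b1), -1, dtype=np.int8)
        ctx[b1 == 2] = 0  # CG
        ctx[h1 & (b2 == 2)] = 1  # CHG
        ctx[h1 & h2] = 2  # CHH
        return ctx

    plus = np.flatnonzero(codes == 1)
    ctx_plus = classify(padded[plus + 3], padded[plus + 4])
    minus = np.flatnonzero(codes == 2)
    ctx_minus = classify(_CODE_COMPLEMENT[padded[minus + 1]],
                         _CODE_COMPLEMENT[padded[minus]])

    pos = np.concatenate([plus[ctx_plus >= 0], minus[ctx_minus >= 0]])
    strand = np.concatenate([
        np.zeros(int((ctx_plus >= 0).sum()), dtype=np.int8),
        np.ones(int((ctx_minus >= 0).sum()), dtype=np.int8)])
    ctx = np.concatenate([ctx_plus[ctx_plus >= 0], ctx_minus[ctx_minus >= 0]])
    order = np.argsort(pos, kind="stable")
    return pos[order], strand[order], ctx[order]


def _interval_mask(length: int, intervals) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for lo, hi in intervals:
        mask[max(lo, 0):min(hi, length)] = True
    return mask


def simulate_methylome(genomes: Mapping[str, GenomeSequence],
                       features: List[FeatureInterval],
                       config: SimulationConfig,
                       motif_positions: Optional[Mapping[str, np.ndarray]] = None,
                       ) -> Tuple[MethylationCallSet, GroundTruth]:
    """Draw per-cytosine states and read counts under the logistic model."""
    rng = np.random.default_rng(config.seed + 1)
    base_logit = np.array([math.log(config.context_base_rates[CONTEXT_CODES[c]]
                                    / (1 - config.context_base_rates[
                                        CONTEXT_CODES[c]]))
                           for c in range(3)])
    records: List[CytosineRecord] = []
    frames: List[pd.DataFrame] = []
    motif_len = len(config.planted_motif) if config.planted_motif else 0
    for chrom in sorted(genomes):
        genome = genomes[chrom]
        length = len(genome)
        pos, strand, ctx = cytosine_sites(genome)
        n = len(pos)
        gene_mask = _interval_mask(length, [
            (f.start, f.end) for f in features
            if f.chrom == chrom and f.feature_type == "gene"])
        repeat_mask = _interval_mask(length, [
            (f.start, f.end) for f in features
            if f.chrom == chrom and f.feature_type == "repeat"])
        starts = (motif_positions or {}).get(chrom, np.empty(0, dtype=np.int64))
        w = config.motif_effect_window
        motif_mask = _interval_mask(length, [
            (s - w, s + motif_len + w) for s in starts])

        logit = base_logit[ctx].copy()
        logit += config.gene_effect * gene_mask[pos]
        logit += config.repeat_effect * repeat_mask[pos]
        logit += config.motif_effect * motif_mask[pos]
        rho = config.neighbor_correlation
        if config.neighbor_weight:
            eps = rng.standard_normal(n)
            drive = eps * math.sqrt(1 - rho ** 2)
            if n:
                drive[0] = eps[0]
            z = lfilter([1.0], [1.0, -rho], drive)
            logit += config.neighbor_weight * z
        p = 1.0 / (1.0 + np.exp(-np.clip(logit, -35, 35)))
        state = rng.random(n) < p
        level = np.where(state, config.level_methylated,
                         config.level_unmethylated)
        total = rng.poisson(config.coverage_lambda, size=n)
        meth = rng.binomial(total, level)

        contexts = np.array(["CG", "CHG", "CHH"])[ctx]
        strands = np.array(["+", "-"])[strand]
        records.extend(
            CytosineRecord(chrom, int(pos[i]), strands[i], contexts[i],
                           int(meth[i]), int(total[i]))
            for i in range(n))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": strands,
            "context": contexts, "p": p, "state": state.astype(int),
            "in_gene": gene_mask[pos].astype(int),
            "in_repeat": repeat_mask[pos].astype(int),
            "near_motif": motif_mask[pos].astype(int)}))
    calls = MethylationCallSet(genomes, records)
    truth = GroundTruth(pd.concat(frames, ignore_index=True))
    return calls, truth


def simulate(config: SimulationConfig) -> FixtureBundle:
    genomes, features, motif_positions = simulate_genome(config)
    calls, truth = simulate_methylome(genomes, features, config,
                                      motif_positions)
    return FixtureBundle(config=config, genomes=genomes, features=features,
                         calls=calls, truth=truth,
                         motif_positions=motif_positions)


# canned profiles, sized for CPU-scale tests -------------------------------

#: reverse-complement palindromes, so oriented minus-strand windows contain
#: the same literal string
MOTIF_A = "GCATATGC"
MOTIF_B = "CATGCATG"

_TINY = 1e-4


def _profile_config(profile: str, seed: int) -> SimulationConfig:
    if profile == "motif_driven":
        return SimulationConfig(
            genome_length=400_000, planted_motif=MOTIF_A, motif_spacing=150,
            motif_effect_window=10,
            context_base_rates={"CG": _TINY, "CHG": _TINY, "CHH": _TINY},
            motif_effect=30.0, seed=seed)
    if profile == "annotation_driven":
        return SimulationConfig(
            genome_length=300_000, gene_density=0.4,
            gene_length=(2000, 4000), repeat_density=0.15,
            context_base_rates={"CG": 0.15, "CHG": 0.15, "CHH": 0.15},
            gene_effect=3.46, repeat_effect=1.0, seed=seed)
    if profile == "neighbor_driven":
        return SimulationConfig(
            genome_length=150_000,
            context_base_rates={"CG": 0.5, "CHG": 0.5, "CHH": 0.5},
            neighbor_correlation=0.999, neighbor_weight=12.0, seed=seed)
    raise ValueError(f"unknown fixture profile {profile!r}")


def make_fixture(profile: str, seed: int = 0, **overrides):
    """A canned, fully reproducible fixture bundle.

    ``divergent_pair`` returns a ``(bundle_a, bundle_b)`` tuple of two
    "species" whose methylation is driven by disjoint planted motifs; the
    other profiles return a single :class:`FixtureBundle`.
    """
    if profile == "divergent_pair":
        base = _profile_config("motif_driven", seed)
        cfg_a = replace(base, **{"genome_length": 200_000, **overrides})
        cfg_b = replace(cfg_a, planted_motif=MOTIF_B, seed=seed + 1000)
        return simulate(cfg_a), simulate(cfg_b)
    if profile not in PROFILES:
        raise ValueError(f"unknown fixture profile {profile!r}")
    config = replace(_profile_config(profile, seed), **overrides) \
        if overrides else _profile_config(profile, seed)
    return simulate(config)
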