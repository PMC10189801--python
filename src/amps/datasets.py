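"""Balanced training-set construction.

Two example families are produced, both centered on a cytosine with a known
(covered) methylation call:

* encoded sequence windows — a ``W_s x (4 + a)`` binary matrix of one-hot
  bases (columns A,C,G,T) plus ``a`` annotation channels copied from the
  per-base bit vectors;
* neighbor vectors — the methylation levels of the ``W_p/2`` nearest covered
  cytosines on each side of the center (any context, both strands), ordered
  by genomic coordinate.

Minus-strand windows are reverse-complemented so the center cytosine reads C
in its own 5'->3' orientation; the two gene channels are swapped and all
channels reversed accordingly.

Datasets are balanced: n/2 methylated and n/2 unmethylated centers, and for
the mixed "ALL" context additionally n/6 per (context, label) cell.  When a
cell cannot meet its quota every quota shrinks to the minimum availability so
the output stays balanced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .methylome import (
    METHYLATED,
    UNKNOWN,
    CytosineRecord,
    GenomeSequence,
    MethylationCallSet,
)
from .tracks import TRACK_NAMES, AnnotationTrackSet

ALL_CONTEXTS = "ALL"
DEFAULT_WINDOW_SIZE = 3200
DEFAULT_NEIGHBOR_COUNT = 20
DEFAULT_SEQUENCE_N = 500_000
DEFAULT_NEIGHBOR_N = 50_000

# base -> one-hot column; N has no column (all-zero row)
_BASE_CODE = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
# complement in code space: A<->T, C<->G, N fixed
_CODE_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


class WindowOutOfBounds(ValueError):
    """Window around the candidate does not fit inside the chromosome."""


class NeighborsUnavailable(ValueError):
    """Too few covered cytosines on one side of the candidate."""


Center = Tuple[str, int, str, str]  # chrom, pos, strand, context


@dataclass(frozen=True)
class EncodedWindow:
    matrix: np.ndarray  # (W_s, 4 + a) uint8
    label: int
    center: Center
    sequence: str  # oriented window sequence, key for dedup

    def __post_init__(self) -> None:
        if self.matrix[:, :4].sum(axis=1).max(initial=0) > 1:
            raise ValueError("one-hot rows must have at most a single 1")


@dataclass(frozen=True)
class NeighborVector:
    values: np.ndarray  # (W_p,) float64 levels in [0, 1]
    label: int
    center: Center


@dataclass
class Dataset:
    """Stacked example arrays: X windows and/or V neighbor vectors."""

    y: np.ndarray
    centers: List[Center]
    keys: List[str]
    X: Optional[np.ndarray] = None
    V: Optional[np.ndarray] = None

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            y=self.y[idx],
            centers=[self.centers[i] for i in idx],
            keys=[self.keys[i] for i in idx],
            X=None if self.X is None else self.X[idx],
            V=None if self.V is None else self.V[idx],
        )


@dataclass
class DatasetSplit:
    train: Dataset
    validation: Dataset
    test: Dataset
    seed: int


def sequence_codes(genome: GenomeSequence) -> np.ndarray:
    """Chromosome as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    raw = np.frombuffer(genome.seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def encode_window(genomes: Mapping[str, GenomeSequence],
                  tracks: Optional[AnnotationTrackSet],
                  center: CytosineRecord | Center,
                  W_s: int,
                  label: Optional[int] = None) -> EncodedWindow:
    """Encode the ``W_s`` window centered on one cytosine.

    Raises :class:`WindowOutOfBounds` when the window would run off the
    chromosome (candidates are rejected, never padded).
    """
    if W_s % 2:
        raise ValueError("window size must be even")
    if isinstance(center, CytosineRecord):
        if center.status == UNKNOWN:
            raise ValueError("center cytosine has unknown status")
        if label is None:
            label = int(center.status == METHYLATED)
        center_key: Center = (center.chrom, center.pos, center.strand,
                              center.context)
    else:
        center_key = tuple(center)  # type: ignore[assignment]
        if label is None:
            raise ValueError("label required when center is a bare tuple")
    chrom, pos, strand = center_key[0], center_key[1], center_key[2]
    genome = genomes[chrom]
    half = W_s // 2
    start, stop = pos - half, pos + half
    if start < 0 or stop > len(genome):
        raise WindowOutOfBounds(
            f"window [{start}, {stop}) outside {chrom} (len {len(genome)})")

    codes = sequence_codes(genome)[start:stop]
    ann = tracks.matrix(chrom)[start:stop] if tracks is not None else None
    if strand == "-":
        codes = _CODE_COMPLEMENT[codes][::-1]
        if ann is not None:
            ann = ann[::-1][:, [1, 0, 2]]  # swap gene_fwd/gene_rev
    onehot = (codes[:, None] == np.arange(4, dtype=np.uint8)).astype(np.uint8)
    matrix = onehot if ann is None else np.concatenate([onehot, ann], axis=1)
    sequence = _CODE_TO_BASE[codes].tobytes().decode("ascii")
    return EncodedWindow(matrix=matrix, label=int(label), center=center_key,
                         sequence=sequence)


def encode_windows(genomes: Mapping[str, GenomeSequence],
                   tracks: Optional[AnnotationTrackSet],
                   centers: Sequence[CytosineRecord],
                   W_s: int) -> Dataset:
    """Vectorized batch encoding; all windows must fit (pre-filter centers)."""
    if W_s % 2:
        raise ValueError("window size must be even")
    half = W_s // 2
    a = 0 if tracks is None else tracks.a
    n = len(centers)
    X = np.empty((n, W_s, 4 + a), dtype=np.uint8)
    y = np.empty(n, dtype=np.uint8)
    keys: List[str] = []
    center_keys: List[Center] = []
    code_cache: Dict[str, np.ndarray] = {}
    ann_cache: Dict[str, np.ndarray] = {}
    for i, rec in enumerate(centers):
        if rec.chrom not in code_cache:
            code_cache[rec.chrom] = sequence_codes(genomes[rec.chrom])
            if tracks is not None:
                ann_cache[rec.chrom] = tracks.matrix(rec.chrom)
        start, stop = rec.pos - half, rec.pos + half
        if start < 0 or stop > len(genomes[rec.chrom]):
            raise WindowOutOfBounds(f"window around {rec.key} does not fit")
        codes = code_cache[rec.chrom][start:stop]
        ann = ann_cache[rec.chrom][start:stop] if tracks is not None else None
        if rec.strand == "-":
            codes = _CODE_COMPLEMENT[codes][::-1]
            if ann is not None:
                ann = ann[::-1][:, [1, 0, 2]]
        X[i, :, :4] = codes[:, None] == np.arange(4, dtype=np.uint8)
        if ann is not None:
            X[i, :, 4:] = ann
        y[i] = rec.status == METHYLATED
        keys.append(_CODE_TO_BASE[codes].tobytes().decode("ascii"))
        center_keys.append((rec.chrom, rec.pos, rec.strand, rec.context))
    return Dataset(y=y, centers=center_keys, keys=keys, X=X)


class NeighborIndex:
    """Sorted per-chromosome positions and levels of covered cytosines."""

    def __init__(self, calls: MethylationCallSet) -> None:
        per_chrom: Dict[str, List[Tuple[int, float]]] = {}
        for rec in calls:
            if rec.status != UNKNOWN:
                per_chrom.setdefault(rec.chrom, []).append(
                    (rec.pos, rec.level))
        self.positions: Dict[str, np.ndarray] = {}
        self.levels: Dict[str, np.ndarray] = {}
        for chrom, pairs in per_chrom.items():
            pairs.sort()
            arr = np.array(pairs, dtype=np.float64)
            self.positions[chrom] = arr[:, 0].astype(np.int64)
            self.levels[chrom] = arr[:, 1]

    def vector(self, chrom: str, pos: int, W_p: int) -> Optional[np.ndarray]:
        """Levels of the W_p/2 nearest covered cytosines per side, or None."""
        half = W_p // 2
        positions = self.positions.get(chrom)
        if positions is None:
            return None
        lo = np.searchsorted(positions, pos, side="left")
        hi = np.searchsorted(positions, pos, side="right")
        if lo < half or len(positions) - hi < half:
            return None
        levels = self.levels[chrom]
        return np.concatenate([levels[lo - half:lo], levels[hi:hi + half]])


def build_neighbor_vector(calls: MethylationCallSet,
                          center: CytosineRecord,
                          W_p: int = DEFAULT_NEIGHBOR_COUNT,
                          index: Optional[NeighborIndex] = None,
                          ) -> NeighborVector:
    """Neighbor-level vector for one center; raises on insufficient coverage."""
    if W_p % 2:
        raise ValueError("neighbor count must be even")
    if center.status == UNKNOWN:
        raise ValueError("center cytosine has unknown status")
    if index is None:
        index = NeighborIndex(calls)
    values = index.vector(center.chrom, center.pos, W_p)
    if values is None:
        raise NeighborsUnavailable(
            f"fewer than {W_p // 2} covered cytosines on one side of "
            f"{center.key}")
    return NeighborVector(values=values, label=int(center.status == METHYLATED),
                          center=(center.chrom, center.pos, center.strand,
                                  center.context))


def sample_balanced(calls: MethylationCallSet,
                    context: str,
                    n: int,
                    seed: int,
                    eligible=None) -> List[CytosineRecord]:
    """Draw a balanced list of center cytosines, reproducible under ``seed``.

    Single context: n/2 methylated + n/2 unmethylated, drawn uniformly
    without replacement.  ``ALL``: n/6 per (context, label) cell.  Quotas
    shrink together to the minimum cell availability; an empty required cell
    raises.
    """
    contexts = ("CG", "CHG", "CHH") if context == ALL_CONTEXTS else (context,)
    if context == ALL_CONTEXTS:
        if n % 6:
            raise ValueError("n must be divisible by 6 for the ALL context")
        quota = n // 6
    else:
        if n % 2:
            raise ValueError("n must be even")
        quota = n // 2

    cells: Dict[Tuple[str, int], List[CytosineRecord]] = {
        (ctx, lab): [] for ctx in contexts for lab in (0, 1)}
    for rec in sorted(calls, key=lambda r: (r.chrom, r.pos, r.strand)):
        if rec.status == UNKNOWN or rec.context not in contexts:
            continue
        if eligible is not None and not eligible(rec):
            continue
        cells[(rec.context, int(rec.status == METHYLATED))].append(rec)

    for key, members in cells.items():
        if not members:
            raise ValueError(f"no eligible examples in cell {key}")
    quota = min(quota, *(len(m) for m in cells.values()))

    rng = np.random.default_rng(seed)
    chosen: List[CytosineRecord] = []
    for key in sorted(cells):
        members = cells[key]
        idx = rng.choice(len(members), size=quota, replace=False)
        chosen.extend(members[i] for i in idx)
    return chosen


def split_80_10_10(dataset: Dataset, seed: int) -> DatasetSplit:
    """Deduplicate, then partition 80/10/10 stratified by label."""
    if len(dataset) < 10:
        raise ValueError("need at least 10 examples to split")
    seen: set = set()
    keep: List[int] = []
    for i, key in enumerate(dataset.keys):
        if key not in seen:
            seen.add(key)
            keep.append(i)
    dataset = dataset.subset(np.array(keep, dtype=np.int64))

    rng = np.random.default_rng(seed)
    train_idx: List[np.ndarray] = []
    val_idx: List[np.ndarray] = []
    test_idx: List[np.ndarray] = []
    for label in (0, 1):
        idx = np.flatnonzero(dataset.y == label)
        rng.shuffle(idx)
        n = len(idx)
        n_val = round(n * 0.1)
        n_test = round(n * 0.1)
        val_idx.append(idx[:n_val])
        test_idx.append(idx[n_val:n_val + n_test])
        train_idx.append(idx[n_val + n_test:])
    train = np.concatenate(train_idx)
    val = np.concatenate(val_idx)
    test = np.concatenate(test_idx)
    rng.shuffle(train)
    rng.shuffle(val)
    rng.shuffle(test)
    return DatasetSplit(train=dataset.subset(train),
                        validation=dataset.subset(val),
                        test=dataset.subset(test), seed=seed)


def save_dataset(dataset: Dataset, path) -> None:
    """Serialize to .npz (arrays plus centers/keys as string arrays)."""
    import json

    centers = json.dumps(dataset.centers)
    arrays = {"y": dataset.y,
              "centers": np.frombuffer(centers.encode(), dtype=np.uint8),
              "keys": np.array(dataset.keys)}
    if dataset.X is not None:
        arrays["X"] = dataset.X
    if dataset.V is not None:
        arrays["V"] = dataset.V
    np.savez_compressed(path, **arrays)


def load_dataset(path) -> Dataset:
    import json

    data = np.load(path, allow_pickle=False)
    centers = [tuple(c) for c in
               json.loads(data["centers"].tobytes().decode())]
    return Dataset(y=data["y"], centers=centers,
                   keys=[str(k) for k in data["keys"]],
                   X=data["X"] if "X" in data else None,
                   V=data["V"] if "V" in data else None)


def _window_fits(rec: CytosineRecord,
                 genomes: Mapping[str, GenomeSequence], half: int) -> bool:
    return rec.pos >= half and rec.pos + half <= len(genomes[rec.chrom])


def build_sequence_dataset(genomes: Mapping[str, GenomeSequence],
                           tracks: Optional[AnnotationTrackSet],
                           calls: MethylationCallSet,
                           context: str,
                           n: int,
                           W_s: int = DEFAULT_WINDOW_SIZE,
                           seed: int = 0) -> Dataset:
    """Balanced encoded-window dataset (annotations included iff ``tracks``)."""
    half = W_s // 2
    centers = sample_balanced(
        calls, context, n, seed,
        eligible=lambda rec: _window_fits(rec, genomes, half))
    return encode_windows(genomes, tracks, centers, W_s)


def build_neighbor_dataset(calls: MethylationCallSet,
                           context: str,
                           n: int,
                           W_p: int = DEFAULT_NEIGHBOR_COUNT,
                           seed: int = 0) -> Dataset:
    """Balanced neighbor-level dataset."""
    index = NeighborIndex(calls)
    centers = sample_balanced(
        calls, context, n, seed,
        eligible=lambda rec: index.vector(rec.chrom, rec.pos, W_p) is not None)
    V = np.stack([index.vector(rec.chrom, rec.pos, W_p) for rec in centers])
    y = np.array([rec.status == METHYLATED for rec in centers], dtype=np.uint8)
    keys = [v.tobytes().hex() for v in V]
    center_keys = [(r.chrom, r.pos, r.strand, r.context) for r in centers]
    return Dataset(y=y, centers=center_keys, keys=keys, V=V)


def build_combined_dataset(genomes: Mapping[str, GenomeSequence],
                           tracks: Optional[AnnotationTrackSet],
                           calls: MethylationCallSet,
                           context: str,
                           n: int,
                           W_s: int = DEFAULT_WINDOW_SIZE,
                           W_p: int = DEFAULT_NEIGHBOR_COUNT,
                           seed: int = 0) -> Dataset:
    """Windows plus neighbor vectors for the combined classifier."""
    half = W_s // 2
    index = NeighborIndex(calls)
    centers = sample_balanced(
        calls, context, n, seed,
        eligible=lambda rec: (_window_fits(rec, genomes, half)
                              and index.vector(rec.chrom, rec.pos, W_p)
                              is not None))
    dataset = encode_windows(genomes, tracks, centers, W_s)
    dataset.V = np.stack([index.vector(rec.chrom, rec.pos, W_p)
                          for rec in centers])
    return dataset
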