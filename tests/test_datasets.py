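import numpy as np
import pytest

from amps import datasets
from amps.datasets import (
    NeighborIndex,
    NeighborsUnavailable,
    WindowOutOfBounds,
    build_neighbor_dataset,
    build_neighbor_vector,
    build_sequence_dataset,
    encode_window,
    encode_windows,
    sample_balanced,
    split_80_10_10,
)
from amps.methylome import (
    UNKNOWN,
    CytosineRecord,
    GenomeSequence,
    MethylationCallSet,
    reverse_complement,
)
from amps.tracks import FeatureInterval, build_tracks

from conftest import random_genome


def callset_on(seq, records):
    genomes = {"chr1": GenomeSequence("chr1", seq)}
    return genomes, MethylationCallSet(genomes, records)


class TestEncodeWindow:
    def test_one_hot_identity(self):
        # minus-strand center over the palindrome ACGT: oriented slice reads
        # ACGT again, so the one-hot block is the 4x4 identity
        genomes = {"chr1": GenomeSequence("chr1", "ACGT")}
        win = encode_window(genomes, None, ("chr1", 2, "-", "CG"), 4, label=1)
        assert (win.matrix == np.eye(4, dtype=np.uint8)).all()
        assert win.sequence == "ACGT"

    def test_plus_strand_rows_follow_genome(self):
        genomes = {"chr1": GenomeSequence("chr1", "AACGTA")}
        win = encode_window(genomes, None, ("chr1", 2, "+", "CG"), 4, label=0)
        assert win.sequence == "AACG"
        expected = np.array([[1, 0, 0, 0], [1, 0, 0, 0],
                             [0, 1, 0, 0], [0, 0, 1, 0]], dtype=np.uint8)
        assert (win.matrix == expected).all()

    def test_n_row_all_zero(self):
        genomes = {"chr1": GenomeSequence("chr1", "ANCGTA")}
        win = encode_window(genomes, None, ("chr1", 2, "+", "CG"), 4, label=0)
        assert win.matrix[1].sum() == 0

    def test_minus_window_is_reverse_complement_of_slice(self):
        genome = random_genome(60, 3)
        genomes = {"chr1": genome}
        pos = next(p for p in range(20, 40) if genome.seq[p] == "G")
        win = encode_window(genomes, None, ("chr1", pos, "-", "CHH"),
                            20, label=1)
        expected = reverse_complement(genome.seq[pos - 10:pos + 10])
        assert win.sequence == expected
        for row, base in zip(win.matrix, expected):
            target = np.zeros(4, dtype=np.uint8)
            if base != "N":
                target["ACGT".index(base)] = 1
            assert (row == target).all()

    def test_annotation_channels_copied(self):
        genomes = {"chr1": GenomeSequence("chr1", "AACGTAAA")}
        tracks = build_tracks([FeatureInterval("chr1", 0, 3, "+", "gene"),
                               FeatureInterval("chr1", 3, 6, "-", "gene"),
                               FeatureInterval("chr1", 2, 4, ".", "repeat")],
                              genomes)
        win = encode_window(genomes, tracks, ("chr1", 2, "+", "CG"), 4, label=0)
        assert win.matrix.shape == (4, 7)
        assert (win.matrix[:, 4] == [1, 1, 1, 0]).all()  # gene_fwd 0..2
        assert (win.matrix[:, 5] == [0, 0, 0, 1]).all()  # gene_rev 3..5
        assert (win.matrix[:, 6] == [0, 0, 1, 1]).all()  # repeat 2..3

    def test_minus_strand_swaps_gene_channels(self):
        genomes = {"chr1": GenomeSequence("chr1", "AACGTAAA")}
        tracks = build_tracks([FeatureInterval("chr1", 0, 3, "+", "gene")],
                              genomes)
        win = encode_window(genomes, tracks, ("chr1", 3, "-", "CG"), 4, label=0)
        # window [1,5) reversed to genomic rows 4,3,2,1; plus-gene bits at
        # genomic 1,2 land in the gene_rev column
        assert win.matrix[:, 4].sum() == 0
        assert (win.matrix[:, 5] == [0, 0, 1, 1]).all()

    def test_out_of_bounds_rejected(self):
        genomes = {"chr1": GenomeSequence("chr1", "AACGTA")}
        with pytest.raises(WindowOutOfBounds):
            encode_window(genomes, None, ("chr1", 2, "+", "CG"), 8, label=0)

    def test_decode_recovers_genome_slice(self):
        genome = random_genome(300, 7)
        genomes = {"chr1": genome}
        recs = [CytosineRecord("chr1", p, "+", "CHH", 12, 12)
                for p in range(100, 200) if genome.seq[p] == "C"][:5]
        ds = encode_windows(genomes, None, recs, 40)
        for i, rec in enumerate(recs):
            decoded = ds.keys[i]
            assert decoded == genome.seq[rec.pos - 20:rec.pos + 20]
            onehot = ds.X[i, :, :4]
            recovered = "".join("ACGT"[j] if onehot[r].sum() else "N"
                                for r, j in enumerate(onehot.argmax(axis=1)))
            assert recovered == decoded


class TestNeighborVector:
    def make_calls(self):
        seq = "C" * 200
        records = [
            CytosineRecord("chr1", 50, "+", "CHH", 2, 20),    # 0.1
            CytosineRecord("chr1", 90, "+", "CHH", 18, 20),   # 0.9
            CytosineRecord("chr1", 100, "+", "CHH", 15, 20),  # center
            CytosineRecord("chr1", 105, "+", "CHH", 4, 20),   # 0.2
            CytosineRecord("chr1", 130, "+", "CHH", 16, 20),  # 0.8
            CytosineRecord("chr1", 160, "+", "CHH", 1, 5),    # uncovered
        ]
        return callset_on(seq, records)

    def test_ordering(self):
        _, calls = self.make_calls()
        center = calls.get("chr1", 100, "+")
        nv = build_neighbor_vector(calls, center, W_p=4)
        assert np.allclose(nv.values, [0.1, 0.9, 0.2, 0.8])
        assert nv.label == 1

    def test_insufficient_side_rejected(self):
        _, calls = self.make_calls()
        center = calls.get("chr1", 100, "+")
        with pytest.raises(NeighborsUnavailable):
            build_neighbor_vector(calls, center, W_p=6)

    def test_unknown_center_rejected(self):
        _, calls = self.make_calls()
        center = calls.get("chr1", 160, "+")
        with pytest.raises(ValueError):
            build_neighbor_vector(calls, center, W_p=2)

    def test_index_excludes_unknown(self, small_calls):
        index = NeighborIndex(small_calls)
        covered = {(r.chrom, r.pos) for r in small_calls
                   if r.status != UNKNOWN}
        for chrom, positions in index.positions.items():
            assert set((chrom, int(p)) for p in positions) == \
                {(c, p) for c, p in covered if c == chrom}

    def test_default_is_ten_per_side(self):
        assert datasets.DEFAULT_NEIGHBOR_COUNT == 20


class TestSampleBalanced:
    def test_single_context_even_split(self, small_calls):
        centers = sample_balanced(small_calls, "CG", 100, seed=1)
        labels = [c.status == "methylated" for c in centers]
        assert len(centers) == 100
        assert sum(labels) == 50

    def test_all_context_cells(self, small_calls):
        centers = sample_balanced(small_calls, "ALL", 90, seed=1)
        assert len(centers) == 90
        for ctx in ("CG", "CHG", "CHH"):
            members = [c for c in centers if c.context == ctx]
            assert len(members) == 30
            assert sum(c.status == "methylated" for c in members) == 15

    def test_shrink_to_availability(self):
        seq = "C" * 400
        records = [CytosineRecord("chr1", p, "+", "CHH",
                                  20 if p < 30 else 0, 20)
                   for p in range(0, 398)]
        _, calls = callset_on(seq, records)
        centers = sample_balanced(calls, "CHH", 100, seed=0)
        assert len(centers) == 60
        assert sum(c.status == "methylated" for c in centers) == 30

    def test_empty_cell_raises(self):
        seq = "C" * 100
        records = [CytosineRecord("chr1", p, "+", "CHH", 20, 20)
                   for p in range(0, 98)]
        _, calls = callset_on(seq, records)
        with pytest.raises(ValueError, match="cell"):
            sample_balanced(calls, "CHH", 10, seed=0)

    def test_reproducible(self, small_calls):
        a = sample_balanced(small_calls, "CG", 60, seed=7)
        b = sample_balanced(small_calls, "CG", 60, seed=7)
        assert [r.key for r in a] == [r.key for r in b]

    def test_odd_n_rejected(self, small_calls):
        with pytest.raises(ValueError):
            sample_balanced(small_calls, "CG", 99, seed=0)
        with pytest.raises(ValueError):
            sample_balanced(small_calls, "ALL", 100, seed=0)


def toy_dataset(n, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2).astype(np.uint8)
    X = rng.integers(0, 2, size=(n, 8, 4)).astype(np.uint8)
    keys = [f"seq{i}" for i in range(n)]
    centers = [("chr1", i, "+", "CG") for i in range(n)]
    return datasets.Dataset(y=y, centers=centers, keys=keys, X=X)


class TestSplit:
    def test_sizes(self):
        split = split_80_10_10(toy_dataset(1000), seed=1)
        assert (len(split.train), len(split.validation), len(split.test)) == \
            (800, 100, 100)

    def test_stratified(self):
        split = split_80_10_10(toy_dataset(1000), seed=1)
        for part in (split.train, split.validation, split.test):
            assert part.y.mean() == 0.5

    def test_duplicates_removed(self):
        ds = toy_dataset(100)
        ds.keys[5] = ds.keys[3]
        split = split_80_10_10(ds, seed=1)
        total = len(split.train) + len(split.validation) + len(split.test)
        assert total == 99
        all_keys = split.train.keys + split.validation.keys + split.test.keys
        assert len(set(all_keys)) == len(all_keys)

    def test_no_center_shared_across_partitions(self):
        split = split_80_10_10(toy_dataset(200), seed=2)
        parts = [set(map(tuple, p.centers))
                 for p in (split.train, split.validation, split.test)]
        assert not (parts[0] & parts[1] or parts[0] & parts[2]
                    or parts[1] & parts[2])

    def test_deterministic(self):
        s1 = split_80_10_10(toy_dataset(300), seed=9)
        s2 = split_80_10_10(toy_dataset(300), seed=9)
        assert s1.train.centers == s2.train.centers
        assert (s1.train.y == s2.train.y).all()

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            split_80_10_10(toy_dataset(8), seed=0)


class TestBuilders:
    def test_sequence_dataset_balanced(self, small_bundle):
        ds = build_sequence_dataset(small_bundle.genomes,
                                    small_bundle.annotation_tracks(),
                                    small_bundle.calls, "ALL", 600,
                                    W_s=64, seed=5)
        assert len(ds) == 600
        assert ds.y.mean() == 0.5
        assert ds.X.shape == (600, 64, 7)

    def test_sequence_dataset_windows_fit(self, small_bundle):
        ds = build_sequence_dataset(small_bundle.genomes, None,
                                    small_bundle.calls, "CG", 100,
                                    W_s=128, seed=5)
        half = 64
        length = len(small_bundle.genomes["chr1"])
        for chrom, pos, strand, ctx in ds.centers:
            assert half <= pos <= length - half

    def test_neighbor_dataset(self, small_bundle):
        ds = build_neighbor_dataset(small_bundle.calls, "CG", 200, W_p=10,
                                    seed=3)
        assert ds.V.shape == (200, 10)
        assert ds.y.mean() == 0.5
        assert (ds.V >= 0).all() and (ds.V <= 1).all()

    def test_save_load_round_trip(self, small_bundle, tmp_path):
        ds = build_sequence_dataset(small_bundle.genomes, None,
                                    small_bundle.calls, "CG", 50, W_s=32,
                                    seed=1)
        path = tmp_path / "ds.npz"
        datasets.save_dataset(ds, path)
        again = datasets.load_dataset(path)
        assert (again.X == ds.X).all()
        assert (again.y == ds.y).all()
        assert again.keys == ds.keys
        assert again.centers == ds.centers
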