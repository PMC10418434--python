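import numpy as np
import pandas as pd
import pytest

from deepsata.dataset import (
    Dataset,
    extract_window,
    label_bins,
    load_dataset,
    make_bins,
    partition_and_sample,
    prepare_dataset,
    save_dataset,
    select_ocbs,
    split_by_chromosome,
)
from deepsata.formats import Interval


class TestMakeBins:
    @pytest.mark.parametrize(
        "length,n_expected",
        [(1000, 5), (1050, 5), (150, 0), (200, 1)],
    )
    def test_bin_census(self, length, n_expected):
        bins = make_bins({"c1": "A" * length})
        assert len(bins) == n_expected
        if n_expected:
            assert bins["start"].iloc[0] == 0
            assert (bins["end"] - bins["start"] == 200).all()


class TestLabelBins:
    def _label(self, peaks):
        bins = make_bins({"c1": "A" * 200})
        labels, feats = label_bins(bins, {"f": peaks})
        return labels[0, 0]

    def test_overlap_above_half_is_open(self):
        assert self._label([Interval("c1", 0, 150, "f")]) == 1

    def test_overlap_exactly_half_is_closed(self):
        # "more than half" is strict: 100 of 200 bp is not enough
        assert self._label([Interval("c1", 0, 100, "f")]) == 0

    def test_disjoint_peaks_sum_their_overlap(self):
        assert self._label([Interval("c1", 0, 60, "f"), Interval("c1", 120, 200, "f")]) == 1

    def test_matches_interval_oracle(self, rng):
        genome = {"c1": "A" * 2000, "c2": "A" * 1400}
        bins = make_bins(genome)
        peaks = []
        for _ in range(15):
            chrom = "c1" if rng.random() < 0.6 else "c2"
            start = int(rng.integers(0, len(genome[chrom]) - 50))
            end = start + int(rng.integers(30, 400))
            peaks.append(Interval(chrom, start, min(end, len(genome[chrom])), "f"))
        labels, _ = label_bins(bins, {"f": peaks})
        # oracle: per-base coverage counting
        for i, row in bins.iterrows():
            cov = np.zeros(200, dtype=bool)
            for p in peaks:
                if p.chrom != row.chrom:
                    continue
                lo = max(p.start, row.start) - row.start
                hi = min(p.end, row.end) - row.start
                if hi > lo:
                    cov[lo:hi] = True
            assert labels[i, 0] == int(cov.sum() > 100)

    def test_invariant_to_peak_order(self, rng):
        genome = {"c1": "A" * 2000}
        bins = make_bins(genome)
        peaks = [Interval("c1", int(s), int(s) + 120, "f") for s in rng.integers(0, 1800, 8)]
        l1, _ = label_bins(bins, {"f": peaks})
        l2, _ = label_bins(bins, {"f": peaks[::-1]})
        np.testing.assert_array_equal(l1, l2)


class TestSelectOcbs:
    def test_retained_iff_any_positive(self):
        labels = np.array([[1, 0, 0], [0, 0, 0], [0, 1, 1]], dtype=np.int8)
        bins = pd.DataFrame({"chrom": ["c1"] * 3, "start": [0, 200, 400], "end": [200, 400, 600]})
        keep = select_ocbs(bins, labels)
        np.testing.assert_array_equal(keep, [0, 2])

    def test_count_matches_brute_force(self, rng):
        labels = (rng.random((100, 3)) < 0.2).astype(np.int8)
        bins = pd.DataFrame({"chrom": "c1", "start": np.arange(100) * 200, "end": np.arange(1, 101) * 200})
        keep = select_ocbs(bins, labels)
        assert len(keep) == sum(1 for row in labels if row.sum() > 0)


class TestExtractWindow:
    def test_interior_bin(self):
        genome = {"c1": "".join("ACGT"[i % 4] for i in range(2000))}
        w = extract_window(genome, "c1", 400, 600)
        assert w == genome["c1"][0:1000]

    def test_left_edge_padded(self):
        genome = {"c1": "A" * 2000}
        w = extract_window(genome, "c1", 0, 200)
        assert w.startswith("N" * 400) and len(w) == 1000

    def test_window_always_1000(self):
        genome = {"c1": "A" * 300}
        w = extract_window(genome, "c1", 0, 200)
        assert len(w) == 1000
        # left pad 400, genome 300, right pad 300
        assert w == "N" * 400 + genome["c1"] + "N" * 300


class TestSplit:
    def _ds(self, chroms):
        bins = pd.DataFrame(
            {"chrom": chroms, "start": np.zeros(len(chroms), dtype=int),
             "end": np.full(len(chroms), 200)}
        )
        return Dataset(bins, np.ones((len(chroms), 1), dtype=np.int8), ["f"])

    def test_chr1_val_chr23_test_rest_train(self):
        ds = self._ds(["chr1", "chr2", "chr3", "chr4"])
        split = split_by_chromosome(ds)
        assert list(split.validation.bins["chrom"]) == ["chr1"]
        assert sorted(split.test.bins["chrom"]) == ["chr2", "chr3"]
        assert list(split.train.bins["chrom"]) == ["chr4"]

    def test_missing_designated_chromosomes_error(self):
        with pytest.raises(ValueError, match="empty"):
            split_by_chromosome(self._ds(["chr5", "chr5"]))

    def test_partition_is_disjoint_and_exhaustive(self):
        chroms = ["chr%d" % (i % 5 + 1) for i in range(40)]
        ds = self._ds(chroms)
        split = split_by_chromosome(ds)
        n = len(split.train) + len(split.validation) + len(split.test)
        assert n == len(ds)

    def test_explicit_role_mapping(self):
        ds = self._ds(["scaffoldA", "scaffoldB", "scaffoldC"])
        split = split_by_chromosome(
            ds, chrom_roles={"scaffoldA": "validation", "scaffoldB": "test", "scaffoldC": "train"}
        )
        assert list(split.validation.bins["chrom"]) == ["scaffoldA"]


class TestPartitionAndSample:
    def test_round_robin_partition(self):
        sel, assign = partition_and_sample(100, k=10, seed=0)
        assert len(sel) == 10
        counts = np.bincount(assign, minlength=10)
        assert (counts == 10).all()

    def test_k_one_is_identity(self):
        sel, _ = partition_and_sample(7, k=1, seed=0)
        np.testing.assert_array_equal(sel, np.arange(7))

    def test_same_seed_same_partition(self):
        s1, a1 = partition_and_sample(50, k=10, seed=7)
        s2, a2 = partition_and_sample(50, k=10, seed=7)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(a1, a2)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            partition_and_sample(5, k=10, seed=0)


class TestPrepare:
    def _toy(self):
        rng = np.random.default_rng(1)
        genome = {f"chr{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 3000)) for i in range(1, 5)}
        peaks = {
            "tA": [Interval("chr1", 0, 400, "tA"), Interval("chr4", 600, 1000, "tA"),
                   Interval("chr2", 200, 600, "tA"), Interval("chr3", 0, 200, "tA")],
            "tB": [Interval("chr4", 0, 200, "tB"), Interval("chr1", 2000, 2400, "tB"),
                   Interval("chr2", 0, 200, "tB"), Interval("chr3", 400, 800, "tB")],
        }
        return genome, peaks

    def test_every_kept_bin_is_open_somewhere(self):
        genome, peaks = self._toy()
        ds, split = prepare_dataset(genome, peaks)
        assert (ds.labels.sum(axis=1) > 0).all()
        assert all(len(w) == 1000 for w in ds.windows)

    def test_save_load_round_trip(self, tmp_path):
        genome, peaks = self._toy()
        ds, _ = prepare_dataset(genome, peaks)
        p = tmp_path / "ds.npz"
        save_dataset(ds, p)
        back = load_dataset(p)
        pd.testing.assert_frame_equal(back.bins, ds.bins)
        np.testing.assert_array_equal(back.labels, ds.labels)
        assert back.windows == ds.windows
        assert back.features == ds.features

    def test_subsampling_takes_one_partition(self):
        genome, peaks = self._toy()
        full, _ = prepare_dataset(genome, peaks)
        sub, _ = prepare_dataset(genome, peaks, subsample_k=2, seed=3, split=False)
        assert len(sub) == pytest.approx(len(full) / 2, abs=1)
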