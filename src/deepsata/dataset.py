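"""Genome binning, peak-overlap labeling, OCB selection and dataset splits.

The genome is partitioned into consecutive 200 bp bins; a bin is labeled
open (1) for a chromatin feature when more than half of its length falls
inside that feature's peak regions.  Only open chromatin bins (OCBs) — bins
open in at least one feature — are retained for training; their zeros in
other features serve as the negatives.  Each retained bin carries a 1000 bp
window (the bin plus 400 bp flanks, N-padded at chromosome edges).

Splits are chromosome-based: chromosome 1 is the validation set,
chromosomes 2 and 3 the test set, and all remaining chromosomes the
training set.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import GenomeSequence, Interval, merge_intervals

logger = logging.getLogger(__name__)

BIN_SIZE = 200
WINDOW_SIZE = 1000
FLANK = (WINDOW_SIZE - BIN_SIZE) // 2


@dataclass
class LabeledBin:
    chrom: str
    start: int
    end: int
    labels: np.ndarray
    window_seq: str

    def __post_init__(self) -> None:
        if self.end - self.start != BIN_SIZE:
            raise ValueError("bin must be exactly 200 bp")
        if len(self.window_seq) != WINDOW_SIZE:
            raise ValueError("window must be exactly 1000 bp")


@dataclass
class Dataset:
    """A collection of labeled bins with their 1000 bp windows."""

    bins: pd.DataFrame           # columns chrom, start, end
    labels: np.ndarray           # (n_bins, n_features) in {0,1}
    features: list[str]
    windows: list[str] | None = None

    def __len__(self) -> int:
        return len(self.bins)

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            self.bins.iloc[idx].reset_index(drop=True),
            self.labels[idx],
            list(self.features),
            [self.windows[i] for i in idx] if self.windows is not None else None,
        )

    def to_labeled_bins(self) -> list[LabeledBin]:
        if self.windows is None:
            raise ValueError("windows not extracted yet")
        return [
            LabeledBin(r.chrom, int(r.start), int(r.end), self.labels[i], self.windows[i])
            for i, r in enumerate(self.bins.itertuples())
        ]


@dataclass
class DatasetSplit:
    train: Dataset
    validation: Dataset
    test: Dataset


def _genome_mapping(genome) -> dict[str, str]:
    if isinstance(genome, Mapping):
        return dict(genome)
    return {g.name: g.sequence for g in genome}


def make_bins(genome, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Consecutive non-overlapping bins from position 0; a trailing remainder
    shorter than the bin size is dropped."""
    seqs = _genome_mapping(genome)
    frames = []
    for chrom, seq in seqs.items():
        n = len(seq) // bin_size
        if n == 0:
            continue
        starts = np.arange(n) * bin_size
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + bin_size}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def label_bins(
    bins: pd.DataFrame,
    peak_sets: Mapping[str, Sequence[Interval]],
    bin_size: int = BIN_SIZE,
) -> tuple[np.ndarray, list[str]]:
    """Binary labels per (bin, feature): 1 iff the bin's total overlap with
    the feature's merged peaks strictly exceeds half the bin size."""
    features = list(peak_sets)
    n_bins = len(bins)
    labels = np.zeros((n_bins, len(features)), dtype=np.int8)
    # per-chromosome bin bookkeeping: row index of bin number b on chrom
    chrom_rows: dict[str, np.ndarray] = {}
    for chrom, grp in bins.groupby("chrom", sort=False):
        order = grp["start"].to_numpy() // bin_size
        rows = np.full(order.max() + 1 if len(order) else 0, -1, dtype=np.int64)
        rows[order] = grp.index.to_numpy()
        chrom_rows[chrom] = rows
    for f, feat in enumerate(features):
        overlap = np.zeros(n_bins, dtype=np.int64)
        for iv in merge_intervals(list(peak_sets[feat])):
            rows = chrom_rows.get(iv.chrom)
            if rows is None or len(rows) == 0:
                continue
            b_first = iv.start // bin_size
            b_last = min((iv.end - 1) // bin_size, len(rows) - 1)
            if b_first > b_last:
                continue
            bs = np.arange(b_first, b_last + 1)
            ov = np.minimum(iv.end, (bs + 1) * bin_size) - np.maximum(iv.start, bs * bin_size)
            valid = rows[bs] >= 0
            np.add.at(overlap, rows[bs[valid]], ov[valid])
        labels[:, f] = (overlap > bin_size // 2).astype(np.int8)
    return labels, features


def select_ocbs(bins: pd.DataFrame, labels: np.ndarray) -> np.ndarray:
    """Indices of open chromatin bins: open (label 1) in at least one feature."""
    return np.nonzero(labels.sum(axis=1) > 0)[0]


def extract_window(
    genome, chrom: str, start: int, end: int, flank: int = FLANK
) -> str:
    """The bin's sequence plus flanks; positions outside the chromosome are 'N'."""
    seqs = _genome_mapping(genome)
    seq = seqs[chrom]
    ws, we = start - flank, end + flank
    left_pad = max(0, -ws)
    right_pad = max(0, we - len(seq))
    core = seq[max(0, ws) : min(len(seq), we)]
    return "N" * left_pad + core + "N" * right_pad


def chromosome_index(name: str) -> int | None:
    m = re.search(r"(\d+)\s*$", name)
    return int(m.group(1)) if m else None


def split_by_chromosome(
    dataset: Dataset,
    validation_chroms: set[int] = frozenset({1}),
    test_chroms: set[int] = frozenset({2, 3}),
    chrom_roles: Mapping[str, str] | None = None,
) -> DatasetSplit:
    """Chromosome-based partition: chr1 validation, chr2+chr3 test, rest train.

    ``chrom_roles`` may map chromosome names directly to
    'train'/'validation'/'test' when names carry no numeric index.
    """
    roles = []
    for chrom in dataset.bins["chrom"]:
        if chrom_roles is not None:
            roles.append(chrom_roles[chrom])
            continue
        ci = chromosome_index(chrom)
        if ci is None:
            raise ValueError(f"chromosome {chrom!r} has no numeric index; supply chrom_roles")
        if ci in validation_chroms:
            roles.append("validation")
        elif ci in test_chroms:
            roles.append("test")
        else:
            roles.append("train")
    roles = np.array(roles)
    idx = {r: np.nonzero(roles == r)[0] for r in ("train", "validation", "test")}
    for r, ix in idx.items():
        if len(ix) == 0:
            raise ValueError(f"chromosome split produced an empty {r} set")
    return DatasetSplit(
        train=dataset.subset(idx["train"]),
        validation=dataset.subset(idx["validation"]),
        test=dataset.subset(idx["test"]),
    )


def partition_and_sample(
    n_bins: int, k: int = 10, seed: int = 0, index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deal bins into ``k`` disjoint sets (seeded shuffle, round-robin) and
    return (indices of set ``index``, full assignment vector)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_bins:
        raise ValueError(f"k={k} exceeds the number of bins ({n_bins})")
    if not (0 <= index < k):
        raise ValueError(f"partition index {index} out of range for k={k}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_bins)
    assignment = np.empty(n_bins, dtype=np.int64)
    assignment[perm] = np.arange(n_bins) % k
    selected = np.sort(perm[index::k])
    return selected, assignment


def prepare_dataset(
    genome,
    peak_sets: Mapping[str, Sequence[Interval]],
    bin_size: int = BIN_SIZE,
    include_closed_bins: bool = False,
    subsample_k: int | None = None,
    subsample_index: int = 0,
    seed: int = 0,
    split: bool = True,
) -> tuple[Dataset, DatasetSplit | None]:
    """Full preparation: bin, label, keep OCBs, optionally subsample one of
    k partitions, extract 1000 bp windows, and split by chromosome."""
    seqs = _genome_mapping(genome)
    bins = make_bins(seqs, bin_size)
    labels, features = label_bins(bins, peak_sets, bin_size)
    if include_closed_bins:
        keep = np.arange(len(bins))
    else:
        keep = select_ocbs(bins, labels)
    ds = Dataset(bins.iloc[keep].reset_index(drop=True), labels[keep], features)
    if subsample_k is not None and subsample_k > 1:
        sel, _ = partition_and_sample(len(ds), subsample_k, seed, subsample_index)
        ds = ds.subset(sel)
    ds.windows = [
        extract_window(seqs, r.chrom, int(r.start), int(r.end))
        for r in ds.bins.itertuples()
    ]
    return ds, (split_by_chromosome(ds) if split else None)


def save_dataset(ds: Dataset, path: str | Path) -> None:
    """Persist a dataset as an .npz container with a JSON manifest entry."""
    np.savez_compressed(
        path,
        chrom=np.array(ds.bins["chrom"], dtype="U32"),
        start=ds.bins["start"].to_numpy(),
        labels=ds.labels,
        windows=np.array(ds.windows if ds.windows is not None else [], dtype="U1000"),
        manifest=np.array(json.dumps({"features": ds.features}), dtype="U"),
    )


def load_dataset(path: str | Path) -> Dataset:
    with np.load(path, allow_pickle=False) as z:
        manifest = json.loads(str(z["manifest"]))
        chrom = z["chrom"]
        start = z["start"]
        bins = pd.DataFrame({"chrom": chrom, "start": start, "end": start + BIN_SIZE})
        windows = [str(w) for w in z["windows"]] if z["windows"].size else None
        return Dataset(bins, z["labels"], manifest["features"], windows)
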