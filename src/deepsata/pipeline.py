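"""Glue between motif scanning, datasets and the encoder.

Scanning whole chromosomes once and mapping hits into bin windows by
coordinate arithmetic is equivalent to scanning each 1000 bp window
separately (a hit must lie fully inside the window either way, and padded
N positions can never carry a hit), but avoids rescanning the heavily
overlapping windows of neighbouring bins.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Mapping, Sequence

import numpy as np

from .dataset import Dataset, FLANK
from .encoding import encode_windows
from .motifs import Motif, MotifHit, MotifScanner, TFRanking, rank_tfs

GenomeHits = dict[tuple[str, str], tuple[list[MotifHit], list[int]]]


def scan_genome(scanner: MotifScanner, genome: Mapping[str, str]) -> GenomeHits:
    """All hits of every motif on every chromosome, keyed (chrom, motif_id),
    stored with a parallel sorted start list for fast window queries."""
    out: GenomeHits = {}
    for chrom, seq in genome.items():
        for mid in scanner.motifs:
            hits = scanner.scan(seq, mid, chrom=chrom)
            out[(chrom, mid)] = (hits, [h.start for h in hits])
    return out


def hits_in_window(
    genome_hits: GenomeHits, chrom: str, mid: str, wstart: int, wend: int
) -> list[MotifHit]:
    """Hits lying fully inside [wstart, wend), re-based to window offsets."""
    entry = genome_hits.get((chrom, mid))
    if entry is None:
        return []
    hits, starts = entry
    lo = bisect_left(starts, wstart)
    hi = bisect_right(starts, wend)
    out = []
    for h in hits[lo:hi]:
        if h.start >= wstart and h.start + len(h.matched_seq) <= wend:
            out.append(
                MotifHit(h.motif_id, chrom, h.start - wstart, h.strand,
                         h.score, h.pvalue, h.matched_seq)
            )
    return out


def window_hit_maps(
    ds: Dataset,
    genome_hits: GenomeHits,
    motif_ids: Sequence[str],
    flank: int = FLANK,
) -> list[dict[str, list[MotifHit]]]:
    """Per-bin {motif_id: hits} over each bin's 1000 bp window."""
    maps = []
    for r in ds.bins.itertuples():
        ws, we = int(r.start) - flank, int(r.end) + flank
        maps.append(
            {mid: hits_in_window(genome_hits, r.chrom, mid, ws, we) for mid in motif_ids}
        )
    return maps


def rank_dataset_tfs(
    train_ds: Dataset,
    genome_hits: GenomeHits,
    motifs: Sequence[Motif],
    n: int,
    mode: str = "hits",
) -> TFRanking:
    """TF ranking by motif presence over the training bins' windows."""
    maps = window_hit_maps(train_ds, genome_hits, [m.id for m in motifs])
    return rank_tfs(maps, motifs, n, mode=mode)


def encode_dataset(
    ds: Dataset,
    genome_hits: GenomeHits,
    tf_order: Sequence[str],
    motifs: Mapping[str, Motif],
    flat: bool = False,
) -> np.ndarray:
    """Encoded tensors for every bin window of a dataset."""
    if ds.windows is None:
        raise ValueError("dataset windows not extracted")
    maps = window_hit_maps(ds, genome_hits, list(tf_order))
    return encode_windows(ds.windows, maps, tf_order, motifs, flat=flat)
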