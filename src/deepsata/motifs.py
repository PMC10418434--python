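"""MEME motif parsing, calibrated motif scanning, and TF ranking.

The scanner reproduces the classic occurrence-scanner behaviour: each
length-L window on either strand is scored with the log-odds (bits) of the
position probability matrix against an iid background, the exact null
distribution of the score is obtained by dynamic-programming convolution of
per-position score distributions (after discretizing scores to integer
levels), and windows whose tail p-value falls at or below the threshold
(default 1e-4) are reported as hits.

Internal channel order is A, T, C, G throughout the package; MEME files use
A, C, G, T and are re-ordered at parse time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: internal channel order
BASES = "ATCG"
#: index into the internal order for each base character; N -> 4
BASE_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4}
#: MEME column order -> internal order permutation (A,C,G,T -> A,T,C,G)
_MEME_TO_INTERNAL = [0, 3, 1, 2]  # internal col j takes MEME col _MEME_TO_INTERNAL[j]
_INTERNAL_TO_MEME = [0, 2, 3, 1]

#: reverse-complement permutation of the internal channels (A<->T, C<->G)
RC_PERM = np.array([1, 0, 3, 2])

PSEUDOCOUNT = 1e-4
DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_N_BINS = 1000

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_indices(seq: str) -> np.ndarray:
    """Map a sequence over {A,C,G,T,N} to internal indices 0..4 (N=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(128, 255, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    out = lut[arr]
    if (out == 255).any():
        bad = sorted({chr(c) for c in arr[out == 255]})
        raise ValueError(f"illegal sequence characters {bad}")
    return out


@dataclass
class Motif:
    """A named position probability matrix (rows x {A,T,C,G}) with background."""

    id: str
    name: str
    ppm: np.ndarray  # (L, 4), internal A,T,C,G order
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 4 or self.ppm.shape[0] == 0:
            raise ValueError(f"motif {self.id}: ppm must be (L, 4) with L >= 1")
        if (self.ppm < 0).any():
            raise ValueError(f"motif {self.id}: negative ppm entries")
        if not np.allclose(self.ppm.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError(f"motif {self.id}: ppm rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-3):
            raise ValueError(f"motif {self.id}: background must sum to 1")

    def __len__(self) -> int:
        return self.ppm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.ppm.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """(L, 4) log2 odds of the pseudocounted PPM against the background."""
        p = self.ppm + PSEUDOCOUNT
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background[None, :])

    def reverse_complement(self) -> "Motif":
        rc = self.ppm[::-1][:, RC_PERM]
        return Motif(self.id, self.name, rc, self.background[RC_PERM])


@dataclass(frozen=True)
class MotifHit:
    """A located, stranded, scored motif occurrence.

    ``start`` is the 0-based offset of the site's first base on the forward
    strand of the scanned sequence; ``matched_seq`` is always the
    forward-strand sequence of the site.
    """

    motif_id: str
    chrom: str
    start: int
    strand: str
    score: float
    pvalue: float
    matched_seq: str


@dataclass
class TFRanking:
    """Motifs ordered by presence over the input bins."""

    ranking: list[tuple[str, int]]
    selected_n: int

    @property
    def tf_order(self) -> list[str]:
        return [mid for mid, _ in self.ranking[: self.selected_n]]


# ---------------------------------------------------------------------------
# MEME format
# ---------------------------------------------------------------------------

def parse_meme(path: str | Path) -> list[Motif]:
    """Parse a MEME minimal-format motif file.

    Columns are re-ordered from MEME's A,C,G,T to the internal A,T,C,G.
    A missing background line defaults to uniform.
    """
    path = Path(path)
    text = path.read_text()
    background = np.full(4, 0.25)
    m = re.search(
        r"Background letter frequencies.*?\n\s*A\s+([\d.eE+-]+)\s+C\s+([\d.eE+-]+)"
        r"\s+G\s+([\d.eE+-]+)\s+T\s+([\d.eE+-]+)",
        text,
    )
    if m:
        a, c, g, t = (float(x) for x in m.groups())
        background = np.array([a, t, c, g])  # internal order
    alpha = re.search(r"ALPHABET\s*=?\s*(\S+)", text)
    if alpha and alpha.group(1) != "ACGT":
        raise ValueError(f"unsupported alphabet {alpha.group(1)!r} (need ACGT)")

    motifs: list[Motif] = []
    blocks = re.split(r"(?m)^MOTIF\s+", text)[1:]
    for block in blocks:
        header = block.splitlines()[0].split()
        mid = header[0]
        name = header[1] if len(header) > 1 else mid
        lm = re.search(r"letter-probability matrix:[^\n]*\n", block)
        if lm is None:
            raise ValueError(f"motif {mid}: missing letter-probability matrix")
        rows = []
        for line in block[lm.end():].splitlines():
            line = line.strip()
            if not line:
                if rows:
                    break
                continue
            fields = line.split()
            try:
                vals = [float(x) for x in fields]
            except ValueError:
                break
            if len(vals) != 4:
                raise ValueError(f"motif {mid}: matrix row with {len(vals)} columns")
            rows.append(vals)
        if not rows:
            raise ValueError(f"motif {mid}: empty letter-probability matrix")
        meme_ppm = np.array(rows)
        if not np.allclose(meme_ppm.sum(axis=1), 1.0, atol=1e-3):
            raise ValueError(f"motif {mid}: matrix rows must sum to 1")
        ppm = meme_ppm[:, _MEME_TO_INTERNAL]
        motifs.append(Motif(mid, name, ppm, background.copy()))
    return motifs


def write_meme(motifs: Sequence[Motif], path: str | Path) -> None:
    """Write motifs in MEME minimal format (columns back in A,C,G,T order)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write(
                "Background letter frequencies\n"
                f"A {bg[0]:.5f} C {bg[2]:.5f} G {bg[3]:.5f} T {bg[1]:.5f}\n\n"
            )
        for mo in motifs:
            fh.write(f"MOTIF {mo.id} {mo.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(mo)} "
                f"nsites= 20 E= 0\n"
            )
            for row in mo.ppm[:, _INTERNAL_TO_MEME]:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# p-value calibration
# ---------------------------------------------------------------------------

@dataclass
class PValueTable:
    """Exact null distribution of a motif's discretized log-odds score.

    ``int_matrix[i, b]`` is the integer score level of base ``b`` at motif
    position ``i`` (N scores as the level closest to 0 bits); ``tail[s]`` is
    ``P(int score >= s)`` under the iid background.
    """

    int_matrix: np.ndarray  # (L, 5) int levels, last column = N
    tail: np.ndarray        # (max_total + 1,)
    offsets: np.ndarray     # per-position offsets (bits)
    scale: float            # levels per bit

    def pvalue_of_int(self, int_score: np.ndarray | int) -> np.ndarray | float:
        s = np.clip(int_score, 0, len(self.tail) - 1)
        return self.tail[s]

    def pvalue(self, score_bits: float) -> float:
        """Tail probability of a real-valued total log-odds score (bits)."""
        s = int(round((score_bits - self.offsets.sum()) * self.scale))
        return float(self.pvalue_of_int(s))

    def int_threshold(self, p_threshold: float) -> int:
        """Smallest integer score whose tail p-value is <= p_threshold."""
        ok = np.nonzero(self.tail <= p_threshold)[0]
        return int(ok[0]) if len(ok) else len(self.tail)  # unattainable if none

    @property
    def max_int_score(self) -> int:
        return int(self.int_matrix[:, :4].max(axis=1).sum())


def pvalue_table(
    motif: Motif,
    background: np.ndarray | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> PValueTable:
    """Exact score -> p-value calibration by dynamic-programming convolution.

    Per-position log-odds scores are discretized to ``n_bins`` integer
    levels; the distribution of the total over iid background positions is
    the convolution of the per-position distributions.
    """
    if n_bins < 100:
        raise ValueError("n_bins must be >= 100")
    bg = np.asarray(background, dtype=float) if background is not None else motif.background
    lo = motif.log_odds()  # (L, 4), bits
    L = lo.shape[0]
    offsets = lo.min(axis=1)
    shifted = lo - offsets[:, None]
    max_range = shifted.max()
    scale = (n_bins - 1) / max_range if max_range > 0 else 1.0
    int_core = np.rint(shifted * scale).astype(np.int64)  # (L, 4)

    # N contributes the background expectation: 0 bits
    n_level = np.rint((0.0 - offsets) * scale).astype(np.int64)
    per_pos_max = int_core.max(axis=1)
    n_level = np.clip(n_level, 0, per_pos_max)
    int_matrix = np.concatenate([int_core, n_level[:, None]], axis=1)

    max_total = int(per_pos_max.sum())
    pdf = np.zeros(max_total + 1)
    pdf[0] = 1.0
    top = 0
    for i in range(L):
        new = np.zeros_like(pdf)
        for b in range(4):
            v = int_core[i, b]
            new[v : top + v + 1] += bg[b] * pdf[: top + 1]
        pdf = new
        top += int(per_pos_max[i])
    tail = pdf[::-1].cumsum()[::-1]
    return PValueTable(int_matrix, tail, offsets, scale)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _window_int_scores(idx: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Integer score of every length-L window of an index sequence."""
    L = int_matrix.shape[0]
    W = len(idx) - L + 1
    if W <= 0:
        return np.zeros(0, dtype=np.int64)
    wins = np.lib.stride_tricks.sliding_window_view(idx, L)  # (W, L)
    return int_matrix[np.arange(L)[None, :], wins].sum(axis=1)


def _window_real_scores(idx: np.ndarray, lo5: np.ndarray) -> np.ndarray:
    L = lo5.shape[0]
    W = len(idx) - L + 1
    if W <= 0:
        return np.zeros(0)
    wins = np.lib.stride_tricks.sliding_window_view(idx, L)
    return lo5[np.arange(L)[None, :], wins].sum(axis=1)


class MotifScanner:
    """Caches per-motif calibration so repeated scans are cheap."""

    def __init__(
        self,
        motifs: Sequence[Motif],
        p_threshold: float = DEFAULT_P_THRESHOLD,
        n_bins: int = DEFAULT_N_BINS,
    ) -> None:
        if not motifs:
            raise ValueError("empty motif list")
        self.motifs = {m.id: m for m in motifs}
        self.p_threshold = p_threshold
        self._cal: dict[str, dict] = {}
        for m in motifs:
            fwd = pvalue_table(m, n_bins=n_bins)
            rc = m.reverse_complement()
            rev = pvalue_table(rc, background=m.background, n_bins=n_bins)
            lo5_f = np.concatenate([m.log_odds(), np.zeros((len(m), 1))], axis=1)
            lo5_r = np.concatenate([rc.log_odds(), np.zeros((len(m), 1))], axis=1)
            self._cal[m.id] = {
                "fwd": fwd,
                "rev": rev,
                "lo5_f": lo5_f,
                "lo5_r": lo5_r,
                "thr_f": fwd.int_threshold(p_threshold),
                "thr_r": rev.int_threshold(p_threshold),
            }

    def scan(self, seq: str, motif_id: str, chrom: str = "seq") -> list[MotifHit]:
        """All hits of one motif on both strands of ``seq``, sorted by start."""
        motif = self.motifs[motif_id]
        L = len(motif)
        if len(seq) < L:
            return []
        idx = seq_to_indices(seq.upper())
        cal = self._cal[motif_id]
        hits: list[MotifHit] = []
        for strand, key, thr_key, lo_key in (
            ("+", "fwd", "thr_f", "lo5_f"),
            ("-", "rev", "thr_r", "lo5_r"),
        ):
            table: PValueTable = cal[key]
            ints = _window_int_scores(idx, table.int_matrix)
            keep = np.nonzero(ints >= cal[thr_key])[0]
            if len(keep) == 0:
                continue
            reals = _window_real_scores(idx, cal[lo_key])
            pvals = table.pvalue_of_int(ints[keep])
            for j, s in enumerate(keep):
                s = int(s)
                hits.append(
                    MotifHit(
                        motif_id=motif_id,
                        chrom=chrom,
                        start=s,
                        strand=strand,
                        score=float(reals[s]),
                        pvalue=float(pvals[j]),
                        matched_seq=seq[s : s + L].upper(),
                    )
                )
        hits.sort(key=lambda h: (h.start, h.strand))
        return hits

    def scan_all(self, seq: str, chrom: str = "seq") -> dict[str, list[MotifHit]]:
        return {mid: self.scan(seq, mid, chrom) for mid in self.motifs}


def scan_sequence(
    seq: str,
    motif: Motif,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_bins: int = DEFAULT_N_BINS,
    chrom: str = "seq",
) -> list[MotifHit]:
    """Scan one sequence with one motif on both strands.

    Convenience wrapper around :class:`MotifScanner` (which should be used
    directly when scanning many sequences with the same motifs).
    """
    if len(seq) < len(motif):
        return []
    return MotifScanner([motif], p_threshold, n_bins).scan(seq, motif.id, chrom)


def rank_tfs(
    bins_hits: Sequence[Mapping[str, Sequence[MotifHit]]],
    motifs: Sequence[Motif],
    n: int,
    mode: str = "hits",
) -> TFRanking:
    """Rank motifs by presence over the input bins and keep the top ``n``.

    ``mode='hits'`` counts total hits across all bins (default);
    ``mode='bins'`` counts bins containing at least one hit.  Ties are
    broken lexicographically by motif id.
    """
    if not motifs:
        raise ValueError("empty motif list")
    if mode not in ("hits", "bins"):
        raise ValueError(f"unknown ranking mode {mode!r}")
    counts = {m.id: 0 for m in motifs}
    for bin_hits in bins_hits:
        for mid in counts:
            hs = bin_hits.get(mid, ())
            counts[mid] += len(hs) if mode == "hits" else int(len(hs) > 0)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n_present = sum(1 for _, c in ordered if c > 0)
    return TFRanking(ranking=ordered, selected_n=min(n, n_present))


def hits_to_fimo_table(hits: Iterable[MotifHit]) -> pd.DataFrame:
    """Hits as a FIMO-style TSV table (1-based inclusive coordinates)."""
    rows = []
    for h in hits:
        stop = h.start + len(h.matched_seq)
        rows.append(
            {
                "motif_id": h.motif_id,
                "sequence_name": h.chrom,
                "start": h.start + 1,
                "stop": stop,
                "strand": h.strand,
                "score": h.score,
                "p-value": h.pvalue,
                "matched_sequence": h.matched_seq,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "motif_id", "sequence_name", "start", "stop",
            "strand", "score", "p-value", "matched_sequence",
        ],
    )
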