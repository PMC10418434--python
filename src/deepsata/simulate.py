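"""Seeded generator of a complete toy study.

Produces a random genome, a motif library (driver and decoy PWMs), ATAC-like
peaks for several "tissues" driven by planted driver-motif density, and a
SNP panel split into motif-ablating and neutral variants with ground truth.
Every quantity derives from a single seeded Generator, so a fixed seed gives
byte-identical outputs.

What it emulates: open chromatin that is determined by the local density of
tissue-specific TF binding sites, observed through a noisy peak caller.
What it does not: repeats, isochores, linkage disequilibrium, cooperative
binding, or chromatin state beyond the planted-motif rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import Interval, Variant
from .motifs import BASES, Motif, reverse_complement

BIN_SIZE = 200


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 250_000 for i in range(1, 8)}
    )
    gc_content: float = 0.41
    n_motifs: int = 12
    n_drivers: int = 10
    motif_length: tuple[int, int] = (10, 12)
    core_positions: int = 4
    n_tissues: int = 3
    motifs_per_tissue: int = 1
    plant_rate_per_kb: float = 4.0
    peak_fraction: float = 0.20
    label_noise: float = 0.005
    n_variants: int = 500
    fraction_regulatory: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.peak_fraction < 1):
            raise ValueError("peak_fraction must be in (0, 1)")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_drivers > self.n_motifs:
            raise ValueError("n_drivers cannot exceed n_motifs")
        if self.motifs_per_tissue > self.n_drivers:
            raise ValueError("motifs_per_tissue cannot exceed n_drivers")


@dataclass
class GroundTruth:
    """Registry of planted motif instances and tissue driver assignments."""

    registry: pd.DataFrame            # motif_id, chrom, start, strand, length, is_driver
    tissue_drivers: dict[str, list[str]]
    variant_classes: pd.DataFrame | None = None  # chrom, pos, ref, alt, klass


@dataclass
class SimStudy:
    config: SimConfig
    genome: dict[str, str]
    motifs: list[Motif]
    ground_truth: GroundTruth
    peaks: dict[str, list[Interval]] = field(default_factory=dict)

    @property
    def motif_map(self) -> dict[str, Motif]:
        return {m.id: m for m in self.motifs}

    @property
    def tissues(self) -> list[str]:
        return list(self.ground_truth.tissue_drivers)


def _random_motif(
    rng: np.random.Generator, mid: str, length: int, background: np.ndarray,
    n_core: int = 4,
) -> Motif:
    """A PWM with a realistic heterogeneous information profile.

    A few "core" positions are near-deterministic (consensus probability
    0.93-0.99) and the remaining positions are weak (0.60-0.80), the shape
    typical of curated TF motifs.  The profile matters for in-silico
    mutagenesis: substituting the most informative core base costs more
    log-odds than any combination of two weak-position changes, so a single
    SNP there pushes the site below the scanning significance threshold.
    """
    ppm = np.zeros((length, 4))
    core = set(rng.choice(length, size=min(n_core, length), replace=False).tolist())
    for i in range(length):
        consensus = rng.integers(0, 4)
        p = rng.uniform(0.93, 0.99) if i in core else rng.uniform(0.60, 0.80)
        rest = rng.dirichlet(np.ones(3)) * (1.0 - p)
        row = np.empty(4)
        row[consensus] = p
        row[[b for b in range(4) if b != consensus]] = rest
        ppm[i] = row
    return Motif(mid, f"TF_{mid}", ppm, background.copy())


def make_motif_library(config: SimConfig, rng: np.random.Generator) -> list[Motif]:
    gc = config.gc_content
    background = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    lo, hi = config.motif_length
    motifs = []
    for i in range(config.n_motifs):
        L = int(rng.integers(lo, hi + 1))
        motifs.append(
            _random_motif(rng, f"M{i + 1:02d}", L, background, config.core_positions)
        )
    return motifs


def _sample_spaced_positions(
    rng: np.random.Generator, n: int, length: int, gap: int
) -> np.ndarray:
    """n sorted positions in [0, length) pairwise at least ``gap`` apart."""
    usable = length - n * gap
    if usable <= 0:
        raise ValueError("plant density exceeds genome capacity")
    raw = np.sort(rng.integers(0, usable, size=n))
    return raw + np.arange(n) * gap


def simulate_genome(
    config: SimConfig,
    library: tuple[list[Motif], dict[str, list[str]]] | None = None,
) -> SimStudy:
    """Background genome with planted driver/decoy motif instances.

    ``library`` optionally supplies a pre-existing motif library and tissue
    driver assignment (used for a second species sharing species 1's
    drivers); the generator's own library draws still happen so the random
    stream stays aligned, they are just discarded.
    """
    rng = np.random.default_rng(config.seed)
    own_motifs = make_motif_library(config, rng)
    own_drivers = [m.id for m in own_motifs[: config.n_drivers]]
    # disjoint driver subsets per tissue when the library allows; independent
    # draws (which may share drivers across tissues) otherwise
    mpt = config.motifs_per_tissue
    if config.n_tissues * mpt <= config.n_drivers:
        perm = rng.permutation(own_drivers)
        own_assignment = {
            f"tissue{t + 1}": sorted(perm[t * mpt : (t + 1) * mpt].tolist())
            for t in range(config.n_tissues)
        }
    else:
        own_assignment = {
            f"tissue{t + 1}": sorted(
                rng.choice(own_drivers, size=mpt, replace=False).tolist()
            )
            for t in range(config.n_tissues)
        }
    if library is None:
        motifs, tissue_drivers = own_motifs, own_assignment
    else:
        motifs, tissue_drivers = library
    # "driver" in the planted-site registry means: drives at least one tissue
    drivers = sorted({mid for mids in tissue_drivers.values() for mid in mids})

    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    genome: dict[str, str] = {}
    chars = np.array(list(BASES))
    for chrom, length in config.chrom_lengths.items():
        idx = rng.choice(4, size=length, p=base_p)
        genome[chrom] = "".join(chars[idx])

    total_kb = sum(config.chrom_lengths.values()) / 1000.0
    n_plants = int(round(config.plant_rate_per_kb * total_kb))
    lmax = max(len(m) for m in motifs)
    # apportion plants to chromosomes by length
    lengths = np.array(list(config.chrom_lengths.values()), dtype=float)
    per_chrom = np.floor(n_plants * lengths / lengths.sum()).astype(int)
    per_chrom[: n_plants - per_chrom.sum()] += 1

    rows = []
    for (chrom, length), n_c in zip(config.chrom_lengths.items(), per_chrom):
        if n_c == 0:
            continue
        starts = _sample_spaced_positions(rng, n_c, length - lmax, lmax + 10)
        chosen = rng.integers(0, config.n_motifs, size=n_c)
        strands = rng.choice(["+", "-"], size=n_c)
        seq = list(genome[chrom])
        for s, mi, strand in zip(starts, chosen, strands):
            motif = motifs[mi]
            L = len(motif)
            # planted instances realize the consensus, so every registered
            # site is recoverable by the calibrated scanner
            inst = motif.consensus
            if strand == "-":
                inst = reverse_complement(inst)
            seq[s : s + L] = inst
            rows.append(
                {
                    "motif_id": motif.id, "chrom": chrom, "start": int(s),
                    "strand": strand, "length": L,
                    "is_driver": motif.id in drivers,
                }
            )
        genome[chrom] = "".join(seq)
    registry = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return SimStudy(config, genome, motifs, GroundTruth(registry, tissue_drivers))


def simulate_peaks(study: SimStudy) -> dict[str, list[Interval]]:
    """Per-tissue peaks: top-q 200 bp regions by planted driver-instance count.

    Regions with no driver instance never become peaks by score; the label
    noise then flips a small random fraction of the per-bin peak membership
    (in both directions) before merging runs of peak bins into intervals.
    """
    config = study.config
    rng = np.random.default_rng(config.seed + 1)
    reg = study.ground_truth.registry
    bins_per_chrom = {c: len(s) // BIN_SIZE for c, s in study.genome.items()}
    order = list(study.genome)
    offsets = np.cumsum([0] + [bins_per_chrom[c] for c in order])
    chrom_offset = dict(zip(order, offsets[:-1]))
    n_bins = int(offsets[-1])

    peaks: dict[str, list[Interval]] = {}
    for tissue, driver_ids in study.ground_truth.tissue_drivers.items():
        score = np.zeros(n_bins, dtype=np.int64)
        sub = reg[reg["motif_id"].isin(driver_ids)]
        for row in sub.itertuples():
            b_first = row.start // BIN_SIZE
            b_last = (row.start + row.length - 1) // BIN_SIZE
            for b in range(b_first, min(b_last, bins_per_chrom[row.chrom] - 1) + 1):
                score[chrom_offset[row.chrom] + b] += 1
        n_top = int(np.ceil(config.peak_fraction * n_bins))
        positive = np.nonzero(score > 0)[0]
        if len(positive) == 0:
            raise ValueError(f"peak_fraction yields zero peaks for {tissue}")
        ranked = positive[np.lexsort((positive, -score[positive]))]
        member = np.zeros(n_bins, dtype=bool)
        member[ranked[:n_top]] = True
        if config.label_noise > 0:
            flip = rng.random(n_bins) < config.label_noise
            member ^= flip
        # merge runs of member bins into intervals per chromosome
        ivs: list[Interval] = []
        for c in order:
            o, nb = chrom_offset[c], bins_per_chrom[c]
            mem = member[o : o + nb]
            run_start = None
            for b in range(nb + 1):
                inside = b < nb and mem[b]
                if inside and run_start is None:
                    run_start = b
                elif not inside and run_start is not None:
                    ivs.append(Interval(c, run_start * BIN_SIZE, b * BIN_SIZE, tissue))
                    run_start = None
        peaks[tissue] = ivs
    study.peaks = peaks
    return peaks


def _information_argmax(ppm: np.ndarray) -> int:
    p = np.clip(ppm, 1e-9, 1.0)
    info = 2.0 + (p * np.log2(p)).sum(axis=1)
    return int(np.argmax(info))


_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def simulate_variants(study: SimStudy) -> tuple[list[Variant], pd.DataFrame]:
    """SNP panel: motif-ablating SNPs hit the most informative position of a
    planted driver instance with the PPM's least-probable base; neutral SNPs
    fall at least 50 bp from any planted instance."""
    config = study.config
    rng = np.random.default_rng(config.seed + 2)
    reg = study.ground_truth.registry
    drivers = reg[reg["is_driver"]].reset_index(drop=True)
    n_reg = int(round(config.n_variants * config.fraction_regulatory))
    n_neutral = config.n_variants - n_reg
    if n_reg > len(drivers):
        raise ValueError("not enough planted driver instances for the requested panel")
    motif_map = study.motif_map

    chosen = rng.choice(len(drivers), size=n_reg, replace=False)
    variants: list[Variant] = []
    rows = []
    for ci in np.sort(chosen):
        row = drivers.iloc[int(ci)]
        motif = motif_map[row["motif_id"]]
        i_star = _information_argmax(motif.ppm)
        alt_channel = int(np.argmin(motif.ppm[i_star]))
        alt_base = BASES[alt_channel]
        if row["strand"] == "+":
            gpos = int(row["start"]) + i_star
        else:
            gpos = int(row["start"]) + (row["length"] - 1 - i_star)
            alt_base = _COMP[alt_base]
        ref_base = study.genome[row["chrom"]][gpos]
        if ref_base == alt_base:  # realized base happened to be the least-probable one
            channels = np.argsort(motif.ppm[i_star])
            alt_base = BASES[int(channels[1])]
            if row["strand"] == "-":
                alt_base = _COMP[alt_base]
            if ref_base == alt_base:
                continue
        v = Variant(row["chrom"], gpos + 1, ref_base, alt_base)
        variants.append(v)
        rows.append(
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "klass": "motif_ablating", "motif_id": row["motif_id"]}
        )

    # neutral positions: >= 50 bp from every planted instance
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for r in reg.itertuples():
        forbidden.setdefault(r.chrom, []).append((r.start - 50, r.start + r.length + 50))
    chroms = list(study.genome)
    lengths = np.array([len(study.genome[c]) for c in chroms], dtype=float)
    placed = 0
    attempts = 0
    while placed < n_neutral:
        attempts += 1
        if attempts > 100 * config.n_variants:
            raise ValueError("insufficient neutral space in the simulated genome")
        c = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
        pos0 = int(rng.integers(0, len(study.genome[c])))
        if any(s <= pos0 < e for s, e in forbidden.get(c, ())):
            continue
        ref_base = study.genome[c][pos0]
        if ref_base == "N":
            continue
        alt_base = BASES[int(rng.choice([b for b in range(4) if BASES[b] != ref_base]))]
        v = Variant(c, pos0 + 1, ref_base, alt_base)
        variants.append(v)
        rows.append(
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "klass": "neutral", "motif_id": ""}
        )
        placed += 1

    classes = pd.DataFrame(rows)
    study.ground_truth.variant_classes = classes
    return variants, classes


def simulate_study(config: SimConfig) -> SimStudy:
    """Genome + peaks in one call (variants via :func:`simulate_variants`)."""
    study = simulate_genome(config)
    simulate_peaks(study)
    return study


def simulate_second_species(
    config: SimConfig,
    shared: SimStudy | None,
    seed: int,
) -> SimStudy:
    """An independent background genome under the same accessibility rule.

    With ``shared`` given, the first species' motif library and tissue
    driver assignments are reused (the conserved-TF premise), so a model
    trained on species 1 faces the same regulatory grammar on new sequence.
    With ``shared=None`` a completely fresh motif library is drawn and no
    regulatory signal transfers.
    """
    cfg = replace(config, seed=seed)
    if shared is not None:
        study = simulate_genome(
            cfg, library=(shared.motifs, shared.ground_truth.tissue_drivers)
        )
    else:
        study = simulate_genome(cfg)
    simulate_peaks(study)
    return study
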