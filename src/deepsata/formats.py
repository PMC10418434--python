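"""Readers and writers for the standard file formats the pipeline touches.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open.  BED input is already
0-based half-open and is taken as-is; VCF positions are 1-based and are
converted (``pos - 1``) only at the point of use, never stored differently
than the VCF convention on the :class:`Variant` itself (``Variant.pos`` is
the 1-based VCF position, ``Variant.pos0`` the 0-based one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
_SNP_ALLELES = set("ACGT")


@dataclass
class GenomeSequence:
    """A single chromosome: upper-case sequence over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"empty sequence for record {self.name!r}")
        if not set(self.sequence) <= _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(f"illegal bases {bad} in record {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval, optionally tagged with a feature."""

    chrom: str
    start: int
    end: int
    feature_id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP.  ``pos`` is 1-based (VCF convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.ref not in _SNP_ALLELES or self.alt not in _SNP_ALLELES:
            raise ValueError(f"SNP alleles must be one of ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1


def _normalize_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    # IUPAC ambiguity codes other than N are collapsed to N
    cleaned = "".join(b if b in _VALID_BASES else "N" for b in seq)
    n_fixed = sum(1 for a, b in zip(seq, cleaned) if a != b)
    logger.warning("record %s: %d ambiguous bases mapped to N", name, n_fixed)
    return cleaned


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into upper-cased :class:`GenomeSequence` records.

    Ambiguity codes other than N are mapped to N (with a logged warning);
    duplicate record names and empty records are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _normalize_sequence(str(rec.seq), rec.id)
        records.append(GenomeSequence(rec.id, seq))
    return records


def genome_dict(records: Iterable[GenomeSequence]) -> dict[str, str]:
    """Convenience mapping chromosome name -> sequence string."""
    return {r.name: r.sequence for r in records}


def write_fasta(records: Iterable[GenomeSequence], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent-by-overlap intervals of the same (chrom, feature)."""
    out: list[Interval] = []
    keyed: dict[tuple[str, str | None], list[Interval]] = {}
    for iv in intervals:
        keyed.setdefault((iv.chrom, iv.feature_id), []).append(iv)
    for (chrom, feat), ivs in keyed.items():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_e:  # strict overlap merges; bookended intervals stay apart
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e, feat))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e, feat))
    return sorted(out, key=lambda iv: (iv.chrom, iv.start))


def read_bed(path: str | Path, feature_id: str | None = None) -> list[Interval]:
    """Read a BED3+ file (0-based half-open) into sorted, merged intervals.

    The optional 4th column is used as the feature id unless ``feature_id``
    is given explicitly (which then applies to every row).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            feat = feature_id if feature_id is not None else (parts[3] if len(parts) > 3 else None)
            intervals.append(Interval(chrom, start, end, feat))
    return merge_intervals(intervals)


def write_bed(intervals: Sequence[Interval], path: str | Path) -> None:
    """Write intervals as BED (3 or 4 columns); refuses invalid coordinates."""
    for iv in intervals:
        if iv.start < 0 or iv.start >= iv.end:
            raise ValueError(f"refusing to write invalid interval {iv}")
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.feature_id is not None:
                cols.append(iv.feature_id)
            fh.write("\t".join(cols) + "\n")


@dataclass
class VcfReadResult:
    variants: list[Variant]
    n_skipped_indels: int = 0
    n_skipped_multiallelic: int = 0

    def __iter__(self):
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def read_vcf(path: str | Path) -> VcfReadResult:
    """Read SNPs from a VCF 4.x file.

    Indels and multi-allelic records are skipped; the skip counts are logged
    and returned on the result object.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    variants: list[Variant] = []
    n_indel = n_multi = 0
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                saw_header = True
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not saw_header:
                raise ValueError(f"{path}: malformed VCF header (data before ##fileformat)")
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: fewer than 5 VCF columns")
            chrom, pos_s, vid, ref, alt = parts[:5]
            if "," in alt:
                n_multi += 1
                continue
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _SNP_ALLELES or alt not in _SNP_ALLELES:
                n_indel += 1
                continue
            variants.append(Variant(chrom, int(pos_s), ref, alt, None if vid == "." else vid))
    if n_indel or n_multi:
        logger.info(
            "%s: skipped %d non-SNP and %d multi-allelic records", path, n_indel, n_multi
        )
    return VcfReadResult(variants, n_indel, n_multi)


def write_vcf(variants: Sequence[Variant], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\n")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV (with header, no index)."""
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
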