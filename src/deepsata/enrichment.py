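"""GWAS-window intersection, nearest-TSS gene assignment, trait enrichment.

Regulatory SNPs are intersected with 2 Mb windows centered on GWAS signal
midpoints (inclusive bounds), assigned to the nearest transcription start
site within 1 Mb, and the resulting gene set is tested per trait with a
hypergeometric tail against the background of all genes in the windows,
with Benjamini-Hochberg FDR across traits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .formats import Variant

HALF_WIDTH = 1_000_000   # GWAS window half-width (2 Mb window)
MAX_TSS_DIST = 1_000_000


@dataclass(frozen=True)
class GwasSignal:
    chrom: str
    midpoint: int  # 1-based
    trait: str

    def __post_init__(self) -> None:
        if self.midpoint < 1:
            raise ValueError("midpoint must be >= 1")


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    start: int    # 0-based half-open gene span
    end: int
    strand: str = "+"

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (0-based)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class EnrichmentResult:
    trait: str
    k: int      # linked genes in the trait set
    K: int      # background genes in the trait set
    n: int      # linked genes total
    M: int      # background genes total
    fold: float
    pvalue: float
    fdr: float = float("nan")


def snps_in_gwas_windows(
    snps: Sequence[Variant],
    signals: Sequence[GwasSignal],
    half_width: int = HALF_WIDTH,
) -> list[Variant]:
    """SNPs within ``half_width`` (inclusive) of any signal midpoint on the
    same chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for sig in signals:
        by_chrom.setdefault(sig.chrom, []).append(sig.midpoint)
    out = []
    for v in snps:
        mids = by_chrom.get(v.chrom)
        if mids and min(abs(v.pos - m) for m in mids) <= half_width:
            out.append(v)
    return out


def nearest_tss(
    snps: Sequence[Variant],
    genes: Sequence[Gene],
    max_dist: int = MAX_TSS_DIST,
) -> dict[Variant, Gene]:
    """Assign each SNP to the nearest TSS within ``max_dist`` (inclusive);
    distance ties go to the gene with the smaller TSS coordinate."""
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gs in by_chrom.values():
        gs.sort(key=lambda g: g.tss)
    assignments: dict[Variant, Gene] = {}
    for v in snps:
        gs = by_chrom.get(v.chrom)
        if not gs:
            continue
        best: Gene | None = None
        best_d = None
        for g in gs:  # genes sorted by TSS => first minimal-distance gene wins ties
            d = abs(v.pos0 - g.tss)
            if best_d is None or d < best_d:
                best, best_d = g, d
        if best is not None and best_d <= max_dist:
            assignments[v] = best
    return assignments


def hypergeometric_enrichment(
    linked_genes: Sequence[str],
    trait_gene_sets: Mapping[str, Sequence[str]],
    background_genes: Sequence[str],
) -> list[EnrichmentResult]:
    """Per-trait hypergeometric tail P(X >= k) with BH FDR across traits.

    ``fold = (k/n) / (K/M)``; trait sets are intersected with the background
    and linked genes must be a subset of the background.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene set")
    linked = set(linked_genes)
    if not linked <= background:
        raise ValueError("linked genes must be a subset of the background")
    M, n = len(background), len(linked)
    results: list[EnrichmentResult] = []
    for trait, genes in trait_gene_sets.items():
        trait_set = set(genes) & background
        K = len(trait_set)
        k = len(trait_set & linked)
        # P(X >= k), X ~ Hypergeom(M, K, n); sf(k-1) is the inclusive tail
        pvalue = float(hypergeom.sf(k - 1, M, K, n)) if n > 0 else 1.0
        fold = (k / n) / (K / M) if (n > 0 and K > 0) else 0.0
        results.append(EnrichmentResult(trait, k, K, n, M, fold, min(pvalue, 1.0)))
    if results:
        _, fdrs, _, _ = multipletests([r.pvalue for r in results], method="fdr_bh")
        for r, q in zip(results, fdrs):
            r.fdr = float(q)
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": r.trait, "k": r.k, "K": r.K, "n": r.n, "M": r.M,
                "fold": r.fold, "pvalue": r.pvalue, "fdr": r.fdr,
            }
            for r in results
        ]
    )
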