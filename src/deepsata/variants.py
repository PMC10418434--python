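"""In-silico mutagenesis: per-allele accessibility, thresholds, regulatory calls.

For each SNP the 1000 bp window covering 500 bp on either side is scored
twice — once with the reference allele and once with the alternative at
window offset 500.  Motif sites are re-scanned separately per allele (a
substitution can create or destroy a binding site).  A per-feature
open/closed probability threshold is picked on held-out predictions by
maximizing Youden's J (sensitivity + specificity - 1), and a SNP is called
regulatory for a feature when its two alleles fall on opposite sides of
that threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import Variant
from .motifs import Motif, MotifScanner

logger = logging.getLogger(__name__)

WINDOW = 1000
HALF_WINDOW = 500


@dataclass
class VariantEffect:
    variant: Variant
    p_ref: np.ndarray     # per-feature probabilities
    p_alt: np.ndarray
    regulatory: np.ndarray | None = None  # per-feature booleans, set by classify

    @property
    def delta(self) -> np.ndarray:
        return self.p_alt - self.p_ref


@dataclass
class ThresholdSet:
    feature_names: list[str]
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


class RefMismatchCounter:
    """Counts declared-ref vs genome disagreements during window extraction."""

    def __init__(self) -> None:
        self.count = 0


def variant_window(
    genome: Mapping[str, str],
    variant: Variant,
    mismatch_counter: RefMismatchCounter | None = None,
) -> tuple[str, str]:
    """(ref_window, alt_window): 1000 bp centered with the SNP at offset 500.

    Positions outside the chromosome are 'N'.  If the genome base disagrees
    with the declared reference allele, a warning is logged and the declared
    alleles are used regardless.
    """
    seq = genome[variant.chrom]
    p0 = variant.pos0
    if not (0 <= p0 < len(seq)):
        raise ValueError(f"variant {variant.chrom}:{variant.pos} outside the chromosome")
    ws, we = p0 - HALF_WINDOW, p0 + HALF_WINDOW
    left_pad = max(0, -ws)
    right_pad = max(0, we - len(seq))
    core = seq[max(0, ws) : min(len(seq), we)]
    window = "N" * left_pad + core + "N" * right_pad
    genome_base = window[HALF_WINDOW]
    if genome_base != variant.ref:
        logger.warning(
            "genome base %s at %s:%d differs from declared ref %s; using declared alleles",
            genome_base, variant.chrom, variant.pos, variant.ref,
        )
        if mismatch_counter is not None:
            mismatch_counter.count += 1
    ref_window = window[:HALF_WINDOW] + variant.ref + window[HALF_WINDOW + 1 :]
    alt_window = window[:HALF_WINDOW] + variant.alt + window[HALF_WINDOW + 1 :]
    return ref_window, alt_window


def score_variants(
    fit_result,
    scanner: MotifScanner,
    motifs: Mapping[str, Motif],
    genome: Mapping[str, str],
    variants: Sequence[Variant],
    batch_size: int = 64,
) -> list[VariantEffect]:
    """Per-allele accessibility probabilities for a batch of SNPs.

    Motif hits are recomputed on each allele's window before encoding, so
    allele-specific binding-site gain/loss reaches the TF layers.
    """
    from .encoding import encode_windows  # local import avoids a cycle at module load

    tf_order = fit_result.tf_order
    flat = fit_result.config.mode == "flat"
    mismatches = RefMismatchCounter()
    windows: list[str] = []
    for v in variants:
        rw, aw = variant_window(genome, v, mismatches)
        windows.append(rw)
        windows.append(aw)
    if mismatches.count:
        logger.warning("%d variants had reference-allele mismatches", mismatches.count)
    effects: list[VariantEffect] = []
    for s in range(0, len(windows), batch_size):
        chunk = windows[s : s + batch_size]
        hits = [
            {mid: scanner.scan(w, mid) for mid in tf_order} if tf_order else {}
            for w in chunk
        ]
        X = encode_windows(chunk, hits, tf_order, motifs, flat=flat)
        probs = fit_result.predict(X)
        for j in range(0, len(chunk), 2):
            vi = (s + j) // 2
            effects.append(VariantEffect(variants[vi], probs[j], probs[j + 1]))
    return effects


def optimal_threshold(
    labels: np.ndarray,
    scores: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> ThresholdSet:
    """Per-feature threshold maximizing Youden's J over all midpoints
    between consecutive distinct scores; ties take the smaller threshold."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if labels.ndim == 1:
        labels = labels[:, None]
        scores = scores[:, None]
    names = list(feature_names) if feature_names is not None else [
        f"feature_{i}" for i in range(labels.shape[1])
    ]
    ts, sens, spec = [], [], []
    for f in range(labels.shape[1]):
        y, s = labels[:, f], scores[:, f]
        if len(np.unique(y)) < 2:
            raise ValueError(f"feature {names[f]!r} has a single class")
        distinct = np.unique(s)
        if len(distinct) < 2:
            raise ValueError(f"feature {names[f]!r} has constant scores")
        cands = (distinct[:-1] + distinct[1:]) / 2.0
        n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
        # sensitivity/specificity of the rule score >= t at each candidate
        tp = (s[y == 1][:, None] >= cands[None, :]).sum(axis=0)
        tn = (s[y == 0][:, None] < cands[None, :]).sum(axis=0)
        se = tp / n_pos
        sp = tn / n_neg
        j = se + sp - 1.0
        best = int(np.argmax(j))  # argmax takes the first (smallest) tie
        ts.append(float(cands[best]))
        sens.append(float(se[best]))
        spec.append(float(sp[best]))
    return ThresholdSet(names, np.array(ts), np.array(sens), np.array(spec))


def classify_regulatory(
    effect: VariantEffect, thresholds: ThresholdSet
) -> np.ndarray:
    """Per-feature regulatory call: the alleles fall on opposite sides of
    the feature's open/closed threshold."""
    t = thresholds.thresholds
    call = (effect.p_ref >= t) != (effect.p_alt >= t)
    effect.regulatory = call
    return call


def classify_all(effects: Sequence[VariantEffect], thresholds: ThresholdSet) -> np.ndarray:
    return np.array([classify_regulatory(e, thresholds) for e in effects])


def top_k_by_effect(
    effects: Sequence[VariantEffect], k: int, feature: int
) -> list[VariantEffect]:
    """Top-k SNPs by |delta| for one feature; ties by (chrom, pos) ascending."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(effects):
        raise ValueError(f"k={k} exceeds the number of effects ({len(effects)})")
    order = sorted(
        effects,
        key=lambda e: (-abs(float(e.delta[feature])), e.variant.chrom, e.variant.pos),
    )
    return order[:k]


def effects_table(effects: Sequence[VariantEffect], feature_names: Sequence[str]) -> pd.DataFrame:
    """VCF-like TSV panel of scored variants (one row per SNP x feature)."""
    rows = []
    for e in effects:
        for f, name in enumerate(feature_names):
            rows.append(
                {
                    "chrom": e.variant.chrom,
                    "pos": e.variant.pos,
                    "ref": e.variant.ref,
                    "alt": e.variant.alt,
                    "feature": name,
                    "p_ref": float(e.p_ref[f]),
                    "p_alt": float(e.p_alt[f]),
                    "delta": float(e.delta[f]),
                    "regulatory": bool(e.regulatory[f]) if e.regulatory is not None else None,
                }
            )
    return pd.DataFrame(rows)
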