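"""ROC/AUC evaluation and the cross-species prediction harness.

Cross-species evaluation applies a trained model, together with *its own*
TF layer order and motif set, to another species' genome: the premise is
that TF binding preferences within a tissue are conserved, so the motif
layers computed on the target genome remain meaningful to the source-trained
network.  The harness is pure inference — weights are never updated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)


@dataclass
class ROCResult:
    feature_name: str
    auc: float
    points: np.ndarray  # (k, 2) of (fpr, tpr)
    n_pos: int
    n_neg: int


def auc(labels: np.ndarray, scores: np.ndarray, feature_name: str = "") -> ROCResult:
    """ROC over all distinct score thresholds; the AUC equals the
    Mann-Whitney statistic with ties counted one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present to compute an ROC")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    a = float(roc_auc_score(labels, scores))
    return ROCResult(
        feature_name=feature_name,
        auc=a,
        points=np.column_stack([fpr, tpr]),
        n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()),
    )


def mean_auc(
    labels: np.ndarray, scores: np.ndarray, feature_names: Sequence[str] | None = None
) -> tuple[list[ROCResult], float]:
    """Per-feature ROC plus the unweighted mean AUC; single-class features
    are skipped with a warning and excluded from the mean."""
    labels = np.atleast_2d(labels)
    scores = np.atleast_2d(scores)
    names = list(feature_names) if feature_names is not None else [
        f"feature_{i}" for i in range(labels.shape[1])
    ]
    results = []
    for f, name in enumerate(names):
        if len(np.unique(labels[:, f])) < 2:
            warnings.warn(f"feature {name!r} has a single class; skipped from mean AUC")
            continue
        results.append(auc(labels[:, f], scores[:, f], name))
    mean = float(np.mean([r.auc for r in results])) if results else float("nan")
    return results, mean


def evaluate_model(fit_result, X: np.ndarray, y: np.ndarray) -> tuple[list[ROCResult], float]:
    """Per-feature test AUCs of a trained model on an encoded split."""
    probs = fit_result.predict(X)
    return mean_auc(y, probs, fit_result.feature_names)


def cross_species_evaluate(
    fit_result,
    target_X: np.ndarray,
    target_labels: np.ndarray,
    target_features: Sequence[str],
    tissue_map: Mapping[str, str],
) -> dict[str, ROCResult]:
    """AUC of a source-species model on a target species, per mapped tissue.

    ``target_X`` must already be encoded with the *model's* tf_order and
    motifs (see :func:`deepsata.encoding.encode_windows`); ``tissue_map``
    pairs each model feature name with at most one target feature name.
    """
    digest_before = fit_result.weights_digest()
    model_features = list(fit_result.feature_names)
    target_features = list(target_features)
    for mf, tf in tissue_map.items():
        if mf not in model_features:
            raise KeyError(f"model has no feature {mf!r}")
        if tf not in target_features:
            raise KeyError(f"target dataset has no feature {tf!r}")
    if not tissue_map:
        return {}
    probs = fit_result.predict(target_X)
    out: dict[str, ROCResult] = {}
    for mf, tfeat in tissue_map.items():
        mi = model_features.index(mf)
        ti = target_features.index(tfeat)
        out[mf] = auc(target_labels[:, ti], probs[:, mi], feature_name=f"{mf}->{tfeat}")
    assert fit_result.weights_digest() == digest_before, "evaluation must not refit"
    return out


def plot_roc(results: Sequence[ROCResult], path: str | None = None):
    """ROC curves for a set of features (matplotlib, imported lazily)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for r in results:
        ax.plot(r.points[:, 0], r.points[:, 1], label=f"{r.feature_name} (AUC={r.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right", fontsize=8)
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
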