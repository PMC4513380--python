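"""Metrics, ROC curves, cutpoint optimization and gene-grouped CV.

The positive class is *pathogenic* throughout.  Balanced accuracy is the
mean of sensitivity and specificity, reported on a 0-100 scale.  The
averaged ("multinomial") ROC of a cross-validation is the vertical mean of
the per-fold curves on a fixed 101-point false-positive-rate grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .estimator import CutpointClassifier, GeneGroupedKFold
from .types import ConfigurationError, MispathError

FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ConfigurationError("confusion counts must be nonnegative")


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, balanced accuracy %)."""
    if c.TP + c.FN == 0 or c.TN + c.FP == 0:
        raise MispathError("empty class: sensitivity/specificity undefined")
    sens = 100.0 * c.TP / (c.TP + c.FN)
    spec = 100.0 * c.TN / (c.TN + c.FP)
    return sens, spec, (sens + spec) / 2.0


def balanced_accuracy_from_rates(sensitivity: float, specificity: float) -> float:
    """Balanced accuracy from already-computed percentage rates."""
    return (sensitivity + specificity) / 2.0


def counts_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
    )


def roc_curve(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """Threshold-sweep ROC (higher score = more pathogenic) and trapezoid AUC.

    Equal scores are grouped at one threshold.  Single-class input raises.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise MispathError("ROC requires both classes")
    fpr, tpr, _ = _skm.roc_curve(y, s, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass(frozen=True)
class CutpointSolution:
    wpc_cutoff: float
    psic_cutoff: Optional[float]
    balanced_accuracy_at_optimum: float
    fold_cutoffs: tuple = ()


def _check_dataset(data: pd.DataFrame, mode: str) -> None:
    need = {"truth", "wpc"}
    if mode == "wpc+psic":
        need.add("psic")
    missing = need - set(data.columns)
    if missing:
        raise ConfigurationError(f"dataset missing columns {sorted(missing)}")
    if mode not in ("wpc-only", "wpc+psic"):
        raise ConfigurationError(f"unknown mode {mode!r}")


def _estimator(mode: str, use_hotspot: bool) -> CutpointClassifier:
    return CutpointClassifier(
        use_hotspot=use_hotspot, use_psic=(mode == "wpc+psic")
    )


def optimize_cutpoints(
    data: pd.DataFrame, mode: str = "wpc-only", use_hotspot: bool = True
) -> CutpointSolution:
    """Grid-search the cutpoint(s) maximizing balanced accuracy of the full
    gated pipeline on ``data`` (columns: truth, wpc[, psic][, hotspot]).

    WPC is searched in steps of 1 over 0-100 and PSIC in steps of 0.01 over
    the observed range; ties break to the smallest cutoff.  Row order of the
    dataset does not affect the result.
    """
    _check_dataset(data, mode)
    if use_hotspot and "hotspot" not in data.columns:
        use_hotspot = False
    est = _estimator(mode, use_hotspot)
    est.fit(data, data["truth"].to_numpy())
    return CutpointSolution(
        wpc_cutoff=est.wpc_cutoff_,
        psic_cutoff=est.psic_cutoff_,
        balanced_accuracy_at_optimum=est.balanced_accuracy_,
    )


def gene_grouped_kfold(genes: Sequence, k: int = 5, seed: int = 0) -> np.ndarray:
    """Fold index per variant; all variants of a gene share one fold."""
    return GeneGroupedKFold(n_splits=k, seed=seed).fold_assignment(genes)


@dataclass(frozen=True)
class CrossValidationResult:
    fold_metrics: tuple[dict, ...]
    sensitivity: float
    specificity: float
    balanced_accuracy: float
    wpc_cutoff: float
    psic_cutoff: Optional[float]
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    auc: float
    fold_aucs: tuple[float, ...]


def cross_validate(
    data: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    mode: str = "wpc-only",
    use_hotspot: bool = True,
) -> CrossValidationResult:
    """Gene-grouped k-fold cross-validation of the cutpoint pipeline.

    Per fold: optimize cutpoints on the other k-1 folds, evaluate on the
    held-out fold.  Reported accuracies and cutpoints are the means over
    folds; the averaged ROC is the vertical mean of fold curves on a common
    101-point FPR grid, with its AUC by trapezoid.
    """
    _check_dataset(data, mode)
    if "gene" not in data.columns:
        raise ConfigurationError("dataset needs a 'gene' column for grouped CV")
    if use_hotspot and "hotspot" not in data.columns:
        use_hotspot = False
    folds = gene_grouped_kfold(data["gene"].to_numpy(), k=k, seed=seed)
    y = data["truth"].to_numpy().astype(int)

    fold_metrics = []
    tprs = []
    aucs = []
    wpc_cuts = []
    psic_cuts = []
    for f in range(k):
        test = folds == f
        train = ~test
        est = _estimator(mode, use_hotspot)
        est.fit(data[train], y[train])
        pred = est.predict(data[test])
        sens, spec, ba = confusion_metrics(counts_from_predictions(y[test], pred))
        scores = est.decision_function(data[test])
        pts, auc = roc_curve(scores, y[test])
        fpr = np.array([p[0] for p in pts])
        tpr = np.array([p[1] for p in pts])
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
        aucs.append(auc)
        wpc_cuts.append(est.wpc_cutoff_)
        if est.psic_cutoff_ is not None:
            psic_cuts.append(est.psic_cutoff_)
        fold_metrics.append(
            {
                "fold": f,
                "n_test": int(test.sum()),
                "sensitivity": sens,
                "specificity": spec,
                "balanced_accuracy": ba,
                "wpc_cutoff": est.wpc_cutoff_,
                "psic_cutoff": est.psic_cutoff_,
                "auc": auc,
            }
        )
    mean_tpr = np.mean(tprs, axis=0)
    return CrossValidationResult(
        fold_metrics=tuple(fold_metrics),
        sensitivity=float(np.mean([m["sensitivity"] for m in fold_metrics])),
        specificity=float(np.mean([m["specificity"] for m in fold_metrics])),
        balanced_accuracy=float(np.mean([m["balanced_accuracy"] for m in fold_metrics])),
        wpc_cutoff=float(np.mean(wpc_cuts)),
        psic_cutoff=float(np.mean(psic_cuts)) if psic_cuts else None,
        fpr_grid=FPR_GRID.copy(),
        mean_tpr=mean_tpr,
        auc=float(np.trapezoid(mean_tpr, FPR_GRID)),
        fold_aucs=tuple(aucs),
    )
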