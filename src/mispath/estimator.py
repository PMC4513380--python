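"""Scikit-learn-style estimator for the trainable cutpoint pipeline.

:class:`CutpointClassifier` applies the ordered decision rules (hotspot gate,
optional PSIC-benign gate, WPC threshold) to precomputed per-variant features
and learns the WPC/PSIC cutoffs by grid search maximizing balanced accuracy.
It composes with scikit-learn model selection; :class:`GeneGroupedKFold` is
the matching cross-validation splitter in which all variants of a gene share
one fold.

Features ``X`` may be a DataFrame with columns ``wpc`` (percent, 0-100),
``psic`` (log-odds delta) and ``hotspot`` (bool), or an ndarray with those
columns in that order (trailing columns optional).  ``y`` is 1 for
pathogenic, 0 for benign.
"""

from __future__ import annotations

from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .types import ConfigurationError, MispathError


def _extract_features(X) -> tuple[np.ndarray, Optional[np.ndarray], Optional[np.ndarray]]:
    if isinstance(X, pd.DataFrame):
        if "wpc" not in X.columns:
            raise ConfigurationError("feature frame must have a 'wpc' column")
        wpc = X["wpc"].to_numpy(dtype=float)
        psic = X["psic"].to_numpy(dtype=float) if "psic" in X.columns else None
        hot = X["hotspot"].to_numpy(dtype=bool) if "hotspot" in X.columns else None
        return wpc, psic, hot
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    wpc = arr[:, 0]
    psic = arr[:, 1] if arr.shape[1] > 1 else None
    hot = arr[:, 2].astype(bool) if arr.shape[1] > 2 else None
    return wpc, psic, hot


def _balanced_accuracy(y: np.ndarray, pred: np.ndarray) -> float:
    pos = y == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise MispathError("both classes required to score balanced accuracy")
    sens = float((pred & pos).sum()) / float(pos.sum())
    spec = float((~pred & neg).sum()) / float(neg.sum())
    return 100.0 * (sens + spec) / 2.0


class CutpointClassifier(BaseEstimator, ClassifierMixin):
    """Ordered-rule pathogenicity classifier with trainable cutpoints.

    Parameters
    ----------
    use_hotspot:
        Gate: variants outside a functional hotspot are benign regardless of
        conservation.
    use_psic:
        Gate: variants with a PSIC delta below ``psic_cutoff`` are benign
        before the WPC threshold is consulted.
    wpc_cutoff, psic_cutoff:
        Fixed cutoffs; ``None`` means learn by grid search in :meth:`fit`
        (WPC step 1 over 0-100, PSIC step 0.01 over the observed range,
        matching the precision at which cutpoints are reported).  Ties in
        balanced accuracy break to the smallest cutoff.
    """

    def __init__(
        self,
        use_hotspot: bool = True,
        use_psic: bool = False,
        wpc_cutoff: Optional[float] = None,
        psic_cutoff: Optional[float] = None,
        wpc_step: float = 1.0,
        psic_step: float = 0.01,
    ):
        self.use_hotspot = use_hotspot
        self.use_psic = use_psic
        self.wpc_cutoff = wpc_cutoff
        self.psic_cutoff = psic_cutoff
        self.wpc_step = wpc_step
        self.psic_step = psic_step

    # -- rule application ---------------------------------------------------

    def _gate(
        self,
        wpc: np.ndarray,
        psic: Optional[np.ndarray],
        hot: Optional[np.ndarray],
        psic_cut: Optional[float],
    ) -> np.ndarray:
        gate = np.ones(len(wpc), dtype=bool)
        if self.use_hotspot:
            if hot is None:
                raise ConfigurationError(
                    "use_hotspot=True requires a 'hotspot' feature"
                )
            gate &= hot
        if self.use_psic:
            if psic is None:
                raise ConfigurationError("use_psic=True requires a 'psic' feature")
            assert psic_cut is not None
            gate &= psic >= psic_cut
        return gate

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        wpc, psic, hot = _extract_features(X)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ConfigurationError("y must be binary (1 = pathogenic)")
        if len(np.unique(y)) < 2:
            raise MispathError("training set is single-class; cannot fit cutpoints")

        if self.wpc_cutoff is not None:
            wpc_grid = np.array([float(self.wpc_cutoff)])
        else:
            wpc_grid = np.arange(0.0, 100.0 + self.wpc_step / 2, self.wpc_step)
        if not self.use_psic:
            psic_grid: list[Optional[float]] = [None]
        elif self.psic_cutoff is not None:
            psic_grid = [float(self.psic_cutoff)]
        else:
            if psic is None:
                raise ConfigurationError("use_psic=True requires a 'psic' feature")
            lo = np.floor(psic.min() / self.psic_step) * self.psic_step
            hi = np.ceil(psic.max() / self.psic_step) * self.psic_step
            psic_grid = list(
                np.round(np.arange(lo, hi + self.psic_step / 2, self.psic_step), 10)
            )

        pos = y == 1
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        best = (-np.inf, None, None)  # (BA, psic_cut, wpc_cut), scanned ascending
        for pc in psic_grid:
            gate = self._gate(wpc, psic, hot, pc)
            # pred matrix over all wpc cutoffs at once
            pred = gate[:, None] & (wpc[:, None] >= wpc_grid[None, :])
            tp = (pred & pos[:, None]).sum(axis=0)
            tn = (~pred & ~pos[:, None]).sum(axis=0)
            ba = 100.0 * (tp / n_pos + tn / n_neg) / 2.0
            j = int(np.argmax(ba))  # first (smallest wpc cutoff) among ties
            if ba[j] > best[0] + 1e-12:
                best = (float(ba[j]), pc, float(wpc_grid[j]))
        self.balanced_accuracy_ = best[0]
        self.psic_cutoff_ = best[1]
        self.wpc_cutoff_ = best[2]
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 3 if isinstance(X, pd.DataFrame) else np.atleast_2d(X).shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "wpc_cutoff_")
        wpc, psic, hot = _extract_features(X)
        gate = self._gate(wpc, psic, hot, self.psic_cutoff_)
        return (gate & (wpc >= self.wpc_cutoff_)).astype(int)

    def decision_function(self, X) -> np.ndarray:
        """Gated continuous score: WPC where the benign gates pass, shifted
        below every passing score where a gate forces benign."""
        check_is_fitted(self, "wpc_cutoff_")
        wpc, psic, hot = _extract_features(X)
        gate = self._gate(wpc, psic, hot, self.psic_cutoff_)
        return np.where(gate, wpc, wpc - 200.0)


class GeneGroupedKFold:
    """K-fold splitter keeping all variants of a gene in one fold.

    Genes are shuffled by a seeded RNG and assigned greedily to the currently
    smallest fold by variant count, producing approximately equal fold sizes.
    """

    def __init__(self, n_splits: int = 5, seed: int = 0):
        if n_splits < 2:
            raise ConfigurationError("n_splits must be >= 2")
        self.n_splits = n_splits
        self.seed = seed

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def fold_assignment(self, groups: Sequence) -> np.ndarray:
        groups = np.asarray(groups)
        genes = np.unique(groups)
        if len(genes) < self.n_splits:
            raise MispathError(
                f"{len(genes)} genes < {self.n_splits} folds"
            )
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(genes))
        counts = {g: int((groups == g).sum()) for g in genes}
        fold_sizes = np.zeros(self.n_splits, dtype=int)
        gene_fold: dict = {}
        for gi in order:
            g = genes[gi]
            f = int(np.argmin(fold_sizes))  # ties -> lowest fold index
            gene_fold[g] = f
            fold_sizes[f] += counts[g]
        return np.array([gene_fold[g] for g in groups])

    def split(self, X, y=None, groups=None) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        if groups is None:
            raise ConfigurationError("GeneGroupedKFold requires groups (gene symbols)")
        folds = self.fold_assignment(groups)
        idx = np.arange(len(folds))
        for f in range(self.n_splits):
            yield idx[folds != f], idx[folds == f]
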