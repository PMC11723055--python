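"""scikit-learn style estimators over epoch matrices.

Samples are epochs: ``X`` is an ``(n_epochs, epoch_samples)`` array of
consecutive, non-overlapping windows of one channel, in temporal order.

* :class:`EpochFeatureExtractor` — transform epochs to the four time-domain
  features (amp, slp, ll, power).
* :class:`SeizureDetector` — the full adaptive-threshold 3-of-4 voting
  detector.  ``fit(X, y)`` runs the (M, N) grid-search calibration per
  feature against per-epoch labels ``y``; ``fit(X)`` keeps the published
  optimal pairs.  ``predict(X)`` replays the closed-loop state machine over
  the epochs and returns the per-epoch seizure flag.

Because the detector is a causal state machine, epochs are *not*
exchangeable samples: predictions depend on epoch order, and shuffling
cross-validators are not meaningful for it.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .closed_loop import run_epochs
from .config import RunConfig
from .detector import DEFAULT_MIN_FEATURES
from .features import (DEFAULT_SLP_SUBWINDOW_MS, FEATURE_NAMES, Mode,
                       feature_matrix)
from .evaluation import grid_search_values
from .signal_io import DEFAULT_FS
from .thresholding import DEFAULT_PARAMS, ThresholdParams


def _check_epochs(X) -> np.ndarray:
    X = check_array(X, ensure_2d=True, dtype="numeric")
    if X.shape[1] < 2:
        raise ValueError("epochs must contain at least 2 samples")
    return X


class EpochFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform an epoch matrix into the four per-epoch features.

    Output columns follow :data:`~epiloop.features.FEATURE_NAMES` order:
    amp, slp, ll, power.
    """

    def __init__(self, fs: float = DEFAULT_FS, mode: Mode = "float",
                 slp_subwindow_ms: float = DEFAULT_SLP_SUBWINDOW_MS):
        self.fs = fs
        self.mode = mode
        self.slp_subwindow_ms = slp_subwindow_ms

    def fit(self, X, y=None):
        X = _check_epochs(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = _check_epochs(X)
        return feature_matrix(X, self.fs, self.mode, self.slp_subwindow_ms)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


class SeizureDetector(ClassifierMixin, BaseEstimator):
    """Adaptive-threshold seizure detector with 3-of-4 voting.

    Parameters
    ----------
    fs, mode, slp_subwindow_ms
        Signal interpretation of the epoch rows.
    threshold_params
        Mapping feature -> (M, N).  None selects the published optima
        (amp (5,4), slp (2,1), power (3,1), ll (2,1)) unless ``fit`` is
        given labels, in which case a per-feature grid search calibrates
        them.
    m_values, n_values
        Calibration grid (default 1..5 each, 25 combinations per feature).
    vote_min_features
        Comparator quorum for declaring a seizure (default 3 of 4).

    Attributes
    ----------
    threshold_params_ : dict[str, ThresholdParams]
        The (M, N) pairs the predictor uses.
    grid_results_ : dict[str, GridResult]
        Per-feature calibration tables (only when ``fit`` received labels).
    """

    def __init__(self, fs: float = DEFAULT_FS, mode: Mode = "float",
                 slp_subwindow_ms: float = DEFAULT_SLP_SUBWINDOW_MS,
                 threshold_params: dict | None = None,
                 m_values: tuple = (1, 2, 3, 4, 5),
                 n_values: tuple = (1, 2, 3, 4, 5),
                 vote_min_features: int = DEFAULT_MIN_FEATURES,
                 freeze_thresholds_during_stim: bool = False,
                 refractory_epochs: int = 0):
        self.fs = fs
        self.mode = mode
        self.slp_subwindow_ms = slp_subwindow_ms
        self.threshold_params = threshold_params
        self.m_values = m_values
        self.n_values = n_values
        self.vote_min_features = vote_min_features
        self.freeze_thresholds_during_stim = freeze_thresholds_during_stim
        self.refractory_epochs = refractory_epochs

    def _config(self) -> RunConfig:
        check_is_fitted(self)
        return RunConfig(
            fs=self.fs, epoch_samples=self.n_features_in_, mode=self.mode,
            slp_subwindow_ms=self.slp_subwindow_ms,
            threshold_params=self.threshold_params_,
            vote_min_features=self.vote_min_features,
            freeze_thresholds_during_stim=self.freeze_thresholds_during_stim,
            refractory_epochs=self.refractory_epochs)

    def fit(self, X, y=None):
        """Set the (M, N) pairs — by grid search when labels are given."""
        X = _check_epochs(X)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([False, True])
        if self.threshold_params is not None:
            self.threshold_params_ = {
                k: p if isinstance(p, ThresholdParams) else ThresholdParams(*p)
                for k, p in self.threshold_params.items()}
            self.grid_results_ = {}
        elif y is None:
            self.threshold_params_ = {
                k: ThresholdParams(*v) for k, v in DEFAULT_PARAMS.items()}
            self.grid_results_ = {}
        else:
            y = np.asarray(y, dtype=bool)
            if y.size != X.shape[0]:
                raise ValueError("y must hold one label per epoch row")
            fmat = feature_matrix(X, self.fs, self.mode, self.slp_subwindow_ms)
            self.grid_results_ = {
                name: grid_search_values(fmat[:, j], y, feature=name,
                                         m_values=self.m_values,
                                         n_values=self.n_values)
                for j, name in enumerate(FEATURE_NAMES)}
            self.threshold_params_ = {
                name: ThresholdParams(*res.best)
                for name, res in self.grid_results_.items()}
        return self

    def predict(self, X) -> np.ndarray:
        """Replay the closed loop over the epochs; per-epoch seizure flags."""
        X = _check_epochs(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"epoch length {X.shape[1]} != fitted {self.n_features_in_}")
        return self.session(X).det

    def session(self, X):
        """Full closed-loop :class:`~epiloop.closed_loop.SessionLog`."""
        return run_epochs(_check_epochs(X), self._config())

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = False
        tags.non_deterministic = False
        return tags
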