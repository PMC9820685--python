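"""Scikit-learn-style transformers for count preprocessing."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import DegenerateInputError


class HousekeepingNormalizer(TransformerMixin, BaseEstimator):
    """Per-sample scaling that equalizes housekeeping geometric means.

    Samples are rows, probes are columns (sklearn convention; the
    probe x sample wrappers in :mod:`mirsig.io` transpose). ``fit`` learns
    the cohort reference level — the arithmetic mean over fit samples of the
    per-sample geometric mean of the housekeeping columns — and ``transform``
    multiplies each row by ``reference_ / geomean_HK(row)``.

    Parameters
    ----------
    housekeeping_mask : array-like of bool, shape (n_probes,)
        True for housekeeping columns. Required.

    Attributes
    ----------
    reference_ : float
        Arithmetic mean of housekeeping geometric means over the fit samples.
    n_features_in_ : int
    """

    def __init__(self, housekeeping_mask=None):
        self.housekeeping_mask = housekeeping_mask

    def _hk_geomeans(self, X: np.ndarray) -> np.ndarray:
        mask = np.asarray(self.housekeeping_mask, dtype=bool)
        if mask.shape != (X.shape[1],):
            raise ValueError(
                "housekeeping_mask length must equal the number of probe columns"
            )
        if not mask.any():
            raise DegenerateInputError("housekeeping_mask selects no probes")
        hk = X[:, mask]
        if (hk <= 0).any():
            raise DegenerateInputError(
                "zero or negative housekeeping count; refusing to pseudo-count"
            )
        return np.exp(np.log(hk).mean(axis=1))

    def fit(self, X, y=None):
        if self.housekeeping_mask is None:
            raise ValueError("housekeeping_mask is required")
        X = check_array(X, dtype=float, ensure_min_samples=1)
        self.n_features_in_ = X.shape[1]
        self.reference_ = float(self._hk_geomeans(X).mean())
        return self

    def scale_factors(self, X) -> np.ndarray:
        """Per-sample multiplicative factors ``reference_ / geomean_HK``."""
        check_is_fitted(self, "reference_")
        X = check_array(X, dtype=float)
        return self.reference_ / self._hk_geomeans(X)

    def transform(self, X) -> np.ndarray:
        X = check_array(X, dtype=float)
        return X * self.scale_factors(X)[:, None]
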