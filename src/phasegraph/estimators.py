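"""scikit-learn style estimators over the functional core.

All estimators consume epoched data ``X`` of shape
``(n_epochs, n_channels, n_times)`` — the layout used by the EEG
machine-learning ecosystem — and expose fitted attributes with trailing
underscores, composing with sklearn pipelines and model selection. They are
thin, stateful facades over :mod:`phasegraph.spectral`,
:mod:`phasegraph.connectivity` and :mod:`phasegraph.graphs`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .bands import CANONICAL_BANDS
from .connectivity import connectivity_matrix
from .graphs import graph_metrics
from .spectral import EpochSet, fit_slope, power_spectrum


def _as_epochs(X, sfreq: float) -> EpochSet:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError(
            "X must be (n_epochs, n_channels, n_times), got "
            f"shape {X.shape}"
        )
    return EpochSet(epochs=X, rate=sfreq,
                    epoch_length_s=X.shape[-1] / sfreq)


class SpectralSlopeEstimator(BaseEstimator):
    """Estimate the 1/f spectral exponent per channel.

    Parameters
    ----------
    sfreq : float
        Sampling frequency of the epochs, Hz.
    fmin, fmax : float
        Log-log fit range in Hz.

    Attributes
    ----------
    alpha_ : ndarray (n_channels,)
        Fitted decay exponents (positive for decaying spectra).
    beta_ : ndarray (n_channels,)
        Fitted intercepts.
    freqs_ : ndarray
        Frequency grid of the underlying power spectra.
    ps_ : ndarray (n_channels, n_freqs)
        Epoch-averaged power spectral densities.
    """

    def __init__(self, sfreq: float = 128.0, fmin: float = 2.0,
                 fmax: float = 43.0):
        self.sfreq = sfreq
        self.fmin = fmin
        self.fmax = fmax

    def fit(self, X, y=None):
        ep = _as_epochs(X, self.sfreq)
        ps = power_spectrum(ep)
        slope = fit_slope(ps, self.fmin, self.fmax)
        self.ps_ = ps.ps
        self.freqs_ = ps.freqs
        self.alpha_ = np.atleast_1d(slope.alpha)
        self.beta_ = np.atleast_1d(slope.beta)
        return self


class LaggedPhaseCoherence(TransformerMixin, BaseEstimator):
    """Band-wise lagged-phase-coherence connectivity matrices.

    ``fit`` stores the matrices for the fitted data; ``transform``
    recomputes them for new epochs and returns the stacked array
    ``(n_bands, n_channels, n_channels)``.

    Attributes
    ----------
    connectivity_ : ndarray (n_bands, n_channels, n_channels)
    band_names_ : list of str
    n_epochs_ : int
    """

    def __init__(self, sfreq: float = 128.0, bands=None):
        self.sfreq = sfreq
        self.bands = bands

    def _bands(self):
        return CANONICAL_BANDS if self.bands is None else tuple(self.bands)

    def fit(self, X, y=None):
        self.connectivity_ = self.transform(X)
        self.band_names_ = [b.name for b in self._bands()]
        self.n_epochs_ = np.asarray(X).shape[0]
        return self

    def transform(self, X):
        ep = _as_epochs(X, self.sfreq)
        mats = [connectivity_matrix(ep, b).w for b in self._bands()]
        return np.stack(mats)


class GraphMetrics(TransformerMixin, BaseEstimator):
    """Weighted topology metrics of a stack of connectivity matrices.

    Input ``X`` is ``(n_bands, n_nodes, n_nodes)`` (one symmetric weight
    matrix per band, as produced by :class:`LaggedPhaseCoherence`).

    Attributes
    ----------
    strength_ : ndarray (n_bands, n_nodes)
    clustering_ : ndarray (n_bands, n_nodes)
    local_efficiency_ : ndarray (n_bands, n_nodes)
    distance_ : ndarray (n_bands, n_nodes, n_nodes)
        Functional (shortest-path) distance matrices.
    char_path_length_ : ndarray (n_bands,)
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        results = [graph_metrics(w) for w in X]
        self.strength_ = np.stack([r.strength for r in results])
        self.clustering_ = np.stack([r.clustering for r in results])
        self.local_efficiency_ = np.stack(
            [r.local_efficiency for r in results])
        self.distance_ = np.stack([r.distance for r in results])
        self.char_path_length_ = np.array(
            [r.char_path_length for r in results])
        return self

    def transform(self, X):
        """Per-band summary features: mean strength, mean clustering,
        mean local efficiency, characteristic path length."""
        check_is_fitted(self, "strength_")
        self.fit(X)
        return np.column_stack([
            self.strength_.mean(axis=1),
            self.clustering_.mean(axis=1),
            self.local_efficiency_.mean(axis=1),
            self.char_path_length_,
        ])

    def fit_transform(self, X, y=None):
        self.fit(X)
        return np.column_stack([
            self.strength_.mean(axis=1),
            self.clustering_.mean(axis=1),
            self.local_efficiency_.mean(axis=1),
            self.char_path_length_,
        ])
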