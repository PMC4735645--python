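"""Lagged phase coherence (LPC) and its significance threshold.

LPC quantifies phase synchronisation between two signals after removing the
instantaneous (zero-phase-lag) component, which in scalp or source EEG is
dominated by volume conduction rather than neural interaction. With rho the
epoch- and bin-averaged coherency of phase-only (unit-modulus) Fourier
coefficients,

    LPC = Im(rho)**2 / (1 - Re(rho)**2)

so purely instantaneous coupling (rho real) scores 0, while a consistent
quarter-cycle lag drives LPC towards 1. At frequency f a quarter-cycle lag
corresponds to a delay of 1/(4f): 25 ms at 10 Hz, 12.5 ms at 20 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .bands import BandDefinition, CANONICAL_BANDS
from .spectral import BandCrossSpectrum, EpochSet, band_cross_spectrum

_RE_TOL = 1.0 - 1e-12


@dataclass
class ConnectivityMatrix:
    """Symmetric LPC weight matrix for one band; weights in [0, 1)."""

    band: BandDefinition
    w: np.ndarray
    n_epochs: int
    labels: list[str] | None = None
    n_bins: int = 1

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        n = self.w.shape[0]
        if self.w.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.w, self.w.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(self.w < 0) or np.any(self.w >= 1):
            raise ValueError("LPC weights must lie in [0, 1)")

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]

    @property
    def n_pairs(self) -> int:
        """Number of undirected edges: n*(n-1)/2 (171 for 19 nodes)."""
        n = self.n_nodes
        return n * (n - 1) // 2


def lagged_phase_coherence(rho: complex) -> float:
    """LPC of a single averaged phase coherency value.

    Returns 0 with a warning when Re(rho)**2 ~ 1 (perfect instantaneous
    coherence leaves no lagged component to measure).
    """
    re2 = rho.real ** 2
    if abs(rho) > 1.0 + 1e-9:
        raise ValueError(f"|rho| = {abs(rho):.6g} > 1 is not a coherency")
    if re2 >= _RE_TOL:
        warnings.warn(
            "perfect instantaneous coherence: lagged phase coherence "
            "is undefined, returning 0", RuntimeWarning, stacklevel=2)
        return 0.0
    val = rho.imag ** 2 / (1.0 - re2)
    return min(float(val), np.nextafter(1.0, 0.0))


def connectivity_from_cross_spectrum(css: BandCrossSpectrum,
                                     labels: list[str] | None = None,
                                     ) -> ConnectivityMatrix:
    """LPC for every unordered node pair from a phase-only cross-spectrum."""
    rho = css.s_phase
    n = rho.shape[0]
    w = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n):
            for j in range(i + 1, n):
                w[i, j] = w[j, i] = lagged_phase_coherence(complex(rho[i, j]))
    return ConnectivityMatrix(band=css.band, w=w, n_epochs=css.n_epochs,
                              labels=labels, n_bins=css.n_bins)


def connectivity_matrix(ep: EpochSet, band: BandDefinition,
                        labels: list[str] | None = None) -> ConnectivityMatrix:
    """End-to-end LPC matrix for one band from epoched data."""
    if ep.n_channels < 2:
        raise ValueError("need at least 2 channels")
    return connectivity_from_cross_spectrum(band_cross_spectrum(ep, band),
                                            labels=labels)


def connectivity_matrices(ep: EpochSet, bands=CANONICAL_BANDS,
                          labels: list[str] | None = None,
                          ) -> dict[str, ConnectivityMatrix]:
    """Band name -> ConnectivityMatrix for every requested band."""
    return {b.name: connectivity_matrix(ep, b, labels=labels) for b in bands}


def significance_threshold(n_epochs: int, alpha_level: float = 0.05,
                           n_pairs: int = 171, n_bins: int = 1) -> float:
    """Bonferroni-corrected asymptotic LPC significance cutoff.

    Under independence the averaged phase coherency over
    N = n_epochs * n_bins unit phasors is isotropic complex Gaussian with
    Var(Im rho) = 1/(2N), so 2*N*LPC is asymptotically chi-square with one
    degree of freedom. The per-pair level is alpha_level / n_pairs.
    The cutoff decreases monotonically in n_epochs and n_bins.
    """
    if n_epochs < 2:
        raise ValueError("need at least 2 epochs")
    if not (0.0 < alpha_level < 1.0):
        raise ValueError("alpha_level must be in (0, 1)")
    if n_pairs < 1 or n_bins < 1:
        raise ValueError("n_pairs and n_bins must be positive")
    per_test = alpha_level / n_pairs
    q = sps.chi2.ppf(1.0 - per_test, df=1)
    return float(q / (2.0 * n_epochs * n_bins))


def phase_lag_delay(freq_hz: float, phase_lag: float = np.pi / 2) -> float:
    """Time delay (s) of a phase lag at a given frequency.

    delay = phase_lag / (2*pi*f); the default quarter cycle gives
    1/(4f) — e.g. 25 ms at 10 Hz, 12.5 ms at 20 Hz.
    """
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    return phase_lag / (2.0 * np.pi * freq_hz)
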