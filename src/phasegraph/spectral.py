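"""Preprocessing, power/cross-spectra, and 1/f slope estimation.

The processing chain mirrors standard resting-state EEG practice: resample
to a nominal 128 Hz, zero-phase band-pass 2-44 Hz, cut into fixed-length
epochs, then estimate per-channel power spectra (Hann-tapered, epoch
averaged) and epoch-averaged Fourier cross-spectral matrices per band.

The 1/f background is summarised by the exponent alpha of
``PS(f) = psi * f**(-alpha)``, obtained by ordinary least squares of
log(PS) on log(f). alpha is reported positive for decaying spectra, so
white noise gives alpha ~ 0, pink noise ~ 1 and Brownian noise ~ 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import statsmodels.api as sm
from scipy import signal

from .bands import BandDefinition, CANONICAL_BANDS
from .recording import Recording


@dataclass
class EpochSet:
    """Epoched multichannel data: array (n_epochs, n_channels, n_times)."""

    epochs: np.ndarray
    rate: float
    epoch_length_s: float

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x channels x times)")
        if self.epochs.shape[0] < 2:
            raise ValueError("need at least 2 epochs")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


@dataclass
class SpectralEstimate:
    """Per-channel power spectral density (units^2/Hz) on a frequency grid."""

    ps: np.ndarray  # (n_channels, n_freqs)
    freqs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.ps < 0):
            raise ValueError("power spectrum must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass
class SpectralSlope:
    """Fitted 1/f exponent: log(PS) = -alpha*log(f) + beta."""

    alpha: np.ndarray | float
    beta: np.ndarray | float
    f_range: tuple[float, float]
    pooled: bool


@dataclass
class BandCrossSpectrum:
    """Epoch- and bin-averaged cross-spectral matrix for one band.

    ``s`` averages the raw cross-spectra; ``s_phase`` averages outer
    products of unit-modulus (phase-only) Fourier coefficients, so its
    off-diagonal entries are the amplitude-blind coherency rho used by the
    lagged-phase-coherence estimator.
    """

    band: BandDefinition
    s: np.ndarray
    s_phase: np.ndarray
    n_epochs: int
    n_bins: int


def preprocess(rec: Recording, target_rate: float = 128.0,
               band: tuple[float, float] = (2.0, 44.0)) -> Recording:
    """Resample to ``target_rate`` and zero-phase band-pass filter.

    Resampling is polyphase; the filter is a 4th-order Butterworth applied
    forward-backward. Output sample count is ``floor(n * target / orig)``.
    """
    if target_rate > rec.rate:
        raise ValueError(
            f"target_rate {target_rate} exceeds recording rate {rec.rate}"
        )
    lo, hi = band
    if not (0.0 < lo < hi < target_rate / 2.0):
        raise ValueError(
            f"band {band} must lie within (0, {target_rate / 2}) Hz"
        )
    data = rec.data
    if target_rate != rec.rate:
        frac = Fraction(target_rate / rec.rate).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator,
                                    axis=1)
        n_out = int(rec.n_samples * target_rate // rec.rate)
        data = data[:, :n_out]
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=target_rate,
                        output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    return Recording(data=data, rate=target_rate, labels=rec.labels,
                     coords=rec.coords, meta=dict(rec.meta))


def epoch(rec: Recording, epoch_length_s: float = 2.0,
          overlap: float = 0.0) -> EpochSet:
    """Cut a Recording into fixed-length epochs; trailing remainder dropped."""
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    n_len = int(round(epoch_length_s * rec.rate))
    if n_len < 2:
        raise ValueError("epoch too short (need >= 2 samples)")
    if n_len > rec.n_samples:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than one "
            f"{epoch_length_s} s epoch ({n_len} samples)"
        )
    step = max(1, int(round(n_len * (1.0 - overlap))))
    starts = range(0, rec.n_samples - n_len + 1, step)
    epochs = np.stack([rec.data[:, s:s + n_len] for s in starts])
    return EpochSet(epochs=epochs, rate=rec.rate,
                    epoch_length_s=epoch_length_s)


def power_spectrum(ep: EpochSet) -> SpectralEstimate:
    """Epoch-averaged Hann-tapered periodogram per channel."""
    freqs, p = signal.periodogram(ep.epochs, fs=ep.rate, window="hann",
                                  axis=-1, detrend=False)
    ps = p.mean(axis=0)
    return SpectralEstimate(ps=ps, freqs=freqs)


def _slope_window(ps: SpectralEstimate, f_lo: float, f_hi: float):
    mask = (ps.freqs >= f_lo) & (ps.freqs <= f_hi) & (ps.freqs > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"fewer than 3 frequency points in [{f_lo}, {f_hi}] Hz"
        )
    p = ps.ps[:, mask]
    if np.any(p <= 0):
        raise ValueError(
            "nonpositive power inside the fit range; cannot take log"
        )
    return np.log(ps.freqs[mask]), np.log(p)


def fit_slope(ps: SpectralEstimate, f_lo: float = 2.0, f_hi: float = 43.0,
              pooled: bool = False) -> SpectralSlope:
    """OLS fit of log(PS) on log(f); alpha is the negated coefficient.

    ``pooled=True`` stacks all channels into one regression; otherwise one
    fit per channel.
    """
    logf, logp = _slope_window(ps, f_lo, f_hi)
    if pooled:
        coef = np.polyfit(np.tile(logf, logp.shape[0]), logp.ravel(), 1)
        return SpectralSlope(alpha=float(-coef[0]), beta=float(coef[1]),
                             f_range=(f_lo, f_hi), pooled=True)
    coefs = np.polyfit(logf, logp.T, 1)  # (2, n_channels)
    return SpectralSlope(alpha=-coefs[0], beta=coefs[1],
                         f_range=(f_lo, f_hi), pooled=False)


@dataclass
class SlopeComparison:
    """Group difference in 1/f steepness from a pooled interaction model."""

    statistic: float  # t for alpha_B - alpha_A (positive: B steeper)
    p_value: float
    df: float
    alpha_diff: float


def compare_slopes(ps_a: SpectralEstimate, ps_b: SpectralEstimate,
                   f_lo: float = 2.0, f_hi: float = 43.0) -> SlopeComparison:
    """Compare 1/f steepness between two groups of spectra.

    Pooled regression of log(PS) on log(f) with a group dummy and a
    group x log(f) interaction; the interaction t tests whether the decay
    exponents differ. Channels (rows of each estimate) are the units.
    The sign convention follows alpha: statistic > 0 means group B decays
    more steeply (larger alpha).
    """
    la, pa = _slope_window(ps_a, f_lo, f_hi)
    lb, pb = _slope_window(ps_b, f_lo, f_hi)
    if pa.shape[0] < 2 or pb.shape[0] < 2:
        raise ValueError("need at least 2 units (channels) per group")
    x = np.concatenate([np.tile(la, pa.shape[0]), np.tile(lb, pb.shape[0])])
    y = np.concatenate([pa.ravel(), pb.ravel()])
    g = np.concatenate([np.zeros(pa.size), np.ones(pb.size)])
    design = sm.add_constant(np.column_stack([x, g, x * g]))
    fit = sm.OLS(y, design).fit()
    # coefficient 3 is the slope change for group B; alpha = -slope
    t = float(-fit.tvalues[3])
    return SlopeComparison(statistic=t, p_value=float(fit.pvalues[3]),
                           df=float(fit.df_resid),
                           alpha_diff=float(-fit.params[3]))


def band_cross_spectrum(ep: EpochSet, band: BandDefinition,
                        ) -> BandCrossSpectrum:
    """Epoch-averaged cross-spectral matrix over the band's Fourier bins.

    Each epoch is Fourier transformed untapered; cross-spectra (outer
    products) are averaged over epochs and over all bins with
    f_lo <= f <= f_hi. The phase-only variant discards amplitudes by
    normalising every Fourier coefficient to unit modulus first.

    No taper is applied here (unlike the power-spectrum route): tapering
    correlates adjacent Fourier bins, which would break the independence
    of the per-bin phase coherencies that the asymptotic significance
    threshold assumes.
    """
    n_times = ep.epochs.shape[-1]
    freqs = np.fft.rfftfreq(n_times, d=1.0 / ep.rate)
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    n_bins = int(mask.sum())
    if n_bins == 0:
        need = 1.0 / (band.f_hi - band.f_lo)
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz has no Fourier "
            f"bin at epoch length {n_times / ep.rate:.3g} s; need epochs of "
            f"at least {need:.3g} s"
        )
    coefs = np.fft.rfft(ep.epochs, axis=-1)[:, :, mask]
    # (n_epochs, n_channels, n_bins)
    mag = np.abs(coefs)
    unit = np.where(mag > 0, coefs / np.where(mag > 0, mag, 1.0), 0.0)
    s = np.einsum("eif,ejf->ij", coefs, np.conj(coefs))
    s_phase = np.einsum("eif,ejf->ij", unit, np.conj(unit))
    denom = ep.n_epochs * n_bins
    return BandCrossSpectrum(band=band, s=s / denom, s_phase=s_phase / denom,
                             n_epochs=ep.n_epochs, n_bins=n_bins)


def cross_spectral_set(ep: EpochSet, bands=CANONICAL_BANDS,
                       ) -> dict[str, BandCrossSpectrum]:
    """Band name -> BandCrossSpectrum for every requested band."""
    return {b.name: band_cross_spectrum(ep, b) for b in bands}
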