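"""Spectral estimation and parameterization.

Power spectra are estimated with Welch's method and decomposed into an
aperiodic 1/f component plus Gaussian oscillatory peaks:

    log10 P(f) = b - chi * log10(f) + sum_n a_n * exp(-(f - mu_n)^2 / (2 sigma_n^2))

where ``b`` is the offset, ``chi`` the aperiodic exponent, and each peak has
amplitude ``a_n`` (log10-power units above the aperiodic fit), centre ``mu_n``
(Hz) and bandwidth ``sigma_n`` (Hz).  The height of the largest in-band peak,
expressed in dB as ``10 * a``, serves as a 1/f-corrected signal-to-noise
ratio for band-limited oscillations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, signal

from .data import Recording

__all__ = [
    "PowerSpectrum",
    "SpectralFit",
    "FitSettings",
    "compute_psd",
    "fit_spectrum",
    "fit_channels",
    "band_snr_db",
    "in_band_peak",
    "detect_oscillation_bands",
]


@dataclass
class PowerSpectrum:
    """One-sided power spectral density on a regular frequency grid.

    ``power`` has shape (n_freqs,) for a single signal or
    (n_freqs, n_signals) for multichannel input; linear power units.
    """

    freqs: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freqs.ndim != 1 or not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be a strictly increasing 1-D grid")
        if np.any(self.freqs < 0):
            raise ValueError("freqs must be non-negative")
        if self.power.shape[0] != self.freqs.size:
            raise ValueError("power and freqs length mismatch")

    @property
    def n_signals(self) -> int:
        return 1 if self.power.ndim == 1 else self.power.shape[1]

    def channel(self, i: int) -> np.ndarray:
        return self.power if self.power.ndim == 1 else self.power[:, i]


@dataclass(frozen=True)
class FitSettings:
    """Settings for spectral parameterization.

    ``peak_width_limits`` bound the Gaussian bandwidth ``sigma`` in Hz;
    ``peak_threshold`` is in units of the residual standard deviation;
    ``min_peak_height`` is in log10-power units above the aperiodic fit.
    Only the fixed (knee-free) aperiodic mode is supported.
    """

    peak_width_limits: tuple[float, float] = (0.5, 12.0)
    max_n_peaks: int = 5
    min_peak_height: float = 0.0
    peak_threshold: float = 2.0
    aperiodic_mode: str = "fixed"
    fit_range: tuple[float, float] = (1.0, 45.0)

    def __post_init__(self) -> None:
        if self.aperiodic_mode != "fixed":
            raise ValueError("only the 'fixed' aperiodic mode is supported")
        if not 0 < self.peak_width_limits[0] < self.peak_width_limits[1]:
            raise ValueError("peak_width_limits must be increasing and positive")


@dataclass
class SpectralFit:
    """Parameterized spectrum: aperiodic component plus Gaussian peaks.

    ``peaks`` is an (n_peaks, 3) array of rows (a_n, mu_n, sigma_n), sorted by
    descending amplitude.  ``residual_error`` is the mean absolute error of
    the model in log10-power on the fit grid.
    """

    offset: float
    exponent: float
    peaks: np.ndarray
    fit_range: tuple[float, float]
    residual_error: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=np.float64).reshape(-1, 3)

    @property
    def n_peaks(self) -> int:
        return self.peaks.shape[0]

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        """Aperiodic component b - chi*log10(f), in log10-power."""
        freqs = np.asarray(freqs, dtype=np.float64)
        return self.offset - self.exponent * np.log10(freqs)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        """Full model evaluation in log10-power."""
        return self.aperiodic(freqs) + _gaussians(freqs, self.peaks)


def _gaussians(freqs: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(freqs, dtype=np.float64))
    for a, mu, sigma in np.asarray(peaks).reshape(-1, 3):
        out = out + a * np.exp(-((freqs - mu) ** 2) / (2.0 * sigma**2))
    return out


def compute_psd(
    rec: Recording | np.ndarray,
    window_s: float = 3.0,
    overlap_frac: float = 0.0,
    fs: float | None = None,
) -> PowerSpectrum:
    """Welch power spectral density (Hann taper, density normalization).

    Defaults: 3 s windows with 0% overlap, hence 1/3 Hz resolution.  Accepts
    a :class:`Recording` or a plain array (then ``fs`` is required); columns
    are treated as channels.
    """
    if isinstance(rec, Recording):
        data, fs = rec.data, rec.fs
    else:
        if fs is None:
            raise ValueError("fs is required for plain-array input")
        data = np.asarray(rec, dtype=np.float64)
    nperseg = int(round(window_s * fs))
    if nperseg < 2:
        raise ValueError("window_s * fs must be at least 2 samples")
    if data.shape[0] < nperseg:
        raise ValueError(
            f"recording ({data.shape[0]} samples) shorter than one "
            f"{nperseg}-sample window"
        )
    noverlap = int(round(overlap_frac * nperseg))
    freqs, power = signal.welch(
        data,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        axis=0,
    )
    return PowerSpectrum(freqs=freqs, power=power, resolution=1.0 / window_s)


def _robust_aperiodic_seed(logf: np.ndarray, logp: np.ndarray) -> np.ndarray:
    """Seed (offset, exponent) by least squares, down-weighting peak bins.

    Points lying more than 2.5 median absolute residuals above the initial
    line (candidate oscillatory peaks) are excluded and the line refit.
    """
    design = np.column_stack([np.ones_like(logf), -logf])
    coef, *_ = np.linalg.lstsq(design, logp, rcond=None)
    resid = logp - design @ coef
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = resid <= 2.5 * mad
        if keep.sum() >= 3:
            coef, *_ = np.linalg.lstsq(design[keep], logp[keep], rcond=None)
    return coef


def _extract_peak_guesses(
    freqs: np.ndarray, resid: np.ndarray, settings: FitSettings
) -> list[tuple[float, float, float]]:
    """Iteratively pull Gaussian guesses off the flattened spectrum."""
    resid = resid.copy()
    lo_w, hi_w = settings.peak_width_limits
    guesses: list[tuple[float, float, float]] = []
    for _ in range(settings.max_n_peaks):
        i = int(np.argmax(resid))
        height = resid[i]
        if height < settings.peak_threshold * np.std(resid):
            break
        if height <= max(settings.min_peak_height, 1e-6):
            break
        mu = freqs[i]
        # half-height width -> sigma via FWHM = 2.355 sigma
        half = height / 2.0
        j_hi = i
        while j_hi + 1 < resid.size and resid[j_hi + 1] > half:
            j_hi += 1
        j_lo = i
        while j_lo - 1 >= 0 and resid[j_lo - 1] > half:
            j_lo -= 1
        fwhm = freqs[min(j_hi + 1, resid.size - 1)] - freqs[max(j_lo - 1, 0)]
        sigma = float(np.clip(fwhm / 2.355, lo_w, hi_w))
        guesses.append((float(height), float(mu), sigma))
        resid -= height * np.exp(-((freqs - mu) ** 2) / (2.0 * sigma**2))
    return guesses


def fit_spectrum(
    ps: PowerSpectrum | tuple[np.ndarray, np.ndarray],
    settings: FitSettings | None = None,
    channel: int = 0,
) -> SpectralFit:
    """Decompose one power spectrum into aperiodic + Gaussian-peak model.

    Procedure: (1) robust seed of the aperiodic line on log-log axes;
    (2) iterative extraction of up to ``max_n_peaks`` Gaussian guesses from
    the flattened residual, each accepted only if its height clears the
    peak threshold (in residual standard deviations) and the minimum
    amplitude; (3) joint bounded nonlinear least-squares refinement of all
    Gaussians; (4) aperiodic refit on the peak-subtracted spectrum.

    Raises ``ValueError`` when fewer than 5 positive-power frequency points
    fall inside the fit range.  A failed nonlinear refinement returns a
    flagged fit (``converged=False``) with the seed aperiodic parameters.
    """
    settings = settings or FitSettings()
    if isinstance(ps, PowerSpectrum):
        freqs, power = ps.freqs, ps.channel(channel)
    else:
        freqs, power = np.asarray(ps[0], float), np.asarray(ps[1], float)
    lo, hi = settings.fit_range
    mask = (freqs >= lo) & (freqs <= hi) & (power > 0) & (freqs > 0)
    f = freqs[mask]
    if f.size < 5:
        raise ValueError(
            f"only {f.size} usable frequency points in fit range {settings.fit_range}"
        )
    logf = np.log10(f)
    logp = np.log10(power[mask])

    offset, exponent = _robust_aperiodic_seed(logf, logp)
    resid = logp - (offset - exponent * logf)
    guesses = _extract_peak_guesses(f, resid, settings)

    converged = True
    peaks = np.empty((0, 3))
    if guesses:
        lo_w, hi_w = settings.peak_width_limits
        x0, lb, ub = [], [], []
        for a, mu, sigma in guesses:
            x0 += [a, mu, sigma]
            lb += [0.0, lo, lo_w]
            ub += [np.inf, hi, hi_w]
        x0 = np.clip(x0, lb, ub)

        def residual_fn(x: np.ndarray) -> np.ndarray:
            return _gaussians(f, x.reshape(-1, 3)) - resid

        try:
            sol = optimize.least_squares(
                residual_fn, x0, bounds=(lb, ub), method="trf", max_nfev=2000
            )
            peaks = sol.x.reshape(-1, 3)
        except Exception:
            converged = False
            peaks = np.empty((0, 3))

    if peaks.size:
        # drop peaks refined away to negligible amplitude
        keep = peaks[:, 0] > max(settings.min_peak_height, 1e-6)
        peaks = peaks[keep]

    # refit aperiodic component on the peak-subtracted spectrum
    flattened = logp - _gaussians(f, peaks)
    design = np.column_stack([np.ones_like(logf), -logf])
    (offset, exponent), *_ = np.linalg.lstsq(design, flattened, rcond=None)

    order = np.argsort(peaks[:, 0])[::-1] if peaks.size else []
    peaks = peaks[order] if peaks.size else np.empty((0, 3))
    model = (offset - exponent * logf) + _gaussians(f, peaks)
    residual_error = float(np.mean(np.abs(logp - model)))
    return SpectralFit(
        offset=float(offset),
        exponent=float(exponent),
        peaks=peaks,
        fit_range=(float(lo), float(hi)),
        residual_error=residual_error,
        converged=converged,
    )


def fit_channels(
    ps: PowerSpectrum, settings: FitSettings | None = None
) -> list[SpectralFit]:
    """Fit every channel of a multichannel spectrum."""
    return [fit_spectrum(ps, settings, channel=i) for i in range(ps.n_signals)]


def in_band_peak(
    fit: SpectralFit, band: tuple[float, float]
) -> tuple[float, float, float] | None:
    """Largest-amplitude fitted peak whose centre lies inside ``band``."""
    best = None
    for a, mu, sigma in fit.peaks:
        if band[0] <= mu <= band[1] and (best is None or a > best[0]):
            best = (float(a), float(mu), float(sigma))
    return best


def band_snr_db(fit: SpectralFit, band: tuple[float, float]) -> float:
    """1/f-corrected SNR in dB: 10x the largest in-band peak amplitude.

    Peak amplitudes are in log10-power units above the aperiodic fit, so
    ``10 * a`` is the dB height of the spectral peak over the 1/f
    contribution.  Returns 0 when no fitted peak lies in the band.
    """
    peak = in_band_peak(fit, band)
    return 0.0 if peak is None else 10.0 * peak[0]


def detect_oscillation_bands(
    fits: Sequence[SpectralFit],
    freq_range: tuple[float, float] = (5.0, 20.0),
) -> list[tuple[float, float]]:
    """Pool per-channel peaks into candidate oscillation bands.

    All fitted peaks with centres inside ``freq_range`` are pooled across
    channels, sorted, and merged into clusters wherever adjacent centres are
    closer than one pooled-mean bandwidth.  Each cluster is summarized by its
    median centre and median bandwidth; clusters are returned sorted by
    descending total peak amplitude, so the strongest rhythm comes first.
    """
    pooled = [
        (a, mu, sigma)
        for fit in fits
        for a, mu, sigma in fit.peaks
        if freq_range[0] <= mu <= freq_range[1]
    ]
    if not pooled:
        return []
    pooled.sort(key=lambda p: p[1])
    mean_sigma = float(np.mean([p[2] for p in pooled]))
    clusters: list[list[tuple[float, float, float]]] = [[pooled[0]]]
    for p in pooled[1:]:
        if p[1] - clusters[-1][-1][1] < mean_sigma:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    out = []
    for cl in clusters:
        strength = sum(a for a, _, _ in cl)
        peak_hz = float(np.median([mu for _, mu, _ in cl]))
        bandwidth = float(np.median([s for _, _, s in cl]))
        out.append((strength, peak_hz, bandwidth))
    out.sort(key=lambda t: -t[0])
    return [(peak_hz, bw) for _, peak_hz, bw in out]
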