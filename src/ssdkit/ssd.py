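"""Spatio-spectral decomposition (SSD).

Given a multichannel recording X (t samples x k channels), SSD finds spatial
filters w maximizing the Rayleigh quotient

    SNR(w) = (w' C_S w) / (w' C_N w)

where C_S is the covariance of the signal-band-filtered data and C_N the
covariance of the flanking-band ("noise") filtered data.  The maximizers are
the solutions of the generalized eigenvalue problem C_S W = C_N W Lambda,
with eigenvalues equal to the achieved band-limited SNR.  Filters estimated
from narrowband covariances are then applied to the *broadband* data, which
preserves harmonics and hence the waveform shape of non-sinusoidal rhythms.

Rank-deficient covariances (e.g. after component removal or re-referencing)
are handled by solving the problem on a whitened expansion of the top-r
eigenvectors of C_S and mapping the filters back to channel space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .data import BandDefinition, Recording

__all__ = [
    "SSDModel",
    "bandpass_filter",
    "band_covariances",
    "solve_gevd",
    "fit_ssd",
    "apply_filters",
]

#: eigenvalues below this fraction of the largest count as numerically zero
RANK_TOL = 1e-6
#: maximum tolerated relative asymmetry of input covariance matrices
ASYM_TOL = 1e-10


@dataclass
class SSDModel:
    """Fitted SSD decomposition.

    ``filters`` holds one spatial filter per column (k x r); ``eigenvalues``
    are the corresponding Rayleigh quotients, descending.  ``rank`` is the
    numerical rank of the signal covariance actually used; when it is below
    the channel count the problem was solved on the whitened expansion.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    band: BandDefinition
    c_signal: np.ndarray
    c_noise: np.ndarray
    rank: int
    channel_names: list[str] = field(default_factory=list)
    fs: float | None = None

    @property
    def n_channels(self) -> int:
        return self.filters.shape[0]

    @property
    def n_components(self) -> int:
        return self.filters.shape[1]

    def rayleigh_quotients(self) -> np.ndarray:
        """Recompute w'C_S w / w'C_N w per filter (consistency check)."""
        W = self.filters
        num = np.einsum("ij,jk,ki->i", W.T, self.c_signal, W)
        den = np.einsum("ij,jk,ki->i", W.T, self.c_noise, W)
        return num / den

    def to_json(self, path: str) -> None:
        payload = {
            "filters": self.filters.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "band": {
                "signal_band": list(self.band.signal_band),
                "flank_left": list(self.band.flank_left),
                "flank_right": list(self.band.flank_right),
                "filter_order": self.band.filter_order,
            },
            "c_signal": self.c_signal.tolist(),
            "c_noise": self.c_noise.tolist(),
            "rank": int(self.rank),
            "channel_names": self.channel_names,
            "fs": self.fs,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SSDModel":
        with open(path) as fh:
            d = json.load(fh)
        band = BandDefinition(
            signal_band=tuple(d["band"]["signal_band"]),
            flank_left=tuple(d["band"]["flank_left"]),
            flank_right=tuple(d["band"]["flank_right"]),
            filter_order=int(d["band"]["filter_order"]),
        )
        return cls(
            filters=np.asarray(d["filters"], float),
            eigenvalues=np.asarray(d["eigenvalues"], float),
            band=band,
            c_signal=np.asarray(d["c_signal"], float),
            c_noise=np.asarray(d["c_noise"], float),
            rank=int(d["rank"]),
            channel_names=list(d.get("channel_names", [])),
            fs=d.get("fs"),
        )


def bandpass_filter(
    rec: Recording, low: float, high: float, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    The filter is applied forward and backward so the effective magnitude
    response is squared (doubled order) and the phase response is zero —
    essential so that downstream waveform-asymmetry measures are not
    distorted by filter phase.
    """
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz outside (0, Nyquist={rec.fs / 2}) Hz"
        )
    settle = 3.0 / low  # seconds for the impulse response to ring down
    if rec.duration < 3 * settle:
        warnings.warn(
            f"recording ({rec.duration:.2f} s) shorter than 3x the filter "
            f"settling length ({settle:.2f} s); edge artifacts likely",
            stacklevel=2,
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.copy_with(signal.sosfiltfilt(sos, rec.data, axis=0))


def _edge_samples(band: BandDefinition, fs: float, n_samples: int) -> int:
    """Samples to discard at each end: max(1 s, 3 cycles of the lowest edge)."""
    edge = int(round(max(1.0, 3.0 / band.flank_left[0]) * fs))
    if n_samples - 2 * edge < max(int(fs), 16):
        edge = max(0, (n_samples - max(int(fs), 16)) // 2)
    return edge


def band_covariances(
    rec: Recording, band: BandDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """Signal- and noise-band covariance matrices.

    The signal contribution is the recording band-passed to the signal band;
    the noise contribution is the sample-wise sum of the two flank-filtered
    recordings.  Covariances are computed after column mean removal,
    normalized by the sample count, and with filter edge transients excluded.
    """
    band.validate_for_fs(rec.fs)
    order = band.filter_order
    xs = bandpass_filter(rec, *band.signal_band, order=order).data
    xn = (
        bandpass_filter(rec, *band.flank_left, order=order).data
        + bandpass_filter(rec, *band.flank_right, order=order).data
    )
    edge = _edge_samples(band, rec.fs, rec.n_samples)
    sl = slice(edge, rec.n_samples - edge) if edge else slice(None)
    xs, xn = xs[sl], xn[sl]
    xs = xs - xs.mean(axis=0)
    xn = xn - xn.mean(axis=0)
    n = xs.shape[0]
    c_s = xs.T @ xs / n
    c_n = xn.T @ xn / n
    return 0.5 * (c_s + c_s.T), 0.5 * (c_n + c_n.T)


def _check_symmetric(c: np.ndarray, name: str) -> np.ndarray:
    c = np.asarray(c, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError(f"{name} must be square")
    scale = np.abs(c).max()
    if scale > 0 and np.abs(c - c.T).max() > max(ASYM_TOL * scale, 1e-300):
        raise ValueError(f"{name} is not symmetric within tolerance")
    return 0.5 * (c + c.T)


def solve_gevd(
    c_signal: np.ndarray, c_noise: np.ndarray, rank_tol: float = RANK_TOL
) -> tuple[np.ndarray, np.ndarray, int]:
    """Solve C_S W = C_N W Lambda with rank-deficiency handling.

    The numerical rank r of C_S is the number of its eigenvalues above
    ``rank_tol`` relative to the largest.  At full rank the generalized
    problem is solved directly.  Otherwise the problem is projected onto the
    whitened expansion M = V_{1:r} diag(1/sqrt(lambda_i)) built from the
    top-r eigenvectors of C_S, solved there, and the filters mapped back to
    channel space as W = M W~.

    Returns (W, eigenvalues, r) with eigenvalues descending and filter
    columns normalized to unit Euclidean norm.
    """
    c_s = _check_symmetric(c_signal, "c_signal")
    c_n = _check_symmetric(c_noise, "c_noise")
    if c_s.shape != c_n.shape:
        raise ValueError("covariance matrices must have the same shape")
    k = c_s.shape[0]

    evals, evecs = linalg.eigh(c_s)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals[0] <= 0:
        raise ValueError("c_signal has no positive eigenvalues")
    r = int(np.sum(evals > rank_tol * evals[0]))

    noise_evals = linalg.eigh(c_n, eigvals_only=True)
    if noise_evals[-1] <= 0:
        raise ValueError("c_noise is numerically zero; contrast undefined")

    if r == k:
        try:
            lam, w = linalg.eigh(c_s, c_n)
            order = np.argsort(lam)[::-1]
            w, lam = w[:, order], lam[order]
            w = w / np.linalg.norm(w, axis=0, keepdims=True)
            return w, lam, r
        except linalg.LinAlgError:
            pass  # C_N not positive definite; fall back to the expansion
    # whitened-expansion path (also the fallback when C_N is near-singular)
    m = evecs[:, :r] / np.sqrt(evals[:r])
    cs_r = m.T @ c_s @ m
    cn_r = m.T @ c_n @ m
    lam, w_r = linalg.eigh(0.5 * (cs_r + cs_r.T), 0.5 * (cn_r + cn_r.T))
    order = np.argsort(lam)[::-1]
    w = m @ w_r[:, order]
    w = w / np.linalg.norm(w, axis=0, keepdims=True)
    return w, lam[order], r


def fit_ssd(rec: Recording, band: BandDefinition) -> SSDModel:
    """Estimate SSD spatial filters for a recording and band definition.

    Composes :func:`band_covariances` and :func:`solve_gevd`; filter signs
    are fixed so each associated spatial pattern has a positive maximum
    (see the patterns module).
    """
    if rec.n_channels < 2:
        raise ValueError("SSD requires at least two channels")
    c_s, c_n = band_covariances(rec, band)
    w, lam, r = solve_gevd(c_s, c_n)
    model = SSDModel(
        filters=w,
        eigenvalues=lam,
        band=band,
        c_signal=c_s,
        c_noise=c_n,
        rank=r,
        channel_names=list(rec.channel_names),
        fs=rec.fs,
    )
    from .patterns import fix_component_signs

    return fix_component_signs(model)


def apply_filters(
    model: SSDModel, rec: Recording, n: int | None = None
) -> np.ndarray:
    """Project broadband data through the first ``n`` spatial filters.

    Filters are applied to the *unfiltered* recording, so harmonics of
    non-sinusoidal rhythms — which share the source's spatial profile —
    are carried into the component time series.  Returns an
    (n_samples, n) array.
    """
    if rec.n_channels != model.n_channels:
        raise ValueError(
            f"recording has {rec.n_channels} channels, model expects "
            f"{model.n_channels}"
        )
    if n is None:
        n = model.n_components
    if not 0 <= n <= model.n_components:
        raise ValueError(f"n must be in [0, {model.n_components}]")
    return rec.data @ model.filters[:, :n]
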