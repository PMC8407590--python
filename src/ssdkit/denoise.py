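"""Narrowband noise removal with spatial filters.

Line noise (and similar equipment artifacts) is spatially stereotyped:
it projects into all channels through a fixed spatial profile.  Instead of
notch-filtering in time — which carves a spectral hole and rings in the
time domain — the noise subspace is estimated with SSD and subtracted
linearly:

    X_cleaned = X - sum_{j=1..n} a_j s_j

where s_j are the noise components obtained by applying the spatial filters
to the broadband data and a_j the matching spatial patterns.  The signal
band is the noise peak +- half_bw (default 1.75 Hz); the contrast band, the
activity that should *remain* in the data, is broadened to run from 1 Hz up
to the lower signal edge and from the upper signal edge to noise_hz + 40 Hz
(capped below Nyquist).  The cleaned data keep their full spectrum apart
from the removed subspace — no notch is introduced — at the cost of one
rank per removed component.
"""

from __future__ import annotations

import numpy as np

from .data import BandDefinition, Recording
from .patterns import patterns_from_covariance
from .ssd import SSDModel, apply_filters, fit_ssd

__all__ = ["fit_noise_model", "subtract_components", "denoise"]


def noise_band(noise_hz: float, half_bw: float, fs: float) -> BandDefinition:
    """Band definition for noise removal at ``noise_hz``."""
    lo = noise_hz - half_bw
    hi = noise_hz + half_bw
    upper = min(fs / 2 - 1.0, noise_hz + 40.0)
    if upper <= hi:
        raise ValueError(
            f"no room for an upper contrast band above {hi} Hz at fs={fs}"
        )
    if lo <= 1.0:
        raise ValueError("noise peak too close to 1 Hz for the contrast band")
    return BandDefinition(
        signal_band=(lo, hi), flank_left=(1.0, lo), flank_right=(hi, upper)
    )


def fit_noise_model(
    rec: Recording, noise_hz: float = 60.0, half_bw: float = 1.75
) -> SSDModel:
    """Estimate spatial filters maximizing SNR in the noise band.

    The leading components capture the spatially coherent narrowband
    artifact; their Rayleigh quotients indicate how dominant it is.
    """
    if noise_hz + half_bw >= rec.fs / 2:
        raise ValueError(
            f"noise band up to {noise_hz + half_bw} Hz exceeds Nyquist "
            f"({rec.fs / 2} Hz)"
        )
    return fit_ssd(rec, noise_band(noise_hz, half_bw, rec.fs))


def subtract_components(rec: Recording, model: SSDModel, n: int) -> Recording:
    """Linearly remove the first ``n`` noise components from the raw data."""
    if not 0 <= n <= model.rank:
        raise ValueError(f"n must be in [0, rank={model.rank}]")
    if n == 0:
        return rec.copy_with(rec.data.copy())
    a = patterns_from_covariance(model).patterns[:, :n]
    s = apply_filters(model, rec, n)
    return rec.copy_with(rec.data - s @ a.T)


def count_noise_components(
    rec: Recording, model: SSDModel, threshold_db: float = 5.0
) -> int:
    """Components whose noise-band 1/f-corrected SNR exceeds the threshold."""
    from .components import score_components

    cs = score_components(model, rec, threshold_db=threshold_db)
    return int(cs.table["retained"].sum())


def denoise(
    rec: Recording,
    noise_hzs: float | list[float] = 60.0,
    half_bw: float = 1.75,
    n: int | None = None,
) -> Recording:
    """Remove one or several narrowband artifacts sequentially.

    For each frequency a noise model is fit on the current data and ``n``
    components subtracted; with ``n=None`` the count is chosen automatically
    as the number of components whose noise-band SNR exceeds 5 dB (at least
    one is always removed).
    """
    if np.isscalar(noise_hzs):
        noise_hzs = [float(noise_hzs)]
    out = rec
    for hz in noise_hzs:
        model = fit_noise_model(out, hz, half_bw)
        n_remove = n
        if n_remove is None:
            n_remove = max(1, count_noise_components(out, model))
            n_remove = min(n_remove, model.rank)
        out = subtract_components(out, model, n_remove)
    return out
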