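"""Core containers and file I/O for multichannel continuous recordings.

A :class:`Recording` holds a time x channels voltage matrix together with its
sampling rate, channel labels and (optionally) 3-D electrode coordinates in
millimetres.  A :class:`BandDefinition` specifies the signal pass-band and the
two flanking noise bands used for spatio-spectral decomposition.

On disk a recording is a plain matrix file (delimited text or raw float64
binary) plus a JSON sidecar carrying the metadata; this keeps the native
format dependency-free and trivially inspectable.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Recording",
    "BandDefinition",
    "read_recording",
    "write_recording",
    "make_band",
]


@dataclass
class Recording:
    """Continuous multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Voltage time series; time runs along rows, channels along columns.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels, one per column.
    channel_positions : ndarray, shape (n_channels, 3), optional
        Electrode coordinates in mm; required only by geometry-dependent
        operations (spatial-spread quantification).
    units : str
        Free-text amplitude units; carried through, never converted.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    channel_positions: np.ndarray | None = None
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n_samples, n_channels) array")
        n_samples, n_channels = self.data.shape
        if n_samples < 1:
            raise ValueError("recording must contain at least one sample")
        if n_channels < 2:
            raise ValueError("recording must contain at least two channels")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(n_channels)]
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{n_channels} data columns"
            )
        if len(set(self.channel_names)) != n_channels:
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or Inf values")
        if self.channel_positions is not None:
            self.channel_positions = np.asarray(
                self.channel_positions, dtype=np.float64
            )
            if self.channel_positions.shape != (n_channels, 3):
                raise ValueError(
                    "channel_positions must have shape (n_channels, 3); got "
                    f"{self.channel_positions.shape}"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        """New Recording sharing this one's metadata but with other samples."""
        return Recording(
            data=np.asarray(data, dtype=np.float64),
            fs=self.fs,
            channel_names=list(self.channel_names),
            channel_positions=None
            if self.channel_positions is None
            else self.channel_positions.copy(),
            units=self.units,
        )


@dataclass(frozen=True)
class BandDefinition:
    """Signal band plus two flanking noise bands, all in Hz.

    The signal band carries the oscillation of interest; the flanks define
    what counts as noise for the Rayleigh-quotient contrast.  Bands must be
    ordered ``flank_left < signal < flank_right`` and may touch but not
    overlap.
    """

    signal_band: tuple[float, float]
    flank_left: tuple[float, float]
    flank_right: tuple[float, float]
    filter_order: int = 4

    def __post_init__(self) -> None:
        fl, fr, sb = self.flank_left, self.flank_right, self.signal_band
        seq = (fl[0], fl[1], sb[0], sb[1], fr[0], fr[1])
        if not all(np.isfinite(seq)):
            raise ValueError("band edges must be finite")
        if not (0 < fl[0] < fl[1] <= sb[0] < sb[1] <= fr[0] < fr[1]):
            raise ValueError(
                "band edges must satisfy 0 < flank_left < signal_band "
                f"< flank_right; got {seq}"
            )
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")

    def validate_for_fs(self, fs: float) -> None:
        """Raise if the uppermost edge reaches the Nyquist frequency."""
        if self.flank_right[1] >= fs / 2:
            raise ValueError(
                f"upper flank edge {self.flank_right[1]} Hz is at or above "
                f"Nyquist ({fs / 2} Hz)"
            )


def make_band(
    peak_hz: float,
    half_bw: float = 2.0,
    flank_gap: float = 1.0,
    flank_width: float = 1.0,
    filter_order: int = 4,
) -> BandDefinition:
    """Build a band definition centred on an oscillation peak.

    The defaults reproduce the canonical alpha-band choice: ``peak_hz=10``
    gives a signal band of (8, 12) Hz and flanking noise bands of (6, 7) and
    (13, 14) Hz.

    Parameters
    ----------
    peak_hz : float
        Centre frequency of the oscillation of interest.
    half_bw : float
        Half-width of the signal band.
    flank_gap : float
        Gap between the signal band and each flank (0 makes them contiguous).
    flank_width : float
        Width of each flanking band.
    """
    lo = peak_hz - half_bw
    hi = peak_hz + half_bw
    fl = (lo - flank_gap - flank_width, lo - flank_gap)
    fr = (hi + flank_gap, hi + flank_gap + flank_width)
    if fl[0] <= 0:
        raise ValueError(
            f"lower flank edge {fl[0]:.3g} Hz is not positive; "
            "reduce half_bw / flank_gap / flank_width"
        )
    return BandDefinition(
        signal_band=(lo, hi),
        flank_left=fl,
        flank_right=fr,
        filter_order=filter_order,
    )


def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".json"


def read_recording(path: str, sidecar: str | None = None) -> Recording:
    """Read a recording from a matrix file plus JSON sidecar.

    ``path`` may be delimited text (comma or tab, autodetected) or raw
    float64 binary.  The sidecar supplies ``fs``, ``channel_names`` and
    optionally ``channel_positions`` (mm) and ``units``; for binary input it
    is mandatory and must also supply ``shape``.  If ``sidecar`` is omitted,
    a file with the same stem and a ``.json`` extension is used.
    """
    if sidecar is None:
        sidecar = _sidecar_path(path)
    meta: dict = {}
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = json.load(fh)

    is_binary = path.endswith((".bin", ".dat", ".raw"))
    if is_binary:
        if "shape" not in meta:
            raise ValueError(
                "binary recordings require a sidecar with a 'shape' entry"
            )
        n_samples, n_channels = (int(v) for v in meta["shape"])
        raw = np.fromfile(path, dtype=np.float64)
        if raw.size != n_samples * n_channels:
            raise ValueError(
                f"binary file holds {raw.size} float64 values, expected "
                f"{n_samples}x{n_channels}"
            )
        data = raw.reshape(n_samples, n_channels)
    else:
        with open(path) as fh:
            first = fh.readline()
        delim = "," if first.count(",") >= first.count("\t") else "\t"
        data = np.loadtxt(path, delimiter=delim, ndmin=2)

    if "fs" not in meta:
        raise ValueError(f"sidecar {sidecar!r} is missing the 'fs' entry")
    names = meta.get("channel_names") or []
    if names and len(names) != data.shape[1]:
        raise ValueError(
            f"sidecar lists {len(names)} channel names but matrix has "
            f"{data.shape[1]} columns"
        )
    positions = meta.get("channel_positions")
    if positions is not None:
        positions = np.asarray(positions, dtype=np.float64)
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channel_names=list(names),
        channel_positions=positions,
        units=meta.get("units", "a.u."),
    )


def write_recording(rec: Recording, path: str, sidecar: str | None = None) -> None:
    """Write a recording as matrix file plus JSON sidecar.

    Binary (``.bin``/``.dat``/``.raw`` extension) is bit-exact on round-trip;
    delimited text uses 17 significant digits, which also round-trips float64
    exactly in practice.
    """
    if sidecar is None:
        sidecar = _sidecar_path(path)
    if path.endswith((".bin", ".dat", ".raw")):
        rec.data.astype(np.float64).tofile(path)
    else:
        np.savetxt(path, rec.data, delimiter="\t", fmt="%.17g")
    meta: dict = {
        "fs": rec.fs,
        "shape": [int(rec.n_samples), int(rec.n_channels)],
        "channel_names": list(rec.channel_names),
        "units": rec.units,
    }
    if rec.channel_positions is not None:
        meta["channel_positions"] = rec.channel_positions.tolist()
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)


def grid_positions(
    n_rows: int = 8, n_cols: int = 8, pitch_mm: float = 10.0
) -> np.ndarray:
    """Planar electrode-grid coordinates (z = 0), row-major, in mm."""
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    out = np.zeros((n_rows * n_cols, 3))
    out[:, 0] = cc.ravel() * pitch_mm
    out[:, 1] = rr.ravel() * pitch_mm
    return out
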