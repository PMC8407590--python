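"""End-to-end analysis pipeline.

Wires the modules into the standard workflow: spectra and spectral
parameterization per electrode -> oscillation-band detection (or a
user-fixed band) -> SSD fit -> spatial patterns and spread -> component
scoring and SNR-based selection -> cycle-by-cycle waveform analysis of the
retained components.  All outputs are plain tab-separated tables plus a
JSON run log; runs are byte-reproducible from config + seed.
"""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .components import score_components
from .data import BandDefinition, Recording, make_band, read_recording
from .patterns import patterns_from_covariance, spatial_spread
from .spectral import FitSettings, compute_psd, detect_oscillation_bands, fit_channels
from .ssd import fit_ssd
from .synth import simulate_recording
from .waveform import burst_mask, segment_cycles, summarize_bursts

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "input": None,  # path to matrix file (sidecar alongside); or use simulate
    "simulate": None,  # {"duration": s, "seed": int, "with_line_noise": bool}
    "band": None,  # [low, high] Hz; None -> detect from electrode spectra
    "flanks": None,  # [l0, l1, r0, r1] Hz; None -> derived from band
    "detect_range": [5.0, 20.0],
    "filter_order": 4,
    "window_s": 3.0,
    "fit_range": [1.0, 45.0],
    "snr_db": 5.0,
    "burst_amp_fraction": 0.75,
    "seed": 0,
    "float_fmt": "%.12g",
}


def _load_config(config: dict | str) -> dict:
    if isinstance(config, str):
        with open(config) as fh:
            config = json.load(fh)
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(DEFAULT_CONFIG)
    merged.update(config)
    return merged


def _resolve_band(cfg: dict, fs: float, fits) -> BandDefinition:
    if cfg["band"] is not None:
        lo, hi = (float(v) for v in cfg["band"])
        if cfg["flanks"] is not None:
            l0, l1, r0, r1 = (float(v) for v in cfg["flanks"])
            band = BandDefinition(
                signal_band=(lo, hi),
                flank_left=(l0, l1),
                flank_right=(r0, r1),
                filter_order=int(cfg["filter_order"]),
            )
        else:
            band = make_band(
                (lo + hi) / 2, (hi - lo) / 2, filter_order=int(cfg["filter_order"])
            )
    else:
        detected = detect_oscillation_bands(fits, tuple(cfg["detect_range"]))
        if not detected:
            raise RuntimeError("no oscillation band detected; specify one")
        peak_hz, _bw = detected[0]
        band = make_band(peak_hz, filter_order=int(cfg["filter_order"]))
    band.validate_for_fs(fs)
    return band


def run_pipeline(config: dict | str, out_dir: str) -> dict:
    """Run the full workflow; write tables and a run log to ``out_dir``.

    Returns a summary dict (band used, components retained, output paths).
    Raises before any computation when the config is invalid.
    """
    cfg = _load_config(config)
    if (cfg["input"] is None) == (cfg["simulate"] is None):
        raise ValueError("config must name exactly one of 'input' or 'simulate'")
    fmt = cfg["float_fmt"]
    os.makedirs(out_dir, exist_ok=True)

    if cfg["input"] is not None:
        rec = read_recording(cfg["input"])
    else:
        sim = dict(cfg["simulate"] or {})
        sim.setdefault("seed", cfg["seed"])
        rec, _truth = simulate_recording(**sim)

    # fail fast on an impossible band before any heavy computation
    if cfg["band"] is not None:
        lo, hi = (float(v) for v in cfg["band"])
        if not 0 < lo < hi < rec.fs / 2:
            raise ValueError(
                f"band {cfg['band']} outside (0, Nyquist={rec.fs / 2}) Hz"
            )

    settings = FitSettings(fit_range=tuple(cfg["fit_range"]))
    ps = compute_psd(rec, window_s=cfg["window_s"])
    fits = fit_channels(ps, settings)
    peaks_rows = [
        {"channel": i, "peak_hz": mu, "amplitude": a, "bandwidth": sigma,
         "exponent": fits[i].exponent}
        for i, fit in enumerate(fits)
        for a, mu, sigma in fit.peaks
    ]
    pd.DataFrame(
        peaks_rows,
        columns=["channel", "peak_hz", "amplitude", "bandwidth", "exponent"],
    ).to_csv(os.path.join(out_dir, "electrode_peaks.tsv"), sep="\t",
             index=False, float_format=fmt)

    band = _resolve_band(cfg, rec.fs, fits)
    model = fit_ssd(rec, band)
    model.to_json(os.path.join(out_dir, "model.json"))

    cs = score_components(
        model, rec, settings=settings, window_s=cfg["window_s"],
        threshold_db=cfg["snr_db"],
    )
    cs.table.to_csv(os.path.join(out_dir, "components.tsv"), sep="\t",
                    index=False, float_format=fmt)

    pat = patterns_from_covariance(model)
    if rec.channel_positions is not None:
        spread = spatial_spread(pat, rec.channel_positions)
        spread.to_csv(os.path.join(out_dir, "spread.tsv"), sep="\t",
                      index=False, float_format=fmt)

    retained = cs.table.index[cs.table["retained"]].tolist()
    cycle_targets = retained if retained else [0]
    cycle_frames = []
    for j in cycle_targets:
        peak_hz = cs.table.loc[j, "peak_hz"]
        if not np.isfinite(peak_hz):
            continue
        ct = segment_cycles(cs.series[:, j], rec.fs, float(peak_hz))
        ct = burst_mask(ct, amp_fraction_threshold=cfg["burst_amp_fraction"])
        ct.insert(0, "component", j)
        cycle_frames.append(ct)
    if cycle_frames:
        cycles = pd.concat(cycle_frames, ignore_index=True)
        cycles.to_csv(os.path.join(out_dir, "cycles.tsv"), sep="\t",
                      index=False, float_format=fmt)
        burst_summary = {
            int(j): summarize_bursts(f)
            for j, f in zip(cycle_targets, cycle_frames)
        }
    else:
        burst_summary = {}

    log = {
        "config": cfg,
        "versions": {
            "ssdkit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "band": {
            "signal_band": list(band.signal_band),
            "flank_left": list(band.flank_left),
            "flank_right": list(band.flank_right),
        },
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "rank": int(model.rank),
        "n_retained": int(len(retained)),
        "burst_summary": burst_summary,
    }
    with open(os.path.join(out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return log
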