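"""Spatial patterns and spatial-spread quantification.

Spatial filters (backward model) are not interpretable as source
topographies; the corresponding spatial patterns (forward model) are.  For a
filter matrix W and signal-band covariance C_S the patterns are

    A = C_S W (W' C_S W)^+

with + the Moore-Penrose pseudoinverse, which enforces A'W = Id on the
retained subspace so that X ~= A S_hat reconstructs the band-limited
electrode signals.  At full rank this coincides with A = (W^-1)'.

The spatial spread of a component is summarized by the largest normalized
pattern coefficient among electrodes within a fixed radius (default 25 mm)
of the pattern maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ssd import SSDModel

__all__ = [
    "PatternSet",
    "patterns_from_covariance",
    "fix_component_signs",
    "spatial_spread",
]


@dataclass
class PatternSet:
    """Spatial patterns, one component per column, aligned with the model."""

    patterns: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_components(self) -> int:
        return self.patterns.shape[1]


def _patterns(filters: np.ndarray, c_signal: np.ndarray) -> np.ndarray:
    gram = filters.T @ c_signal @ filters
    return c_signal @ filters @ np.linalg.pinv(gram)


def fix_component_signs(model: SSDModel) -> SSDModel:
    """Resolve the per-component sign ambiguity deterministically.

    A filter/pattern pair is only defined up to a joint sign.  Convention:
    the largest-|coefficient| entry of each pattern column is made positive,
    negating the paired filter column in tandem (the outer product a w' is
    unchanged).  Idempotent.
    """
    a = _patterns(model.filters, model.c_signal)
    flips = np.ones(a.shape[1])
    for j in range(a.shape[1]):
        i = int(np.argmax(np.abs(a[:, j])))
        if a[i, j] < 0:
            flips[j] = -1.0
    return replace(model, filters=model.filters * flips)


def patterns_from_covariance(model: SSDModel) -> PatternSet:
    """Compute spatial patterns A = C_S W (W'C_S W)^+ from a fitted model."""
    if model.filters.shape[0] != model.c_signal.shape[0]:
        raise ValueError("filter and covariance dimensions disagree")
    return PatternSet(
        patterns=_patterns(model.filters, model.c_signal),
        channel_names=list(model.channel_names),
    )


def spatial_spread(
    pat: PatternSet,
    positions: np.ndarray,
    radius_mm: float = 25.0,
) -> pd.DataFrame:
    """Quantify spatial spread of each component's pattern.

    Per component: take |pattern|, normalize to maximum 1, locate the
    maximum electrode, and report the largest normalized coefficient among
    the *other* electrodes within ``radius_mm`` Euclidean distance of the
    maximum.  A focal source yields a small ``neighbor_max``; a spatially
    spread (or deep/common) source yields a value near 1.  Components whose
    maximum has no neighbor within the radius are flagged undefined.
    """
    if positions is None:
        raise ValueError("electrode positions are required for spread analysis")
    positions = np.asarray(positions, dtype=np.float64)
    if positions.shape != (pat.n_channels, 3):
        raise ValueError(
            f"positions shape {positions.shape} does not match "
            f"{pat.n_channels} channels"
        )
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    rows = []
    for j in range(pat.n_components):
        p = np.abs(pat.patterns[:, j])
        p = p / p.max()
        imax = int(np.argmax(p))
        dist = np.linalg.norm(positions - positions[imax], axis=1)
        neigh = (dist <= radius_mm) & (np.arange(p.size) != imax)
        if neigh.any():
            neighbor_max, defined = float(p[neigh].max()), True
        else:
            neighbor_max, defined = np.nan, False
        rows.append(
            {
                "component": j,
                "max_channel": imax,
                "max_channel_name": pat.channel_names[imax]
                if pat.channel_names
                else str(imax),
                "neighbor_max": neighbor_max,
                "n_neighbors": int(neigh.sum()),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)
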