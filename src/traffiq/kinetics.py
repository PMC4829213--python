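"""Per-cell kinetic analysis of nucleocytoplasmic transport traces.

Operates on measured per-frame traces (nuclear / cytoplasmic MFI per
channel) and derives the readouts used to separate the two export
programs: the C:N ratio and its min-to-max transition duration, burst
versus gradual classification, reporter onset times and VLP assembly
onset.

Conventions
-----------
* The min-to-max transition duration is estimated from the 10% and 90%
  crossings of the normalized trace, rescaled by 1/0.8 — robust to
  endpoint noise and exact for linear ramps.
* Onsets require the criterion to hold for two consecutive frames, which
  suppresses single-frame shot-noise excursions.
* A cell counts as having exported at all when its final raw C:N ratio
  is at least 1.5; among exporters, a transition faster than one hour is
  a burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellTrace", "DegenerateTraceError",
    "normalize_minmax", "detect_onset", "align_to_peak",
    "transition_duration", "classify_export", "vlp_onset", "cn_ratio",
]

EXPORTED_CN_THRESHOLD = 1.5
BURST_MAX_DURATION_H = 1.0


class DegenerateTraceError(ValueError):
    """Raised for constant or otherwise unusable traces."""


@dataclass
class CellTrace:
    """Measured time series and derived kinetic calls for one cell."""

    time_h: np.ndarray
    nuclear_mfi: np.ndarray
    cytoplasmic_mfi: np.ndarray
    punctae_count: np.ndarray | None = None
    membrane_punctae: np.ndarray | None = None
    rev_cyto_mfi: np.ndarray | None = None
    # derived
    rev_onset_h: float = float("nan")
    transition_duration_h: float = float("nan")
    export_class: str = "none"
    vlp_onset_h: float = float("nan")

    def cn_ratio(self) -> np.ndarray:
        return cn_ratio(self.nuclear_mfi, self.cytoplasmic_mfi)


def cn_ratio(nuclear_mfi: np.ndarray, cytoplasmic_mfi: np.ndarray) -> np.ndarray:
    """Cytoplasmic:nuclear MFI ratio; NaN where the nuclear MFI vanishes."""
    nuc = np.asarray(nuclear_mfi, dtype=float)
    cyt = np.asarray(cytoplasmic_mfi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(nuc > 0, cyt / np.maximum(nuc, 1e-12), np.nan)
    return out


def normalize_minmax(series: np.ndarray) -> np.ndarray:
    """Rescale a series to [0, 1] by its own minimum and maximum."""
    s = np.asarray(series, dtype=float)
    if s.size < 2:
        raise DegenerateTraceError("need at least two frames to normalize")
    lo, hi = np.nanmin(s), np.nanmax(s)
    if not hi > lo:
        raise DegenerateTraceError("constant series cannot be min-max normalized")
    return (s - lo) / (hi - lo)


def detect_onset(
    series: np.ndarray, time_h: np.ndarray, background_sd: float
) -> float:
    """First time a reporter exceeds 3x the background SD for 2 consecutive frames.

    Returns NaN (no-onset flag) when the criterion is never met.
    """
    s = np.asarray(series, dtype=float)
    above = s > 3.0 * background_sd
    sustained = above[:-1] & above[1:]
    idx = np.nonzero(sustained)[0]
    if len(idx) == 0:
        return float("nan")
    return float(time_h[idx[0]])


def align_to_peak(cn_traces) -> tuple[np.ndarray, np.ndarray]:
    """Align normalized traces so each trace's maximum sits at offset zero.

    Returns ``(matrix, offsets)`` where ``matrix[i, j]`` holds trace ``i``
    at frame offset ``offsets[j]`` relative to its peak, NaN where a trace
    does not cover that offset.  Ties in the maximum break to the earliest
    frame.
    """
    traces = [np.asarray(t, dtype=float) for t in cn_traces]
    if not traces:
        raise DegenerateTraceError("empty trace collection")
    peaks = [int(np.nanargmax(t)) for t in traces]  # argmax takes the first max
    lo = -max(peaks)
    hi = max(len(t) - 1 - p for t, p in zip(traces, peaks))
    offsets = np.arange(lo, hi + 1)
    mat = np.full((len(traces), len(offsets)), np.nan)
    for i, (t, p) in enumerate(zip(traces, peaks)):
        start = -p - lo
        mat[i, start:start + len(t)] = t
    return mat, offsets


def _interp_crossing(time_h, series, level, last=False):
    """Linear-interpolated time at which ``series`` crosses ``level``."""
    s = np.asarray(series, dtype=float)
    t = np.asarray(time_h, dtype=float)
    ge = s >= level
    if not ge.any():
        return float("nan")
    if last:
        # last upward crossing: final frame below the level that precedes a
        # frame at/above it
        j_last = int(np.nonzero(ge)[0][-1])
        below = np.nonzero(~ge[:j_last])[0]
        if len(below) == 0:
            return float(t[0])
        i0 = int(below[-1])
        i1 = i0 + 1
    else:
        first_ge = int(np.nonzero(ge)[0][0])
        if first_ge == 0:
            return float(t[0])
        i0, i1 = first_ge - 1, first_ge
    s0, s1 = s[i0], s[i1]
    if s1 == s0:
        return float(t[i1])
    frac = (level - s0) / (s1 - s0)
    return float(t[i0] + frac * (t[i1] - t[i0]))


def transition_duration(cn_series_normalized, time_h) -> float:
    """Min-to-max duration of a normalized C:N trace, in hours.

    Computed as ``(t_last_cross_0.9 - t_first_cross_0.1) / 0.8`` with
    linear interpolation between frames: the full-range duration under a
    local-linearity assumption.  NaN (undefined flag) when the trace never
    reaches 0.9.
    """
    s = np.asarray(cn_series_normalized, dtype=float)
    t = np.asarray(time_h, dtype=float)
    if np.nanmax(s) < 0.9:
        return float("nan")
    t10 = _interp_crossing(t, s, 0.1, last=False)
    t90 = _interp_crossing(t, s, 0.9, last=True)
    return (t90 - t10) / 0.8


def classify_export(
    cn_trace: np.ndarray, time_h: np.ndarray
) -> tuple[str, float]:
    """Classify a raw C:N trace as burst, gradual or none.

    Returns ``(export_class, transition_duration_h)``.  A final C:N below
    1.5 means the cell never exported; among exporters a min-to-max
    transition under one hour is a burst.  An undefined duration with a
    final C:N at or above 1.5 classifies gradual (with a warning).
    """
    cn = np.asarray(cn_trace, dtype=float)
    finite = np.isfinite(cn)
    if not finite.any():
        return "none", float("nan")
    final = cn[finite][-1]
    if final < EXPORTED_CN_THRESHOLD:
        return "none", float("nan")
    try:
        norm = normalize_minmax(np.where(finite, cn, np.nan))
    except DegenerateTraceError:
        return "gradual", float("nan")
    dur = transition_duration(norm, time_h)
    if np.isnan(dur):
        import warnings

        warnings.warn(
            "exported cell with undefined transition duration; classifying gradual",
            stacklevel=2,
        )
        return "gradual", dur
    return ("burst" if dur < BURST_MAX_DURATION_H else "gradual"), dur


def vlp_onset(membrane_punctae_series, time_h, min_count: int = 3) -> float:
    """First time the membrane punctae count is >= 3 for 2 consecutive frames.

    NaN (no-onset flag) when never sustained.
    """
    s = np.asarray(membrane_punctae_series, dtype=float)
    above = s >= min_count
    sustained = above[:-1] & above[1:]
    idx = np.nonzero(sustained)[0]
    if len(idx) == 0:
        return float("nan")
    return float(time_h[idx[0]])
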