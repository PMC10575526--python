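"""Per-vessel flow summaries from red-blood-cell velocity traces.

A velocity trace is a short (<= 3.4 s) series of cell velocities (mm/s)
sampled at the video frame rate (200 or 300 Hz). The raw flow parameters
are the extrema and mean of the trace and the cardiac modulation index

    pulsatility = (v_max - v_min) / (v_max + v_min),

unitless and confined to [0, 1] for non-negative traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import median_filter

from .errors import InputError, UndefinedPulsatilityError

VALID_RATES_HZ = (200, 300)
MAX_DURATION_S = 3.4


@dataclass
class VelocityTrace:
    samples: np.ndarray    # mm/s
    rate: float            # Hz
    vessel_id: Optional[str] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InputError("velocity trace must be a non-empty 1-D series")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("velocity trace contains non-finite samples")
        if self.rate not in VALID_RATES_HZ:
            raise InputError(f"rate must be one of {VALID_RATES_HZ} Hz, got {self.rate}")
        if self.duration > MAX_DURATION_S + 1e-9:
            raise InputError(
                f"trace duration {self.duration:.2f} s exceeds the {MAX_DURATION_S} s maximum"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class FlowSummary:
    v_max: float           # mm/s
    v_min: float           # mm/s
    v_ave: float           # mm/s
    pulsatility: float     # unitless


def summarize_trace(trace: VelocityTrace, smooth_window: Optional[int] = None) -> FlowSummary:
    """Raw flow parameters of one trace.

    ``smooth_window`` (odd sample count) applies a moving-median filter
    before taking extrema; off by default — the raw measures use the
    unsmoothed plot. The mean is always taken over the raw samples.
    """
    x = trace.samples
    if x.size < 2:
        raise InputError("need at least 2 samples to summarize a trace")
    y = x
    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise InputError("smooth_window must be a positive odd sample count")
        y = median_filter(x, size=smooth_window, mode="nearest")
    v_max = float(y.max())
    v_min = float(y.min())
    v_ave = float(x.mean())
    denom = v_max + v_min
    if denom == 0:
        raise UndefinedPulsatilityError("v_max + v_min = 0; pulsatility undefined")
    return FlowSummary(
        v_max=v_max, v_min=v_min, v_ave=v_ave, pulsatility=(v_max - v_min) / denom
    )
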