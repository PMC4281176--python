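"""Segmentation of a maneuver into the five morphology-analysis zones.

Z1 covers the rise from flow onset to the peak, Z2 the near-peak band, Z3 the
descending limb, Z4 the end-of-test region (at least the final second) and Z5
the whole curve.  All zones are half-open sample-index intervals on the one
shared time base, so they index the VT, FT and FV representations identically.
Consecutive zones may overlap; together Z1-Z4 cover everything from onset to
the end of the record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .config import DEFAULT_CONFIG, ThresholdConfig
from .errors import DegenerateCurveError
from .signal_core import Maneuver, SpiroIndices, smooth

__all__ = ["ZoneInterval", "ZoneSegmentation", "segment"]


class ZoneInterval(NamedTuple):
    """Half-open sample-index interval [start, end)."""

    start: int
    end: int

    @property
    def size(self) -> int:
        return max(0, self.end - self.start)

    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass(frozen=True)
class ZoneSegmentation:
    z1: ZoneInterval
    z2: ZoneInterval
    z3: ZoneInterval
    z4: ZoneInterval
    z5: ZoneInterval
    onset: int
    pef_index: int


def segment(
    maneuver: Maneuver,
    indices: SpiroIndices,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> ZoneSegmentation:
    """Deterministic zone boundaries for one maneuver.

    The onset is the first sample whose (smoothed) flow reaches
    ``cfg.onset_fraction`` of PEF; Z2 is the contiguous band around the PEF
    sample where flow stays at or above ``cfg.z2_fraction`` of PEF; Z3 runs
    from the right edge of Z2 to the start of Z4; Z4 covers the final
    ``max(1 s, cfg.z4_window)`` of the record.
    """
    if indices.pef <= 0:
        raise DegenerateCurveError("peak expiratory flow must be positive")
    time = maneuver.time
    n = maneuver.n
    window = max(1.0, cfg.z4_window)
    if maneuver.duration < window:
        raise DegenerateCurveError(
            f"record of {maneuver.duration:.2f} s is shorter than the "
            f"{window:.2f} s end-of-test window"
        )

    f = smooth(maneuver.flow, cfg.smoothing_window, maneuver.sample_rate)
    pef_idx = int(np.argmax(maneuver.flow))

    above_onset = np.flatnonzero(f >= cfg.onset_fraction * indices.pef)
    onset = int(above_onset[0]) if above_onset.size else 0
    onset = min(onset, pef_idx)

    band = cfg.z2_fraction * indices.pef
    lo = pef_idx
    while lo > 0 and f[lo - 1] >= band:
        lo -= 1
    hi = pef_idx
    while hi < n - 1 and f[hi + 1] >= band:
        hi += 1

    z4_start = max(0, n - int(round(window * maneuver.sample_rate)) - 1)
    z1 = ZoneInterval(onset, pef_idx + 1)
    z2 = ZoneInterval(lo, hi + 1)
    z3 = ZoneInterval(z2.end, max(z2.end, z4_start))
    z4 = ZoneInterval(z4_start, n)
    z5 = ZoneInterval(0, n)
    return ZoneSegmentation(
        z1=z1, z2=z2, z3=z3, z4=z4, z5=z5, onset=onset, pef_index=pef_idx
    )
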