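"""Curve representations and classical spirometric index computation.

A forced-expiration maneuver is held as three aligned series -- time (s),
expiratory flow (L/s, positive) and cumulative expired volume (L) -- on one
uniform time base.  The volume-time (VT), flow-time (FT) and flow-volume (FV)
representations of the maneuver are all views of these arrays.

The classical indices follow the ATS/ERS back-extrapolation convention: the
time origin ``T_zero`` is where the steepest tangent of the VT curve crosses
zero volume, the back-extrapolated volume ``BEV`` is the recorded volume at
that instant, and FEV1, PEFT and FET100 are all measured from ``T_zero``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import savgol_filter

from .config import DEFAULT_CONFIG, ThresholdConfig
from .errors import DegenerateCurveError, InputError

__all__ = [
    "Maneuver",
    "SpiroIndices",
    "integrate_flow",
    "differentiate",
    "smooth",
    "compute_t_zero",
    "compute_indices",
]

_MIN_SAMPLES = 10
_UNIFORMITY_RTOL = 0.01
_VOLUME_START_TOL = 0.05  # L


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional")
    return arr


def _check_time(time: np.ndarray) -> None:
    if np.any(np.diff(time) <= 0):
        raise InputError("time must be strictly increasing")


def _is_uniform(time: np.ndarray, rtol: float = _UNIFORMITY_RTOL) -> bool:
    dt = np.diff(time)
    return bool(dt.min() > 0 and (dt.max() - dt.min()) <= rtol * np.median(dt))


def integrate_flow(flow, time) -> np.ndarray:
    """Cumulative expired volume (L) from flow (L/s) by the trapezoid rule."""
    flow = _as_1d(flow, "flow")
    time = _as_1d(time, "time")
    if flow.shape != time.shape:
        raise InputError("flow and time must have equal length")
    _check_time(time)
    return cumulative_trapezoid(flow, time, initial=0.0)


def differentiate(signal, time, order: int = 1) -> np.ndarray:
    """First or second time derivative by central differences.

    Interior points use central differences, endpoints one-sided ones; the
    output has the same length as the input.  Apply :func:`smooth` first when
    the signal is noisy.
    """
    if order not in (1, 2):
        raise InputError(f"derivative order must be 1 or 2, got {order!r}")
    signal = _as_1d(signal, "signal")
    time = _as_1d(time, "time")
    if signal.shape != time.shape:
        raise InputError("signal and time must have equal length")
    _check_time(time)
    d = np.gradient(signal, time)
    if order == 2:
        d = np.gradient(d, time)
    return d


def smooth(signal, window: float, sample_rate: float) -> np.ndarray:
    """Local quadratic least-squares smoothing over a time window (s).

    ``window=0`` is the identity.  Constant signals are invariant and the
    length is preserved.  The window is converted to an odd sample count; a
    window shorter than three samples degenerates to the identity.
    """
    signal = _as_1d(signal, "signal")
    if window < 0:
        raise InputError("smoothing window must be >= 0")
    n = signal.size
    if n == 0 or window == 0:
        return signal.copy()
    duration = (n - 1) / sample_rate
    if window > duration:
        raise InputError(
            f"smoothing window {window} s exceeds record duration {duration:.3f} s"
        )
    w = int(round(window * sample_rate))
    if w % 2 == 0:
        w += 1
    if w < 3:
        return signal.copy()
    w = min(w, n if n % 2 == 1 else n - 1)
    return savgol_filter(signal, window_length=w, polyorder=2)


@dataclass
class Maneuver:
    """One forced-expiration recording on a uniform time base."""

    time: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = _as_1d(self.time, "time")
        self.flow = _as_1d(self.flow, "flow")
        self.volume = _as_1d(self.volume, "volume")
        if not (self.time.shape == self.flow.shape == self.volume.shape):
            raise InputError("time, flow and volume must have equal length")
        if self.time.size < _MIN_SAMPLES:
            raise InputError(
                f"maneuver needs at least {_MIN_SAMPLES} samples, got {self.time.size}"
            )
        _check_time(self.time)
        if not _is_uniform(self.time):
            raise InputError("time base must be uniform within 1%; use from_samples")
        if abs(self.volume[0]) > _VOLUME_START_TOL:
            raise InputError(
                f"volume must start within +/-{_VOLUME_START_TOL} L of zero, "
                f"got {self.volume[0]:.3f} L"
            )

    # -- construction -------------------------------------------------------

    @classmethod
    def from_samples(
        cls,
        time,
        flow=None,
        volume=None,
        *,
        resample_rate: float | None = None,
        meta: dict | None = None,
    ) -> "Maneuver":
        """Build a maneuver from raw samples.

        Exactly the supplied series are kept; a missing flow is derived from
        volume by differentiation and a missing volume from flow by trapezoidal
        integration.  Non-uniform input (or an explicit ``resample_rate`` that
        differs from the native rate by more than 1%) is linearly resampled to
        a uniform grid.
        """
        time = _as_1d(time, "time")
        _check_time(time)
        if flow is None and volume is None:
            raise InputError("at least one of flow or volume is required")
        if flow is not None:
            flow = _as_1d(flow, "flow")
            if flow.shape != time.shape:
                raise InputError("flow and time must have equal length")
        if volume is not None:
            volume = _as_1d(volume, "volume")
            if volume.shape != time.shape:
                raise InputError("volume and time must have equal length")

        native_rate = (time.size - 1) / (time[-1] - time[0])
        needs_resample = not _is_uniform(time)
        if resample_rate is not None and abs(resample_rate - native_rate) > (
            _UNIFORMITY_RTOL * native_rate
        ):
            needs_resample = True
        if needs_resample:
            rate = resample_rate if resample_rate is not None else native_rate
            n = max(_MIN_SAMPLES, int(math.floor((time[-1] - time[0]) * rate)) + 1)
            new_time = time[0] + np.arange(n) / rate
            if flow is not None:
                flow = np.interp(new_time, time, flow)
            if volume is not None:
                volume = np.interp(new_time, time, volume)
            time = new_time
            sample_rate = rate
        else:
            sample_rate = native_rate

        if volume is None:
            volume = integrate_flow(flow, time)
        if flow is None:
            flow = differentiate(volume, time, order=1)
        return cls(
            time=time,
            flow=flow,
            volume=volume,
            sample_rate=float(sample_rate),
            meta=dict(meta or {}),
        )

    # -- convenience --------------------------------------------------------

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def copy(self) -> "Maneuver":
        return Maneuver(
            time=self.time.copy(),
            flow=self.flow.copy(),
            volume=self.volume.copy(),
            sample_rate=self.sample_rate,
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class SpiroIndices:
    """Classical spirometric indices of one maneuver.

    Times (``peft``, ``tex``, ``fet100``) are measured from ``t_zero``.
    Indices that cannot be computed are NaN with the reason recorded in
    ``na_reasons``.
    """

    fvc: float
    fev1: float
    pef: float
    peft: float
    t_zero: float
    bev: float
    eotv: float
    tex: float
    fet100: float
    na_reasons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "FVC": self.fvc,
            "FEV1": self.fev1,
            "PEF": self.pef,
            "PEFT": self.peft,
            "T_zero": self.t_zero,
            "BEV": self.bev,
            "EOTV": self.eotv,
            "Tex": self.tex,
            "FET100": self.fet100,
        }


def compute_t_zero(maneuver: Maneuver, smoothing_window: float = 0.05) -> float:
    """Back-extrapolated time origin of the maneuver.

    The VT curve is smoothed, its slope estimated by central differences, and
    the tangent at the point of maximum slope extended to zero volume; the
    crossing time is returned (it may precede the first sample).
    """
    if np.max(maneuver.flow) <= 0:
        raise DegenerateCurveError("maneuver has no positive flow")
    v = smooth(maneuver.volume, smoothing_window, maneuver.sample_rate)
    dv = np.gradient(v, maneuver.time)
    k = int(np.argmax(dv))
    slope = dv[k]
    if slope <= 0:
        raise DegenerateCurveError("volume-time curve has no rising segment")
    return float(maneuver.time[k] - v[k] / slope)


def _interp_volume(maneuver: Maneuver, t: float) -> float:
    return float(np.interp(t, maneuver.time, maneuver.volume))


def compute_indices(
    maneuver: Maneuver, cfg: ThresholdConfig = DEFAULT_CONFIG
) -> SpiroIndices:
    """Compute all classical indices of a maneuver.

    FVC is the maximum expired volume; PEF the maximum sampled flow (earliest
    sample on ties); BEV the linearly interpolated volume at ``t = T_zero``;
    FEV1 the volume expired between ``T_zero`` and ``T_zero + 1 s``; EOTV the
    volume span of the final ``cfg.eotv_window`` seconds; Tex runs from
    ``T_zero`` to the first post-peak instant whose trailing per-window volume
    change falls below ``cfg.eotv_threshold`` (or the end of exhalation);
    FET100 runs from ``T_zero`` to the first attainment of FVC.
    """
    time, volume, flow = maneuver.time, maneuver.volume, maneuver.flow
    t_zero = compute_t_zero(maneuver, cfg.smoothing_window)
    na: dict[str, str] = {}

    i_fvc = int(np.argmax(volume))
    fvc = float(volume[i_fvc])
    fet100 = float(time[i_fvc] - t_zero)

    i_pef = int(np.argmax(flow))
    pef = float(flow[i_pef])
    peft = float(time[i_pef] - t_zero)

    bev = max(0.0, _interp_volume(maneuver, t_zero))

    t_end = float(time[-1])
    if t_end - t_zero < 1.0:
        fev1 = math.nan
        na["FEV1"] = "record ends before T_zero + 1 s"
        eotv = math.nan
        na["EOTV"] = "record shorter than 1 s after T_zero"
    else:
        fev1 = _interp_volume(maneuver, t_zero + 1.0) - _interp_volume(
            maneuver, t_zero
        )
        tail = volume[time >= t_end - cfg.eotv_window]
        eotv = float(tail.max() - tail.min())

    # Tex: trailing-anchored sliding window, searched from the peak onwards so
    # that a quiet pre-blast segment cannot masquerade as the plateau.
    tex = t_end - t_zero
    eligible = np.flatnonzero(
        (time >= time[0] + cfg.eotv_window) & (time >= time[i_pef])
    )
    for i in eligible:
        delta = volume[i] - _interp_volume(maneuver, float(time[i]) - cfg.eotv_window)
        if delta < cfg.eotv_threshold:
            tex = float(time[i] - t_zero)
            break

    return SpiroIndices(
        fvc=fvc,
        fev1=fev1,
        pef=pef,
        peft=peft,
        t_zero=t_zero,
        bev=bev,
        eotv=eotv,
        tex=tex,
        fet100=fet100,
        na_reasons=na,
    )
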