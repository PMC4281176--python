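"""Synthetic forced-expiration maneuvers with injectable, labeled defects.

The clean waveform is the simplest shape that satisfies the whole
acceptability battery: a quarter-sine rise to peak flow followed by an
exponential decay whose time constant is solved numerically so that the total
expired volume equals the requested FVC exactly at the requested duration.
It plays the role of the simulated standard curves used to commission
quality-control algorithms; optional additive white noise emulates sensor
noise but defaults to zero (see docs/methods.md).

Nine defect transforms reproduce the canonical failure morphologies: hesitant
(delayed) start, cough, bimodal peak, flat peak, slow peak, early
termination, end-of-test oscillation and irregular ascent/descent.  Severity
0 is the identity; severity 1 decisively violates the corresponding
published threshold (0.15 L back-extrapolation, 0.025 L plateau, 6 s
expiratory time) or its calibrated morphological analogue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.signal import butter, sosfiltfilt

from .errors import InputError, ParameterError
from .signal_core import Maneuver, integrate_flow

__all__ = [
    "CleanParams",
    "DefectSpec",
    "DEFECT_KINDS",
    "DESIGNATED_CRITERION",
    "DatasetEntry",
    "generate_clean",
    "inject_defect",
    "generate_labeled_dataset",
]

DEFECT_KINDS = (
    "delayed_start",
    "cough",
    "bimodal_peak",
    "flat_peak",
    "slow_peak",
    "early_termination",
    "end_oscillation",
    "irregular_ascent",
    "irregular_descent",
)

#: The criterion each defect is designed to trip.
DESIGNATED_CRITERION = {
    "delayed_start": "C8",
    "cough": "C12a",
    "bimodal_peak": "C5c",
    "flat_peak": "C5a",
    "slow_peak": "C3",
    "early_termination": "FET",
    "end_oscillation": "C11",
    "irregular_ascent": "C2a",
    "irregular_descent": "C7b",
}


@dataclass(frozen=True)
class CleanParams:
    """Parameters of one clean maneuver.

    ``tau`` is normally left ``None`` and solved so the expired volume reaches
    ``fvc`` at ``duration``; an explicit value overrides the solve (the
    realized FVC then follows from it).
    """

    fvc: float = 4.0          # L
    pef: float = 8.0          # L/s
    rise_time: float = 0.1    # s, time from onset to peak flow
    tau: float | None = None  # s, descent decay constant
    duration: float = 8.0     # s, exhalation duration
    sample_rate: float = 100.0  # Hz
    noise_sd: float = 0.0     # L/s, additive white sensor noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fvc", "pef", "rise_time", "duration", "sample_rate"):
            if not (getattr(self, name) > 0):
                raise ParameterError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.tau is not None and not (self.tau > 0):
            raise ParameterError("tau must be positive when given")


@dataclass(frozen=True)
class DefectSpec:
    """One defect to inject: kind, severity in [0, 1], optional location (s)."""

    kind: str
    severity: float = 1.0
    location: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DEFECT_KINDS:
            raise InputError(
                f"unknown defect kind {self.kind!r}; expected one of {DEFECT_KINDS}"
            )
        if not (0.0 <= self.severity <= 1.0):
            raise InputError("severity must lie in [0, 1]")


def _solve_tau(fvc: float, pef: float, rise_time: float, duration: float) -> float:
    """Decay constant giving expired volume ``fvc`` at ``duration``."""
    v_rise = pef * 2.0 * rise_time / math.pi
    v_descent = fvc - v_rise
    span = duration - rise_time
    if span <= 0:
        raise ParameterError("duration must exceed rise_time")
    if v_descent <= 0:
        raise ParameterError(
            f"FVC {fvc} L is not reachable: the rise alone expires {v_rise:.3f} L"
        )
    if v_descent >= pef * span:
        raise ParameterError(
            f"FVC {fvc} L cannot be expired within {duration} s at PEF {pef} L/s"
        )

    def gap(tau: float) -> float:
        return pef * tau * (1.0 - math.exp(-span / tau)) - v_descent

    lo, hi = 1e-6, 1e6
    tau = brentq(gap, lo, hi, xtol=1e-10, rtol=1e-12)
    if abs(gap(tau)) > 1e-4:
        raise ParameterError("decay-constant solve did not converge to 1e-4 L")
    return float(tau)


def generate_clean(params: CleanParams) -> Maneuver:
    """Deterministic clean maneuver for the given parameters."""
    dt = 1.0 / params.sample_rate
    n = int(round(params.duration * params.sample_rate)) + 1
    t = np.arange(n) * dt
    tau = (
        params.tau
        if params.tau is not None
        else _solve_tau(params.fvc, params.pef, params.rise_time, params.duration)
    )
    flow = np.where(
        t <= params.rise_time,
        params.pef * np.sin(0.5 * math.pi * t / params.rise_time),
        params.pef * np.exp(-(t - params.rise_time) / tau),
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        flow = flow + params.noise_sd * rng.standard_normal(n)
    volume = integrate_flow(flow, t)
    meta = {
        "source": "synthetic-clean",
        "fvc": params.fvc,
        "pef": params.pef,
        "rise_time": params.rise_time,
        "tau": tau,
        "duration": params.duration,
        "noise_sd": params.noise_sd,
        "seed": params.seed,
    }
    return Maneuver(
        time=t, flow=flow, volume=volume, sample_rate=params.sample_rate, meta=meta
    )


# ---------------------------------------------------------------------------
# Defect transforms
# ---------------------------------------------------------------------------

def _rebuild(man: Maneuver, time, flow, extra_meta) -> Maneuver:
    volume = integrate_flow(flow, time)
    meta = dict(man.meta)
    meta.update(extra_meta)
    return Maneuver(
        time=np.asarray(time, float),
        flow=np.asarray(flow, float),
        volume=volume,
        sample_rate=man.sample_rate,
        meta=meta,
    )


def _peak_index(flow: np.ndarray) -> int:
    return int(np.argmax(flow))


def _delayed_start(man, severity, location, rng):
    # Prepend a slow half-sine leak expiring severity * 0.5 L before the blast.
    leak_volume = 0.5 * severity
    t_leak = 1.5 if location is None else max(0.2, location)
    dt = 1.0 / man.sample_rate
    n_leak = int(round(t_leak * man.sample_rate))
    tl = np.arange(n_leak) * dt
    leak = (leak_volume * math.pi / (2.0 * t_leak)) * np.sin(math.pi * tl / t_leak)
    flow = np.concatenate([leak, man.flow])
    time = np.arange(flow.size) * dt
    return time, flow


def _cough(man, severity, location, rng):
    # Multiplicative transient valley: flow is scotched by a narrow Gaussian,
    # producing the characteristic valley-then-rebound in the FV curve.
    f = man.flow
    p = _peak_index(f)
    if location is None:
        after = np.flatnonzero(f[p:] <= 0.5 * f[p])
        loc = man.time[p + after[0]] if after.size else man.time[(p + man.n - 1) // 2]
    else:
        loc = location
    g = np.exp(-0.5 * ((man.time - loc) / 0.05) ** 2)
    flow = f * (1.0 - severity * g)
    flow = np.maximum(flow, -0.2 * f[p])
    return man.time.copy(), flow


def _flat_peak(man, severity, location, rng):
    # Clip the top of the curve and insert a plateau so the near-peak band
    # widens with severity; the tail is truncated to preserve the duration.
    f = man.flow.copy()
    p = _peak_index(f)
    level = (1.0 - 0.1 * severity) * f[p]
    f = np.minimum(f, level)
    above = np.flatnonzero(f >= level)
    natural = (above[-1] - above[0]) / man.sample_rate if above.size else 0.0
    extra = max(0.0, 0.5 * severity - natural)
    n_extra = int(round(extra * man.sample_rate))
    if n_extra > 0:
        insert_at = above[0] + 1 if above.size else p
        f = np.concatenate([f[:insert_at], np.full(n_extra, level), f[insert_at:]])
        f = f[: man.n]
    dt = 1.0 / man.sample_rate
    time = np.arange(f.size) * dt
    return time, f


def _bimodal_peak(man, severity, location, rng):
    # Widen the peak into a plateau just below PEF, then carve a Gaussian
    # notch at its centre: twin maxima straddle a valley whose depth grows
    # with severity while staying inside the near-peak band, so the curve is
    # genuinely bimodal at every decay constant.
    f = man.flow.copy()
    n = man.n
    p = _peak_index(f)
    level = 0.97 * f[p]
    f = np.minimum(f, level)
    above = np.flatnonzero(f >= level)
    natural = (above[-1] - above[0]) / man.sample_rate if above.size else 0.0
    width = 0.15 + 0.25 * severity
    n_extra = int(round(max(0.0, width - natural) * man.sample_rate))
    if n_extra > 0:
        insert_at = above[0] + 1 if above.size else p
        f = np.concatenate([f[:insert_at], np.full(n_extra, level), f[insert_at:]])
        f = f[:n]
    t = np.arange(f.size) / man.sample_rate
    centre = (t[above[0]] + width / 2.0) if location is None else location
    notch = severity * 0.15 * np.exp(-0.5 * ((t - centre) / 0.06) ** 2)
    return t, f * (1.0 - notch)


def _slow_peak(man, severity, location, rng):
    # Time-dilate the rise by (1 + 4 * severity); the descent shifts right and
    # the record is truncated at its original duration.
    k = 1.0 + 4.0 * severity
    p = _peak_index(man.flow)
    t_p = man.time[p]
    t = man.time
    warped = np.where(t <= k * t_p, t / k, t - (k - 1.0) * t_p)
    flow = np.interp(warped, man.time, man.flow)
    return t.copy(), flow


def _early_termination(man, severity, location, rng):
    keep = max(10, int(round(man.n * (1.0 - 0.6 * severity))))
    return man.time[:keep].copy(), man.flow[:keep].copy()


def _end_oscillation(man, severity, location, rng):
    flow = man.flow.copy()
    mask = man.time >= man.time[-1] - 1.0
    t_rel = man.time[mask] - man.time[mask][0]
    flow[mask] = flow[mask] + severity * 0.1 * np.sin(2.0 * math.pi * 4.0 * t_rel)
    flow = np.maximum(flow, -0.2 * np.max(man.flow))
    return man.time.copy(), flow


def _band_limited_noise(n, sample_rate, rng):
    white = rng.standard_normal(n)
    nyq = sample_rate / 2.0
    sos = butter(3, [8.0 / nyq, 12.0 / nyq], btype="bandpass", output="sos")
    return sosfiltfilt(sos, white)


def _tukey_mask(n, lo, hi, edge):
    """Unit window over [lo, hi) with raised-cosine edges of ``edge`` samples."""
    w = np.zeros(n)
    w[lo:hi] = 1.0
    edge = min(edge, max(1, (hi - lo) // 4))
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(edge) / edge))
    w[lo : lo + edge] = ramp
    w[hi - edge : hi] = ramp[::-1]
    return w


def _irregular(man, severity, region, rng):
    f = man.flow.copy()
    pef = float(np.max(f))
    p = _peak_index(f)
    if region == "ascent":
        above = np.flatnonzero(f[: p + 1] >= 0.02 * pef)
        lo = int(above[0]) if above.size else 0
        # stop below the peak so the ripple cannot displace the PEF sample
        near_peak = np.flatnonzero(f[: p + 1] >= 0.9 * pef)
        hi = int(near_peak[0]) + 1 if near_peak.size else p + 1
    else:
        below = np.flatnonzero(f[p:] <= 0.8 * pef)
        lo = p + (int(below[0]) if below.size else 1)
        tail = np.flatnonzero(f[lo:] >= 0.05 * pef)
        hi = lo + (int(tail[-1]) + 1 if tail.size else man.n - lo)
    hi = min(hi, man.n)
    if hi - lo < 4:
        return man.time.copy(), f
    noise = _band_limited_noise(man.n, man.sample_rate, rng)
    sd = float(np.std(noise[lo:hi])) or 1.0
    noise = noise / sd * (severity * 0.05 * pef)
    f = f + noise * _tukey_mask(man.n, lo, hi, int(0.05 * man.sample_rate))
    f = np.maximum(f, -0.2 * pef)
    return man.time.copy(), f


_TRANSFORMS = {
    "delayed_start": _delayed_start,
    "cough": _cough,
    "bimodal_peak": _bimodal_peak,
    "flat_peak": _flat_peak,
    "slow_peak": _slow_peak,
    "early_termination": _early_termination,
    "end_oscillation": _end_oscillation,
    "irregular_ascent": lambda m, s, loc, rng: _irregular(m, s, "ascent", rng),
    "irregular_descent": lambda m, s, loc, rng: _irregular(m, s, "descent", rng),
}


def inject_defect(maneuver: Maneuver, spec: DefectSpec) -> Maneuver:
    """Apply one defect transform; severity 0 returns an identical copy."""
    if spec.severity == 0.0:
        return maneuver.copy()
    rng = np.random.default_rng(spec.seed)
    time, flow = _TRANSFORMS[spec.kind](maneuver, spec.severity, spec.location, rng)
    return _rebuild(
        maneuver,
        time,
        flow,
        {"defect": spec.kind, "severity": spec.severity, "defect_seed": spec.seed},
    )


# ---------------------------------------------------------------------------
# Labeled datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetEntry:
    maneuver: Maneuver
    label: int               # expert label: 1 acceptable, 0 reject
    defect_kind: str | None  # None for clean curves
    severity: float
    seed: int


def _draw_clean_params(rng: np.random.Generator, seed: int) -> CleanParams:
    """One clean parameter draw from the documented physiological ranges.

    PEF is drawn conditionally on FVC (PEF/FVC between 1.5 and 2.5 /s,
    clipped to 4-12 L/s): peak flow scales with vital capacity, and the
    conditional draw keeps the implied decay constant short enough that a
    healthy curve genuinely plateaus within its exhalation.
    """
    fvc = rng.uniform(2.0, 6.0)
    pef = float(np.clip(fvc * rng.uniform(1.5, 2.5), 4.0, 12.0))
    return CleanParams(
        fvc=fvc,
        pef=pef,
        rise_time=rng.uniform(0.08, 0.15),
        duration=rng.uniform(7.0, 10.0),
        seed=seed,
    )


def generate_labeled_dataset(
    n_clean: int, n_per_defect: int, master_seed: int = 0
) -> list[DatasetEntry]:
    """Clean curves labeled 1 plus high-severity defect curves labeled 0.

    Fully reproducible from ``master_seed``; defect severities are drawn from
    [0.8, 1.0] so every defect decisively violates its designated criterion.
    """
    if n_clean < 0 or n_per_defect < 0:
        raise InputError("counts must be >= 0")
    rng = np.random.default_rng(master_seed)
    entries: list[DatasetEntry] = []
    for _ in range(n_clean):
        seed = int(rng.integers(0, 2**31 - 1))
        params = _draw_clean_params(rng, seed)
        entries.append(
            DatasetEntry(
                maneuver=generate_clean(params),
                label=1,
                defect_kind=None,
                severity=0.0,
                seed=seed,
            )
        )
    for kind in DEFECT_KINDS:
        for _ in range(n_per_defect):
            seed = int(rng.integers(0, 2**31 - 1))
            params = _draw_clean_params(rng, seed)
            severity = float(rng.uniform(0.8, 1.0))
            clean = generate_clean(params)
            defective = inject_defect(
                clean, DefectSpec(kind=kind, severity=severity, seed=seed)
            )
            entries.append(
                DatasetEntry(
                    maneuver=defective,
                    label=0,
                    defect_kind=kind,
                    severity=severity,
                    seed=seed,
                )
            )
    return entries
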