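"""The quality-criterion battery evaluated per zone.

Each criterion compares one or more shape metrics against configured
thresholds and yields pass / fail / not_applicable.  The traditional ATS/ERS
criteria (C8 back-extrapolated volume, C9 end-of-test plateau, FET expiratory
time, REP session repeatability) implement the published rules verbatim.  The
morphology criteria C1-C7 and C10-C12 are derivative-statistic formulations of
the zone irregularities they target (irregular ascent, flat or bimodal or slow
peak, irregular descent, end-of-test oscillation, mid-curve cough); their
precise metric definitions are this package's own and are documented in
docs/methods.md together with the calibration of their default thresholds.

Boundary conventions follow the printed rules literally: "less than" is
strict, "reaches" is inclusive, so e.g. FET100 exactly equal to the 6 s
minimum passes and an end-of-test volume exactly equal to 0.025 L fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.signal import find_peaks

from .config import DEFAULT_CONFIG, ThresholdConfig
from .errors import InputError
from .signal_core import Maneuver, SpiroIndices, smooth
from .zoning import ZoneInterval, ZoneSegmentation

__all__ = [
    "CriterionResult",
    "ALL_CRITERION_IDS",
    "MANEUVER_CRITERION_IDS",
    "evaluate_z1",
    "evaluate_z2",
    "evaluate_z3",
    "evaluate_z4",
    "evaluate_z5",
    "evaluate_fet",
    "evaluate_repeatability",
    "evaluate_all",
]

#: Criteria evaluated per maneuver, in report order.
MANEUVER_CRITERION_IDS = (
    "C1", "C2a", "C2b",
    "C3", "C4", "C5a", "C5b", "C5c", "C6",
    "C7a", "C7b", "C7c", "C7d",
    "C8", "C9", "C10a", "C10b", "C10c", "C10d", "C10e", "C11",
    "C12a", "C12b",
    "FET",
)

ALL_CRITERION_IDS = MANEUVER_CRITERION_IDS + ("REP",)

_MIN_ZONE_SAMPLES = 5


@dataclass(frozen=True)
class CriterionResult:
    criterion_id: str
    metrics: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    outcome: str = "pass"  # pass | fail | not_applicable
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in ("pass", "fail", "not_applicable"):
            raise InputError(f"invalid outcome {self.outcome!r}")
        if self.outcome == "fail" and not (self.metrics and self.thresholds):
            raise InputError("a failing criterion must record metrics and thresholds")

    @property
    def failed(self) -> bool:
        return self.outcome == "fail"


def _result(cid, metrics, thresholds, failed) -> CriterionResult:
    return CriterionResult(
        criterion_id=cid,
        metrics=metrics,
        thresholds=thresholds,
        outcome="fail" if failed else "pass",
    )


def _na(cid: str, reason: str) -> CriterionResult:
    return CriterionResult(criterion_id=cid, outcome="not_applicable", reason=reason)


# ---------------------------------------------------------------------------
# FV-plane derivative statistics
# ---------------------------------------------------------------------------

def _fv_slope_stats(maneuver, zone: ZoneInterval, indices, cfg, floor_frac):
    """Normalized FV-plane slope and curvature over a zone.

    Flow is smoothed, the zone is restricted to samples with flow above
    ``floor_frac * PEF`` (the FV slope dF/dV = (dF/dt)/F diverges at low
    flow), and the slope and curvature are scaled by FVC/PEF and FVC^2/PEF so
    they are dimensionless and comparable across subjects.
    Returns (v_hat, d1, d2) or None when fewer than 5 samples survive.
    """
    f = smooth(maneuver.flow, cfg.smoothing_window, maneuver.sample_rate)
    sl = zone.slice()
    idx = np.arange(zone.start, zone.end)
    mask = f[sl] >= floor_frac * indices.pef
    idx = idx[mask]
    if idx.size < _MIN_ZONE_SAMPLES:
        return None
    t = maneuver.time[idx]
    fz = f[idx]
    v_hat = maneuver.volume[idx] / indices.fvc
    dfdt = np.gradient(fz, t)
    d1 = (dfdt / fz) * (indices.fvc / indices.pef)
    d2 = (np.gradient(d1, t) / fz) * indices.fvc
    return v_hat, d1, d2


def _rise_shape_stats(maneuver, zone: ZoneInterval, indices, cfg):
    """Normalized rise-shape derivatives over Z1.

    In Z1 the FV slope dF/dV = (dF/dt)/F diverges at onset, so the ascent is
    analysed against normalized time instead: flow scaled by PEF, time scaled
    by the rise duration.  The clean ascent is then a smooth quarter-sine with
    first and second derivatives of order one, and any superimposed ripple
    shows up at full strength.  Returns (x, d1, d2) or None.
    """
    if zone.size < _MIN_ZONE_SAMPLES:
        return None
    f = smooth(maneuver.flow, cfg.z1_smoothing_window, maneuver.sample_rate)
    sl = zone.slice()
    t = maneuver.time[sl]
    span = t[-1] - t[0]
    if span <= 0:
        return None
    x = (t - t[0]) / span
    y = f[sl] / indices.pef
    d1 = np.gradient(y, x)
    d2 = np.gradient(d1, x)
    return x, d1, d2


def _detrended(values: np.ndarray, x: np.ndarray, deg: int = 2) -> np.ndarray:
    deg = min(deg, values.size - 1)
    coeffs = np.polyfit(x, values, deg)
    return values - np.polyval(coeffs, x)


def _sign_changes_above_floor(values: np.ndarray, floor: float) -> int:
    """Sign alternations of ``values`` counted only between excursions whose
    magnitude exceeds ``floor``."""
    big = values[np.abs(values) >= floor]
    if big.size < 2:
        return 0
    signs = np.sign(big)
    return int(np.count_nonzero(np.diff(signs) != 0))


# ---------------------------------------------------------------------------
# Z1: rise to peak flow
# ---------------------------------------------------------------------------

def evaluate_z1(
    maneuver: Maneuver,
    seg: ZoneSegmentation,
    indices: SpiroIndices,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> list[CriterionResult]:
    """C1 irregular concavity/convexity, C2a irregular slope, C2b curvature
    excursion, all on the ascending limb of the FV curve."""
    stats = _rise_shape_stats(maneuver, seg.z1, indices, cfg)
    if stats is None:
        reason = f"zone Z1 has {seg.z1.size} samples (< {_MIN_ZONE_SAMPLES})"
        return [_na(c, reason) for c in ("C1", "C2a", "C2b")]
    x, d1, d2 = stats

    d2_resid = _detrended(d2, x)
    n_flips = _sign_changes_above_floor(d2_resid, cfg.c1_amp_floor)
    c1 = _result(
        "C1",
        {"curvature_sign_changes": float(n_flips)},
        {"c1_signflip_max": float(cfg.c1_signflip_max)},
        n_flips > cfg.c1_signflip_max,
    )

    # Cubic detrending: the clean quarter-sine ascent is captured almost
    # exactly by a cubic, so the residual isolates superimposed irregularity.
    d1_resid = _detrended(d1, x, deg=3)
    resid_rms = float(np.sqrt(np.mean(d1_resid ** 2)))
    c2a = _result(
        "C2a",
        {"slope_residual_rms": resid_rms},
        {"c2a_resid_max": cfg.c2a_resid_max},
        resid_rms > cfg.c2a_resid_max,
    )

    excursion = float(np.max(np.abs(d2_resid)))
    c2b = _result(
        "C2b",
        {"curvature_excursion": excursion},
        {"c2b_excursion_max": cfg.c2b_excursion_max},
        excursion > cfg.c2b_excursion_max,
    )
    return [c1, c2a, c2b]


# ---------------------------------------------------------------------------
# Z2: the peak region
# ---------------------------------------------------------------------------

def _near_peak_band(maneuver, indices, cfg) -> ZoneInterval:
    """Contiguous samples around the PEF sample with flow >=
    ``flat_peak_ratio * PEF``."""
    f = smooth(maneuver.flow, cfg.smoothing_window, maneuver.sample_rate)
    level = cfg.flat_peak_ratio * indices.pef
    p = int(np.argmax(maneuver.flow))
    lo = p
    while lo > 0 and f[lo - 1] >= level:
        lo -= 1
    hi = p
    while hi < maneuver.n - 1 and f[hi + 1] >= level:
        hi += 1
    return ZoneInterval(lo, hi + 1)


def evaluate_z2(
    maneuver: Maneuver,
    seg: ZoneSegmentation,
    indices: SpiroIndices,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> list[CriterionResult]:
    """C3 late peak, C4 premature peak, C5a/C5b flat peak, C5c bimodal peak,
    C6 slow peak (low PEF relative to FVC)."""
    results = [
        _result(
            "C3", {"PEFT": indices.peft}, {"peft_max": cfg.peft_max},
            indices.peft > cfg.peft_max,
        ),
        _result(
            "C4", {"PEFT": indices.peft}, {"peft_min": cfg.peft_min},
            indices.peft < cfg.peft_min,
        ),
    ]

    band = _near_peak_band(maneuver, indices, cfg)
    dt = 1.0 / maneuver.sample_rate
    width_s = max(0.0, band.size - 1) * dt
    vol_span = float(
        maneuver.volume[band.end - 1] - maneuver.volume[band.start]
    )
    volfrac = vol_span / indices.fvc
    results.append(
        _result(
            "C5a",
            {"flat_band_width": width_s, "flat_peak_ratio": cfg.flat_peak_ratio},
            {"flat_peak_width_max": cfg.flat_peak_width_max},
            width_s > cfg.flat_peak_width_max,
        )
    )
    results.append(
        _result(
            "C5b",
            {"flat_band_volume_fraction": volfrac},
            {"flat_peak_volfrac_max": cfg.flat_peak_volfrac_max},
            volfrac > cfg.flat_peak_volfrac_max,
        )
    )

    f = smooth(maneuver.flow, cfg.smoothing_window, maneuver.sample_rate)
    fz2 = f[seg.z2.slice()]
    peaks, props = find_peaks(fz2, prominence=cfg.bimodal_prominence * indices.pef)
    proms = np.sort(props["prominences"])[::-1] if peaks.size else np.array([])
    second_prom = float(proms[1] / indices.pef) if proms.size >= 2 else 0.0
    results.append(
        _result(
            "C5c",
            {"n_peaks_in_z2": float(peaks.size), "second_prominence": second_prom},
            {"bimodal_prominence": cfg.bimodal_prominence},
            peaks.size >= 2,
        )
    )

    ratio = indices.pef / indices.fvc
    results.append(
        _result(
            "C6", {"pef_over_fvc": ratio}, {"c6_threshold": cfg.c6_threshold},
            ratio < cfg.c6_threshold,
        )
    )
    return results


# ---------------------------------------------------------------------------
# Z3: descent from the peak
# ---------------------------------------------------------------------------

def evaluate_z3(
    maneuver: Maneuver,
    seg: ZoneSegmentation,
    indices: SpiroIndices,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> list[CriterionResult]:
    """C7a steep descent slopes, C7b global and C7c per-volume-segment slope
    variance, C7d sign-alternating slope weighted by deviation from the chord.

    For a smooth forced expiration the descending limb of the FV curve is
    close to a straight line, so its normalized slope is nearly constant and
    its chord deviation nearly zero; every C7 metric measures departure from
    that baseline.
    """
    ids = ("C7a", "C7b", "C7c", "C7d")
    if seg.z3.size < _MIN_ZONE_SAMPLES:
        reason = f"zone Z3 has {seg.z3.size} samples (< {_MIN_ZONE_SAMPLES})"
        return [_na(c, reason) for c in ids]
    stats = _fv_slope_stats(maneuver, seg.z3, indices, cfg, cfg.c7_flow_floor)
    if stats is None:
        reason = "zone Z3 too short above the flow floor"
        return [_na(c, reason) for c in ids]
    v_hat, d1, _ = stats

    max_slope = float(np.max(np.abs(d1)))
    slope_var = float(np.var(d1))

    width_hat = cfg.c7_segment_width / indices.fvc
    seg_var = 0.0
    for i in range(v_hat.size):
        j = int(np.searchsorted(v_hat, v_hat[i] + width_hat, side="right"))
        if j - i >= _MIN_ZONE_SAMPLES:
            seg_var = max(seg_var, float(np.var(d1[i:j])))
    if v_hat[-1] - v_hat[0] < width_hat:
        seg_var = slope_var  # zone narrower than one segment

    # Chord in the normalized FV plane from the first to the last zone sample.
    f = smooth(maneuver.flow, cfg.smoothing_window, maneuver.sample_rate)
    sl = seg.z3.slice()
    fz = f[sl] / indices.pef
    vz = maneuver.volume[sl] / indices.fvc
    chord = np.interp(vz, [vz[0], vz[-1]], [fz[0], fz[-1]])
    chord_dev = float(np.trapezoid(np.abs(fz - chord), vz))
    n_flips = int(np.count_nonzero(np.diff(np.sign(d1)) != 0))
    flip_metric = n_flips * chord_dev

    return [
        _result(
            "C7a", {"max_abs_slope": max_slope},
            {"c7_slope_max": cfg.c7_slope_max}, max_slope > cfg.c7_slope_max,
        ),
        _result(
            "C7b", {"slope_variance": slope_var},
            {"c7_slope_var_max": cfg.c7_slope_var_max},
            slope_var > cfg.c7_slope_var_max,
        ),
        _result(
            "C7c", {"segment_slope_variance": seg_var},
            {"c7_segment_var_max": cfg.c7_segment_var_max},
            seg_var > cfg.c7_segment_var_max,
        ),
        _result(
            "C7d",
            {
                "sign_changes": float(n_flips),
                "chord_deviation": chord_dev,
                "weighted_flips": flip_metric,
            },
            {"c7_signflip_max": cfg.c7_signflip_max},
            flip_metric > cfg.c7_signflip_max,
        ),
    ]


# ---------------------------------------------------------------------------
# Z4: end of test
# ---------------------------------------------------------------------------

def _volume_span(maneuver: Maneuver, window: float) -> float:
    tail = maneuver.volume[maneuver.time >= maneuver.time[-1] - window]
    return float(tail.max() - tail.min())


def evaluate_z4(
    maneuver: Maneuver,
    seg: ZoneSegmentation,
    indices: SpiroIndices,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> list[CriterionResult]:
    """C8 back-extrapolated volume, C9 end-of-test plateau, the C10 family of
    Tex-conditioned plateau variants, and C11 end-of-test flow oscillation."""
    results: list[CriterionResult] = []

    bev_limit = max(cfg.bev_abs, cfg.bev_frac * indices.fvc)
    results.append(
        _result(
            "C8",
            {"BEV": indices.bev, "FVC": indices.fvc},
            {"bev_abs": cfg.bev_abs, "bev_frac": cfg.bev_frac, "bev_limit": bev_limit},
            indices.bev > bev_limit,
        )
    )

    eotv_na = math.isnan(indices.eotv)
    if eotv_na:
        reason = indices.na_reasons.get("EOTV", "EOTV not computable")
        results.append(_na("C9", reason))
        results.extend(_na(c, reason) for c in ("C10a", "C10b", "C10c", "C10d", "C10e"))
    else:
        eotv, tex = indices.eotv, indices.tex
        eotv_fail = eotv >= cfg.eotv_threshold
        results.append(
            _result(
                "C9", {"EOTV": eotv}, {"eotv_threshold": cfg.eotv_threshold},
                eotv_fail,
            )
        )
        results.append(
            _result(
                "C10a",
                {"EOTV": eotv, "Tex": tex},
                {"eotv_threshold": cfg.eotv_threshold, "fet_min": cfg.fet_min},
                eotv_fail and tex < cfg.fet_min,
            )
        )
        if tex >= cfg.fet_min:
            eotv2 = _volume_span(maneuver, cfg.c10_window2)
            results.append(
                _result(
                    "C10b",
                    {"EOTV_window2": eotv2, "Tex": tex},
                    {"eotv_threshold": cfg.eotv_threshold,
                     "c10_window2": cfg.c10_window2},
                    eotv2 >= cfg.eotv_threshold,
                )
            )
            results.append(
                _result(
                    "C10c",
                    {"EOTV": eotv, "Tex": tex},
                    {"c10_threshold2": cfg.c10_threshold2},
                    eotv >= cfg.c10_threshold2,
                )
            )
        else:
            reason = f"Tex = {tex:.2f} s below fet_min; variant not applicable"
            results.append(_na("C10b", reason))
            results.append(_na("C10c", reason))
        thr_tex = cfg.eotv_threshold * (
            1.0 + cfg.c10_eotv_tex_slope * max(0.0, cfg.fet_min - tex)
        )
        results.append(
            _result(
                "C10d",
                {"EOTV": eotv, "thr_tex": thr_tex},
                {"eotv_threshold": cfg.eotv_threshold,
                 "c10_eotv_tex_slope": cfg.c10_eotv_tex_slope},
                eotv > thr_tex and eotv >= cfg.eotv_threshold,
            )
        )
        results.append(
            _result(
                "C10e",
                {"eotv_over_thr_tex": eotv / thr_tex},
                {"limit": 1.0},
                eotv / thr_tex > 1.0,
            )
        )

    # C11: flow oscillation over the end-of-test zone, counted as swings
    # between consecutive local extrema of the smoothed FT curve.
    f = smooth(maneuver.flow, cfg.smoothing_window, maneuver.sample_rate)
    fz4 = f[seg.z4.slice()]
    d = np.diff(fz4)
    sign = np.sign(d)
    sign[sign == 0] = 1
    turning = np.flatnonzero(np.diff(sign) != 0) + 1
    extrema = fz4[np.concatenate(([0], turning, [fz4.size - 1]))]
    swings = np.abs(np.diff(extrema))
    n_big = int(np.count_nonzero(swings >= cfg.c11_osc_amplitude))
    max_swing = float(swings.max()) if swings.size else 0.0
    results.append(
        _result(
            "C11",
            {"n_big_swings": float(n_big), "max_swing": max_swing},
            {"c11_osc_amplitude": cfg.c11_osc_amplitude,
             "c11_signflip_max": float(cfg.c11_signflip_max)},
            n_big >= cfg.c11_signflip_max,
        )
    )
    return results


# ---------------------------------------------------------------------------
# Z5: whole-curve shape
# ---------------------------------------------------------------------------

def evaluate_z5(
    maneuver: Maneuver,
    seg: ZoneSegmentation,
    indices: SpiroIndices,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> list[CriterionResult]:
    """C12a multiple prominent maxima anywhere (cough signature); C12b the
    same near the FEV1 point, where a transient corrupts FEV1 directly."""
    f = smooth(maneuver.flow, cfg.smoothing_window, maneuver.sample_rate)
    peaks, props = find_peaks(f, prominence=cfg.c12_prominence * indices.pef)
    proms = props["prominences"] if peaks.size else np.array([])
    order = np.argsort(proms)[::-1]
    second_prom = float(proms[order[1]] / indices.pef) if peaks.size >= 2 else 0.0
    c12a = _result(
        "C12a",
        {"n_prominent_peaks": float(peaks.size), "second_prominence": second_prom},
        {"c12_prominence": cfg.c12_prominence},
        peaks.size >= 2,
    )

    if math.isnan(indices.fev1):
        c12b = _na("C12b", indices.na_reasons.get("FEV1", "FEV1 not computable"))
    else:
        v_fev1 = float(
            np.interp(indices.t_zero + 1.0, maneuver.time, maneuver.volume)
        )
        global_peak = int(np.argmax(maneuver.flow))
        in_band = [
            p for p in peaks
            if abs(maneuver.volume[p] - v_fev1) <= cfg.c12_fev1_band
            and p != global_peak
        ]
        band_prom = 0.0
        if in_band:
            sel = np.isin(peaks, in_band)
            band_prom = float(np.max(proms[sel]) / indices.pef)
        c12b = _result(
            "C12b",
            {"n_secondary_peaks_near_fev1": float(len(in_band)),
             "max_prominence_near_fev1": band_prom},
            {"c12_prominence": cfg.c12_prominence,
             "c12_fev1_band": cfg.c12_fev1_band},
            len(in_band) >= 1,
        )
    return [c12a, c12b]


# ---------------------------------------------------------------------------
# Whole-maneuver and session criteria
# ---------------------------------------------------------------------------

def evaluate_fet(
    indices: SpiroIndices, cfg: ThresholdConfig = DEFAULT_CONFIG
) -> CriterionResult:
    """Forced expiratory time rule: FET100 >= fet_min passes (inclusive)."""
    return _result(
        "FET", {"FET100": indices.fet100}, {"fet_min": cfg.fet_min},
        indices.fet100 < cfg.fet_min,
    )


def evaluate_repeatability(
    session_indices: list[SpiroIndices],
    cfg: ThresholdConfig = DEFAULT_CONFIG,
    acceptable: list[bool] | None = None,
) -> CriterionResult:
    """Session repeatability: at least three acceptable maneuvers, of which
    some pair agrees on both FVC and FEV1 to within ``repeatability_delta``.

    ``acceptable`` flags maneuvers judged individually acceptable (grade 1);
    when omitted, every maneuver is considered.
    """
    if not session_indices:
        raise InputError("session must contain at least one maneuver")
    if acceptable is None:
        acceptable = [True] * len(session_indices)
    if len(acceptable) != len(session_indices):
        raise InputError("acceptable flags must match the number of maneuvers")

    usable = [
        ix
        for ix, ok in zip(session_indices, acceptable)
        if ok and not math.isnan(ix.fev1)
    ]
    n_ok = len(usable)
    if n_ok < 3:
        return CriterionResult(
            criterion_id="REP",
            metrics={"n_acceptable": float(n_ok)},
            thresholds={"min_acceptable": 3.0,
                        "repeatability_delta": cfg.repeatability_delta},
            outcome="fail",
            reason="insufficient maneuvers",
        )

    best = None
    for a, b in combinations(usable, 2):
        d_fvc = abs(a.fvc - b.fvc)
        d_fev1 = abs(a.fev1 - b.fev1)
        key = max(d_fvc, d_fev1)
        if best is None or key < best[0]:
            best = (key, d_fvc, d_fev1)
    _, d_fvc, d_fev1 = best
    ok = d_fvc < cfg.repeatability_delta and d_fev1 < cfg.repeatability_delta
    return _result(
        "REP",
        {"n_acceptable": float(n_ok),
         "best_pair_delta_fvc": d_fvc,
         "best_pair_delta_fev1": d_fev1},
        {"min_acceptable": 3.0, "repeatability_delta": cfg.repeatability_delta},
        not ok,
    )


def evaluate_all(
    maneuver: Maneuver,
    seg: ZoneSegmentation,
    indices: SpiroIndices,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
) -> list[CriterionResult]:
    """Every per-maneuver criterion, in canonical report order."""
    results = (
        evaluate_z1(maneuver, seg, indices, cfg)
        + evaluate_z2(maneuver, seg, indices, cfg)
        + evaluate_z3(maneuver, seg, indices, cfg)
        + evaluate_z4(maneuver, seg, indices, cfg)
        + evaluate_z5(maneuver, seg, indices, cfg)
        + [evaluate_fet(indices, cfg)]
    )
    assert tuple(r.criterion_id for r in results) == MANEUVER_CRITERION_IDS
    return results
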