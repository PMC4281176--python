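"""Threshold configuration for the quality-assessment battery.

Every tunable quantity of the criterion battery is a named scalar here so a
whole deployment can be tuned from one flat key/value file.  The traditional
ATS/ERS thresholds (0.15 L back-extrapolated volume, 5% of FVC, 0.025 L
end-of-test volume over 1 s, 6 s expiratory time, 0.15 L repeatability) carry
their standard published defaults.  The thresholds of the novel shape criteria
(C1-C7, C10-C12) are calibration artifacts: they were chosen once against the
clean synthetic-maneuver generator so that clean curves pass and each injected
defect decisively fails its designated criterion, and are documented in
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields

from .errors import InputError

#: Fields whose value must lie strictly inside (0, 1).
_FRACTION_FIELDS = {
    "bev_frac",
    "onset_fraction",
    "z2_fraction",
    "flat_peak_ratio",
    "bimodal_prominence",
    "c12_prominence",
    "c7_flow_floor",
}

#: Integer-valued count thresholds.
_COUNT_FIELDS = {"c1_signflip_max", "c11_signflip_max"}


@dataclass(frozen=True)
class ThresholdConfig:
    # --- ingest / preprocessing -------------------------------------------
    resample_rate: float = 100.0      # Hz, uniform grid used for analysis
    smoothing_window: float = 0.05    # s, local-quadratic smoothing window

    # --- zone segmentation -------------------------------------------------
    onset_fraction: float = 0.02      # of PEF; start of the rise zone Z1
    z2_fraction: float = 0.80         # of PEF; width of the peak zone Z2
    z4_window: float = 1.0            # s, end-of-test zone Z4 (>= 1 s used)

    # --- traditional ATS/ERS thresholds ------------------------------------
    bev_abs: float = 0.15             # L, back-extrapolated volume limit
    bev_frac: float = 0.05            # fraction of FVC, alternative BEV limit
    eotv_threshold: float = 0.025     # L, end-of-test plateau tolerance
    eotv_window: float = 1.0          # s, window for the EOTV computation
    fet_min: float = 6.0              # s, minimum expiratory time (adults)
    repeatability_delta: float = 0.15  # L, FVC/FEV1 session repeatability

    # --- Z1: rise to peak (C1, C2a, C2b) -----------------------------------
    z1_smoothing_window: float = 0.02  # s; lighter than the global window so
                                       # 8-12 Hz ripple on the short rise is
                                       # not averaged away before measurement
    c1_signflip_max: int = 2          # allowed curvature sign alternations
    c1_amp_floor: float = 1.0         # dimensionless curvature noise floor
    c2a_resid_max: float = 0.022      # dimensionless slope-residual RMS
    c2b_excursion_max: float = 2.0    # dimensionless curvature excursion

    # --- Z2: peak region (C3-C6) --------------------------------------------
    peft_max: float = 0.20            # s, latest acceptable time of PEF
    peft_min: float = 0.02            # s, earliest plausible time of PEF
    flat_peak_ratio: float = 0.90     # of PEF; defines the near-peak band
    flat_peak_width_max: float = 0.20  # s, C5a limit on the band duration
    flat_peak_volfrac_max: float = 0.45  # of FVC, C5b limit on band volume span
    bimodal_prominence: float = 0.03  # of PEF, C5c secondary-peak prominence
    c6_threshold: float = 1.0         # 1/s, minimum PEF/FVC ratio (slow peak)

    # --- Z3: descent (C7a-d) -------------------------------------------------
    c7_flow_floor: float = 0.10       # of PEF; excludes the noisy low-flow tail
    c7_slope_max: float = 3.0         # normalized |dF/dV|, C7a
    c7_slope_var_max: float = 0.02    # variance of normalized dF/dV, C7b
    c7_segment_width: float = 0.5     # L, sliding volume window for C7c
    c7_segment_var_max: float = 0.02  # per-window variance limit, C7c
    c7_signflip_max: float = 0.02     # flips x chord-deviation product, C7d

    # --- Z4: end of test, novel variants (C10, C11) -------------------------
    c10_window2: float = 1.5          # s, alternative EOTV window (C10b)
    c10_threshold2: float = 0.040     # L, relaxed EOTV threshold (C10c)
    c10_eotv_tex_slope: float = 0.5   # 1/s, Tex-indexed threshold slope (C10d/e)
    c11_osc_amplitude: float = 0.05   # L/s, minimum flow swing counted by C11
    c11_signflip_max: int = 4         # number of qualifying swings, C11

    # --- Z5: whole curve (C12a, C12b) ----------------------------------------
    c12_prominence: float = 0.05      # of PEF, secondary-peak prominence
    c12_fev1_band: float = 0.5        # L, volume band around the FEV1 point

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise InputError(f"threshold {f.name!r} must be > 0, got {v!r}")
            if f.name in _FRACTION_FIELDS and not (0.0 < v < 1.0):
                raise InputError(
                    f"threshold {f.name!r} must be a fraction in (0, 1), got {v!r}"
                )
            if f.name in _COUNT_FIELDS and int(v) != v:
                raise InputError(f"threshold {f.name!r} must be an integer, got {v!r}")

    def replace(self, **kwargs) -> "ThresholdConfig":
        return dataclasses.replace(self, **kwargs)

    def to_mapping(self) -> dict:
        """Flat name -> value mapping (round-trips through the config file)."""
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ThresholdConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise InputError(f"unknown threshold keys: {sorted(unknown)}")
        kwargs = {
            k: int(v) if k in _COUNT_FIELDS else float(v) for k, v in mapping.items()
        }
        return cls(**kwargs)

    def fingerprint(self) -> str:
        """Stable short digest identifying this configuration."""
        payload = ";".join(f"{k}={v!r}" for k, v in sorted(self.to_mapping().items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


DEFAULT_CONFIG = ThresholdConfig()
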