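"""Readers and writers: curve files, sessions, configuration, reports.

Curve files are plain delimited text with a header naming ``time`` and at
least one of ``flow`` / ``volume`` (seconds, L/s, L; milliliter units are
converted when declared).  Sessions and configurations are flat YAML
mappings.  Datasets are written one curve file per maneuver plus a manifest
table.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import DEFAULT_CONFIG, ThresholdConfig
from .criteria import CriterionResult
from .errors import FormatError
from .grading import ConfusionStats, GradePolicy, QualityReport, SessionResult
from .signal_core import Maneuver, integrate_flow
from .synthetic import DatasetEntry

logger = logging.getLogger("spiroqc")

__all__ = [
    "read_maneuver",
    "write_maneuver",
    "read_config",
    "write_config",
    "read_session",
    "write_dataset",
    "read_dataset_manifest",
    "report_to_dict",
    "report_to_text",
]

_UNIT_SCALE = {
    ("time", "s"): 1.0,
    ("flow", "L/s"): 1.0,
    ("flow", "mL/s"): 1e-3,
    ("volume", "L"): 1.0,
    ("volume", "mL"): 1e-3,
}


def read_maneuver(
    path,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
    units: dict | None = None,
    resample: bool = True,
) -> Maneuver:
    """Read one maneuver from a delimited-text file.

    The file must have a header row naming ``time`` plus ``flow`` and/or
    ``volume`` (case-insensitive; comma, tab or whitespace delimited).  The
    series are validated and resampled to ``cfg.resample_rate`` unless
    ``resample`` is false.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # malformed text
        raise FormatError(f"could not parse {path}: {exc}") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "time" not in df.columns:
        raise FormatError(f"{path}: missing required column 'time'")
    if "flow" not in df.columns and "volume" not in df.columns:
        raise FormatError(f"{path}: need at least one of 'flow' or 'volume'")

    units = units or {}
    for name, unit in units.items():
        if (name, unit) not in _UNIT_SCALE:
            raise FormatError(f"unsupported unit {unit!r} for column {name!r}")
        if unit.startswith("mL"):
            logger.warning("converting column %s from %s", name, unit)

    defaults = {"flow": "L/s", "volume": "L"}

    def col(name):
        if name not in df.columns:
            return None
        scale = _UNIT_SCALE[(name, units.get(name, defaults[name]))]
        return df[name].to_numpy(dtype=float) * scale

    try:
        time = df["time"].to_numpy(dtype=float)
        flow = col("flow")
        volume = col("volume")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric values: {exc}") from exc
    if np.any(np.diff(time) <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")

    if flow is not None and volume is not None:
        integral = integrate_flow(flow, time) + volume[0]
        dev = float(np.max(np.abs(integral - volume)))
        if dev > 1e-2:
            logger.warning(
                "%s: flow and volume disagree by up to %.3f L; keeping both",
                path,
                dev,
            )
    try:
        return Maneuver.from_samples(
            time,
            flow=flow,
            volume=volume,
            resample_rate=cfg.resample_rate if resample else None,
            meta={"path": str(path)},
        )
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_maneuver(path, maneuver: Maneuver) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time,flow,volume\n")
        for t, f, v in zip(maneuver.time, maneuver.flow, maneuver.volume):
            fh.write(f"{float(t)!r},{float(f)!r},{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def read_config(path) -> tuple[ThresholdConfig, GradePolicy | None]:
    """Flat YAML mapping of threshold names to values, optionally with the
    grading policy under ``policy_rejecting`` / ``policy_warning``."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a flat key/value mapping")
    policy = None
    if "policy_rejecting" in data or "policy_warning" in data:
        try:
            policy = GradePolicy.from_mapping(
                {
                    "policy_rejecting": data.pop("policy_rejecting", []),
                    "policy_warning": data.pop("policy_warning", []),
                }
            )
        except Exception as exc:
            raise FormatError(f"{path}: invalid policy: {exc}") from exc
    try:
        cfg = ThresholdConfig.from_mapping(data)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return cfg, policy


def write_config(path, cfg: ThresholdConfig, policy: GradePolicy | None = None) -> None:
    data: dict = dict(cfg.to_mapping())
    if policy is not None:
        data.update(policy.to_mapping())
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# Sessions and datasets
# ---------------------------------------------------------------------------

def read_session(path, cfg: ThresholdConfig = DEFAULT_CONFIG):
    """Read a session file: YAML with ``session_id`` and a ``maneuvers`` list
    of ``{path: ..., label: 0|1|2}`` records (paths relative to the file).

    Returns ``(session_id, maneuvers, labels)`` where labels may contain None.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"could not parse session {path}: {exc}") from exc
    if not isinstance(data, dict) or "maneuvers" not in data:
        raise FormatError(f"{path}: session file needs a 'maneuvers' list")
    records = data["maneuvers"]
    if not isinstance(records, list) or not records:
        raise FormatError(f"{path}: session must contain at least one maneuver")
    maneuvers, labels = [], []
    for rec in records:
        if not isinstance(rec, dict) or "path" not in rec:
            raise FormatError(f"{path}: each maneuver record needs a 'path'")
        label = rec.get("label")
        if label is not None and label not in (0, 1, 2):
            raise FormatError(f"{path}: labels must be 0, 1 or 2, got {label!r}")
        maneuvers.append(read_maneuver(path.parent / rec["path"], cfg))
        labels.append(label)
    return str(data.get("session_id", path.stem)), maneuvers, labels


def write_dataset(out_dir, entries: list[DatasetEntry]) -> Path:
    """One curve file per maneuver plus ``manifest.csv``; returns the manifest
    path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, entry in enumerate(entries):
        name = f"curve_{i:04d}.csv"
        write_maneuver(out_dir / name, entry.maneuver)
        rows.append(
            {
                "id": f"curve_{i:04d}",
                "path": name,
                "label": entry.label,
                "defect": entry.defect_kind or "",
                "severity": entry.severity,
                "seed": entry.seed,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset_manifest(manifest_path, cfg: ThresholdConfig = DEFAULT_CONFIG):
    """Load a written dataset; returns ``(maneuvers, labels, defects)``."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, keep_default_na=False)
    for col in ("path", "label"):
        if col not in df.columns:
            raise FormatError(f"{manifest_path}: manifest needs column {col!r}")
    maneuvers = [
        read_maneuver(manifest_path.parent / p, cfg) for p in df["path"]
    ]
    defects = [d or None for d in df.get("defect", [""] * len(df))]
    return maneuvers, df["label"].astype(int).tolist(), defects


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _num(x):
    return None if isinstance(x, float) and math.isnan(x) else x


def report_to_dict(report: QualityReport) -> dict:
    return {
        "grade": report.grade,
        "config_fingerprint": report.config_fingerprint,
        "indices": {k: _num(v) for k, v in report.indices.to_dict().items()},
        "criteria": [
            {
                "id": r.criterion_id,
                "outcome": r.outcome,
                "metrics": {k: _num(v) for k, v in r.metrics.items()},
                "thresholds": r.thresholds,
                **({"reason": r.reason} if r.reason else {}),
            }
            for r in report.criterion_results
        ],
    }


def report_to_text(report: QualityReport) -> str:
    lines = [f"grade: {report.grade}",
             f"config: {report.config_fingerprint}",
             "indices:"]
    for k, v in report.indices.to_dict().items():
        shown = "NA" if (isinstance(v, float) and math.isnan(v)) else f"{v:.4f}"
        lines.append(f"  {k:>7}: {shown}")
    lines.append("criteria:")
    for r in report.criterion_results:
        detail = ", ".join(f"{k}={v:.4g}" for k, v in r.metrics.items())
        suffix = f" ({r.reason})" if r.reason else ""
        lines.append(f"  {r.criterion_id:>5}: {r.outcome:<15}{detail}{suffix}")
    return "\n".join(lines)


def session_to_dict(result: SessionResult) -> dict:
    rep = result.repeatability
    return {
        "session_id": result.session_id,
        "grades": result.grades,
        "repeatability": {
            "outcome": rep.outcome,
            "metrics": rep.metrics,
            "thresholds": rep.thresholds,
            **({"reason": rep.reason} if rep.reason else {}),
        },
        "reports": [report_to_dict(r) for r in result.reports],
    }


def confusion_to_dict(stats: ConfusionStats) -> dict:
    return {
        "sensitivity": _num(stats.sensitivity),
        "specificity": _num(stats.specificity),
        "n_grade0": stats.n_grade0,
        "n_grade1": stats.n_grade1,
        "n_grade2": stats.n_grade2,
    }


def dump_json(obj, path=None) -> str:
    text = json.dumps(obj, indent=2, sort_keys=False)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
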