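"""Grade assignment, session aggregation and expert-agreement scoring.

Each maneuver receives one of three grades: 0 (reject, bad morphology),
1 (acceptable morphology) or 2 (needs specialized professional judgment).
A configurable policy routes criterion failures: failures in the *rejecting*
set force grade 0, any remaining failure in the *warning* set yields grade 2,
and a maneuver with no routed failures is grade 1.  Rejecting entries may be
conjunctions (e.g. the end-of-test plateau criterion together with its
short-exhalation companion), written ``C9+C10a`` in configuration files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, ThresholdConfig
from .criteria import (
    MANEUVER_CRITERION_IDS,
    CriterionResult,
    evaluate_all,
    evaluate_repeatability,
)
from .errors import InputError
from .signal_core import Maneuver, SpiroIndices, compute_indices
from .zoning import segment

__all__ = [
    "GradePolicy",
    "QualityReport",
    "SessionResult",
    "ConfusionStats",
    "default_policy",
    "assign_grade",
    "assess_maneuver",
    "assess_session",
    "score_against_labels",
]


@dataclass(frozen=True)
class GradePolicy:
    """Routing of criterion failures to grades.

    ``rejecting`` is a tuple of criterion-id groups; a group triggers grade 0
    only when *all* of its members fail.  ``warning`` is a flat set of ids
    whose failure (absent any rejecting trigger) yields grade 2.  Ids in
    neither place are evaluated and reported but ignored for grading.
    """

    rejecting: tuple[frozenset, ...]
    warning: frozenset

    def __post_init__(self) -> None:
        flat = set().union(*self.rejecting) if self.rejecting else set()
        if flat & self.warning:
            raise InputError("rejecting and warning criterion sets must be disjoint")
        known = set(MANEUVER_CRITERION_IDS) | {"REP"}
        unknown = (flat | self.warning) - known
        if unknown:
            raise InputError(f"unknown criterion ids in policy: {sorted(unknown)}")

    def to_mapping(self) -> dict:
        return {
            "policy_rejecting": ["+".join(sorted(g)) for g in self.rejecting],
            "policy_warning": sorted(self.warning),
        }

    @classmethod
    def from_mapping(cls, mapping: dict) -> "GradePolicy":
        rejecting = tuple(
            frozenset(entry.split("+")) for entry in mapping["policy_rejecting"]
        )
        return cls(rejecting=rejecting, warning=frozenset(mapping["policy_warning"]))


def default_policy() -> GradePolicy:
    """Default failure routing.

    Grade 0 is forced by the criteria that flag decisively unacceptable
    maneuvers: hesitant start (C8), absent plateau on a short exhalation
    (C9 together with C10a), late peak (C3), short exhalation (FET), cough
    signatures (C12a), and the designated detectors of the remaining defect
    families (irregular ascent C2a, flat peak C5a, bimodal peak C5c,
    irregular descent C7b, end-of-test oscillation C11).  Everything else is
    routed to grade 2 for expert review.
    """
    rejecting = (
        frozenset({"C8"}),
        frozenset({"C9", "C10a"}),
        frozenset({"C12a"}),
        frozenset({"C3"}),
        frozenset({"FET"}),
        frozenset({"C2a"}),
        frozenset({"C5a"}),
        frozenset({"C5c"}),
        frozenset({"C7b"}),
        frozenset({"C11"}),
    )
    flat = set().union(*rejecting)
    warning = frozenset(set(MANEUVER_CRITERION_IDS) - flat)
    return GradePolicy(rejecting=rejecting, warning=warning)


DEFAULT_POLICY = default_policy()


def assign_grade(
    criterion_results: list[CriterionResult], policy: GradePolicy = DEFAULT_POLICY
) -> int:
    """Map a full set of criterion outcomes to a grade.

    ``not_applicable`` outcomes never trigger anything; adding a failure to a
    result set can only lower the grade.
    """
    if not criterion_results:
        raise InputError("criterion result list must not be empty")
    failed = {r.criterion_id for r in criterion_results if r.failed}
    for group in policy.rejecting:
        if group <= failed:
            return 0
    if failed & policy.warning:
        return 2
    return 1


@dataclass(frozen=True)
class QualityReport:
    """Grade plus the complete evidence for one maneuver."""

    grade: int
    criterion_results: list[CriterionResult]
    indices: SpiroIndices
    config_fingerprint: str

    def result(self, criterion_id: str) -> CriterionResult:
        for r in self.criterion_results:
            if r.criterion_id == criterion_id:
                return r
        raise KeyError(criterion_id)

    @property
    def failed_ids(self) -> list[str]:
        return [r.criterion_id for r in self.criterion_results if r.failed]


def assess_maneuver(
    maneuver: Maneuver,
    cfg: ThresholdConfig = DEFAULT_CONFIG,
    policy: GradePolicy = DEFAULT_POLICY,
) -> QualityReport:
    """Full pipeline for one maneuver: indices, zones, criteria, grade."""
    indices = compute_indices(maneuver, cfg)
    seg = segment(maneuver, indices, cfg)
    results = evaluate_all(maneuver, seg, indices, cfg)
    return QualityReport(
        grade=assign_grade(results, policy),
        criterion_results=results,
        indices=indices,
        config_fingerprint=cfg.fingerprint(),
    )


@dataclass(frozen=True)
class SessionResult:
    """Per-maneuver reports plus the session repeatability verdict."""

    reports: list[QualityReport]
    repeatability: CriterionResult
    session_id: str = ""

    @property
    def grades(self) -> list[int]:
        return [r.grade for r in self.reports]


def assess_session(
    maneuvers: list[Maneuver],
    cfg: ThresholdConfig = DEFAULT_CONFIG,
    policy: GradePolicy = DEFAULT_POLICY,
    session_id: str = "",
) -> SessionResult:
    if not maneuvers:
        raise InputError("session must contain at least one maneuver")
    reports = [assess_maneuver(m, cfg, policy) for m in maneuvers]
    rep = evaluate_repeatability(
        [r.indices for r in reports],
        cfg,
        acceptable=[r.grade == 1 for r in reports],
    )
    return SessionResult(reports=reports, repeatability=rep, session_id=session_id)


@dataclass(frozen=True)
class ConfusionStats:
    """Agreement between automatic grades and expert labels.

    Sensitivity is the fraction of expert-rejected (grade 0) curves that the
    algorithm also rejects; specificity the fraction of expert-accepted
    (grade 1) curves the algorithm also accepts.  Automatic grade-2 curves are
    counted separately and depress both rates, since they match neither label.
    """

    sensitivity: float
    specificity: float
    n_grade0: int
    n_grade1: int
    n_grade2: int

    @property
    def n_total(self) -> int:
        return self.n_grade0 + self.n_grade1 + self.n_grade2


def score_against_labels(predicted, expert) -> ConfusionStats:
    predicted = np.asarray(predicted, dtype=int)
    expert = np.asarray(expert, dtype=int)
    if predicted.shape != expert.shape or predicted.ndim != 1:
        raise InputError("predicted and expert labels must be equal-length vectors")
    if not np.isin(expert, [0, 1]).all():
        raise InputError("expert labels must be 0 or 1")
    if not np.isin(predicted, [0, 1, 2]).all():
        raise InputError("predicted grades must be 0, 1 or 2")

    n_exp0 = int(np.count_nonzero(expert == 0))
    n_exp1 = int(np.count_nonzero(expert == 1))
    sens = (
        float(np.count_nonzero((predicted == 0) & (expert == 0)) / n_exp0)
        if n_exp0
        else float("nan")
    )
    spec = (
        float(np.count_nonzero((predicted == 1) & (expert == 1)) / n_exp1)
        if n_exp1
        else float("nan")
    )
    return ConfusionStats(
        sensitivity=sens,
        specificity=spec,
        n_grade0=int(np.count_nonzero(predicted == 0)),
        n_grade1=int(np.count_nonzero(predicted == 1)),
        n_grade2=int(np.count_nonzero(predicted == 2)),
    )
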