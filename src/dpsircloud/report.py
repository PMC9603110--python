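"""End-to-end phase assessment and multi-phase comparison.

Two execution modes are supported:

* **full** — start from a raw expert score matrix: entropy weights with
  attribute signs, backward clouds per indicator, signed aggregation,
  grade membership and maximum-membership classification.
* **table replay** — start from an already-computed per-indicator table of
  (code, signed weight, Ex, En, He) rows, as published assessments print
  them, and run only the aggregation/membership/classification tail.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from .clouds import (
    Cloud,
    aggregate_cloud,
    classify_grade,
    estimate_cloud,
    membership_vector,
)
from .errors import AllZeroMembershipError
from .indicators import (
    GradeScheme,
    Indicator,
    Phase,
    PHASE_ORDER,
    ScoreMatrix,
    validate_scores,
)
from .weighting import SignedWeightVector, compute_signed_weights

__all__ = ["AssessmentReport", "assess_matrix", "replay_table", "compare_phases"]


@dataclass
class AssessmentReport:
    """Per-phase assessment output.

    ``rows`` holds one (code, effective weight, Cloud) triple per indicator
    in schema order; ``comprehensive`` is the signed aggregate cloud;
    ``memberships`` maps grade labels to Gaussian memberships of the
    comprehensive expectation; ``grade`` is the maximum-membership label.
    """

    phase: str
    rows: list[tuple[str, float, Cloud]]
    comprehensive: Cloud
    memberships: dict[str, float]
    grade: str
    grade_labels: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Indicator table in the layout of published assessment tables."""
        return pd.DataFrame(
            [
                {"code": c, "weight": w, "ex": cl.ex, "en": cl.en, "he": cl.he}
                for c, w, cl in self.rows
            ]
        ).set_index("code")

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "indicators": [
                {"code": c, "weight": w, "ex": cl.ex, "en": cl.en, "he": cl.he}
                for c, w, cl in self.rows
            ],
            "comprehensive": {
                "ex": self.comprehensive.ex,
                "en": self.comprehensive.en,
                "he": self.comprehensive.he,
            },
            "memberships": dict(self.memberships),
            "grade": self.grade,
            "provenance": dict(self.provenance),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def _provenance(**kw) -> dict:
    blob = json.dumps(kw, sort_keys=True, default=str).encode()
    return {
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "timestamp": datetime.now(timezone.utc).isoformat(),
        **kw,
    }


def _classify(ex: float, memberships: dict[str, float], gs: GradeScheme) -> str:
    try:
        return classify_grade(memberships, gs)
    except AllZeroMembershipError:
        # numerically flat kernel; fall back to the interval containing ex
        return gs.containing(ex).label


def assess_matrix(
    m: ScoreMatrix, schema: Sequence[Indicator], gs: GradeScheme
) -> AssessmentReport:
    """Full-mode assessment of one phase from raw expert scores."""
    m = validate_scores(m, schema)
    weights = compute_signed_weights(m, schema)
    clouds = [estimate_cloud(m.scores[i.code].to_numpy(float)) for i in schema]
    comp = aggregate_cloud(clouds, weights)
    mv = membership_vector(comp.ex, gs)
    grade = _classify(comp.ex, mv, gs)
    rows = [
        (i.code, float(w), c)
        for i, w, c in zip(schema, weights.effective, clouds)
    ]
    return AssessmentReport(
        phase=m.phase.name,
        rows=rows,
        comprehensive=comp,
        memberships=mv,
        grade=grade,
        grade_labels=tuple(gs.labels),
        provenance=_provenance(mode="full", phase=m.phase.name,
                               experts=m.experts, indicators=m.indicators),
    )


def replay_table(
    rows: Sequence[tuple[str, float, float, float, float]],
    gs: GradeScheme,
    phase: str | Phase = "replay",
) -> AssessmentReport:
    """Table-replay assessment from (code, signed weight, Ex, En, He) rows.

    The printed signed weights are taken as-is (no re-derivation from raw
    scores); only aggregation, membership and classification are computed.
    """
    codes = [r[0] for r in rows]
    weights = [float(r[1]) for r in rows]
    clouds = [Cloud(float(r[2]), float(r[3]), float(r[4])) for r in rows]
    comp = aggregate_cloud(clouds, weights)
    mv = membership_vector(comp.ex, gs)
    grade = _classify(comp.ex, mv, gs)
    name = phase.name if isinstance(phase, Phase) else str(phase)
    return AssessmentReport(
        phase=name,
        rows=list(zip(codes, weights, clouds)),
        comprehensive=comp,
        memberships=mv,
        grade=grade,
        grade_labels=tuple(gs.labels),
        provenance=_provenance(mode="table-replay", phase=name, codes=codes),
    )


def compare_phases(reports: Sequence[AssessmentReport]) -> pd.DataFrame:
    """Side-by-side comparison of phase assessments.

    Rows are ordered CP, SOP, LOP first (any other phase names follow in
    input order); columns: comprehensive Ex/En/He, assigned grade, and one
    membership column per grade label. All reports must share a grade
    scheme (same labels).
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    labels = reports[0].grade_labels
    for r in reports[1:]:
        if r.grade_labels != labels:
            raise ValueError(
                f"mismatched grade schemes: {labels} vs {r.grade_labels}"
            )

    def order(r: AssessmentReport) -> tuple[int, int]:
        try:
            return (0, PHASE_ORDER.index(r.phase))
        except ValueError:
            return (1, 0)

    ordered = sorted(enumerate(reports), key=lambda t: (*order(t[1]), t[0]))
    recs = []
    for _, r in ordered:
        rec = {
            "phase": r.phase,
            "ex": r.comprehensive.ex,
            "en": r.comprehensive.en,
            "he": r.comprehensive.he,
            "grade": r.grade,
        }
        rec.update({f"mu_{lab}": r.memberships[lab] for lab in labels})
        recs.append(rec)
    return pd.DataFrame(recs).set_index("phase")
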