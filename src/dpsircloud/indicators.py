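"""Indicator schema, grade scheme, phases and the expert score matrix.

The assessment operates on a DPSIR indicator system: each indicator belongs
to one of the causal categories Driving force, Pressure, State, Impact,
Response, and carries an *attribute* that decides how it enters the signed
aggregation — ``positive`` indicators add to the comprehensive benefit,
``negative`` ones subtract, and ``neutral`` ones take their sign from the
panel's mean score relative to the 0.5 midpoint.

Expert elicitation produces one score matrix per project phase
(construction period CP, short-term operation SOP, long-term operation LOP):
rows are experts, columns are indicator codes, entries are scores on [0, 1].
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ScoreValidationError

CATEGORIES = frozenset("DPSIR")
ATTRIBUTES = frozenset({"positive", "negative", "neutral"})

_EPS = 1e-9


@dataclass(frozen=True)
class Indicator:
    """One evaluation indicator of the DPSIR system."""

    code: str
    category: str
    attribute: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"indicator {self.code!r}: unknown category {self.category!r}"
            )
        if self.attribute not in ATTRIBUTES:
            raise SchemaError(
                f"indicator {self.code!r}: unknown attribute {self.attribute!r}"
            )


@dataclass(frozen=True)
class GradeInterval:
    label: str
    lower: float
    upper: float
    description: str = ""

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise SchemaError(
                f"grade {self.label!r}: bounds must satisfy lower < upper, "
                f"got ({self.lower}, {self.upper})"
            )


@dataclass(frozen=True)
class GradeScheme:
    """Ordered grade intervals partitioning [0, 1], plus the standard-cloud
    hyper-entropy constant ``k``.

    Intervals must be contiguous and cover [0, 1] exactly; the default
    five-grade scheme is I (0, 0.2) ... V (0.8, 1.0), ordered from the
    smallest impact to the greatest.
    """

    grades: tuple[GradeInterval, ...]
    hyper_entropy_constant: float = 0.01

    def __post_init__(self) -> None:
        if not self.grades:
            raise SchemaError("grade scheme needs at least one interval")
        labels = [g.label for g in self.grades]
        if len(set(labels)) != len(labels):
            raise SchemaError(f"duplicate grade labels: {labels}")
        if abs(self.grades[0].lower) > _EPS or abs(self.grades[-1].upper - 1) > _EPS:
            raise SchemaError("grade intervals must cover [0, 1]")
        for a, b in zip(self.grades, self.grades[1:]):
            if abs(a.upper - b.lower) > _EPS:
                raise SchemaError(
                    f"grade intervals not contiguous at {a.label!r}/{b.label!r}: "
                    f"{a.upper} != {b.lower}"
                )
        if self.hyper_entropy_constant < 0:
            raise SchemaError("hyper_entropy_constant must be >= 0")

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.grades]

    def containing(self, x: float) -> GradeInterval:
        """Interval containing score ``x`` (upper bound inclusive at 1)."""
        for g in self.grades:
            if g.lower <= x < g.upper:
                return g
        if abs(x - 1.0) <= _EPS:
            return self.grades[-1]
        raise ValueError(f"score {x} outside [0, 1]")


@dataclass(frozen=True)
class Phase:
    """A project life-cycle phase. CP/SOP/LOP in the default workflow."""

    name: str
    description: str = ""


CP = Phase("CP", "construction period")
SOP = Phase("SOP", "short-term operation period")
LOP = Phase("LOP", "long-term operation period")
PHASE_ORDER = ("CP", "SOP", "LOP")


@dataclass
class ScoreMatrix:
    """Expert scores for one phase: experts x indicators on [0, 1].

    ``scores`` is a DataFrame whose index holds expert identifiers and whose
    columns are indicator codes, in schema order.
    """

    phase: Phase
    scores: pd.DataFrame = field(repr=False)

    @property
    def experts(self) -> list[str]:
        return [str(e) for e in self.scores.index]

    @property
    def indicators(self) -> list[str]:
        return [str(c) for c in self.scores.columns]

    @property
    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)

    @classmethod
    def from_delimited(
        cls, source: str | Path | io.TextIOBase, phase: Phase, sep: str = "\t"
    ) -> "ScoreMatrix":
        """Read a matrix from delimited text: header row of indicator codes,
        first column = expert identifier."""
        df = pd.read_csv(source, sep=sep, index_col=0)
        return cls(phase=phase, scores=df)

    def to_delimited(self, path: str | Path, sep: str = "\t") -> None:
        self.scores.to_csv(path, sep=sep, index_label="expert")


def _build_grade_scheme(doc: dict) -> GradeScheme:
    grades = tuple(
        GradeInterval(
            label=str(g["label"]),
            lower=float(g["lower"]),
            upper=float(g["upper"]),
            description=str(g.get("description", "")),
        )
        for g in doc["grades"]
    )
    return GradeScheme(
        grades=grades,
        hyper_entropy_constant=float(doc.get("hyper_entropy_constant", 0.01)),
    )


def load_schema(
    source: str | Path | io.TextIOBase,
) -> tuple[list[Indicator], GradeScheme]:
    """Load an indicator schema and grade scheme from a YAML document.

    Raises :class:`SchemaError` on duplicate indicator codes, unknown
    categories/attributes, or non-covering grade intervals.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    if not isinstance(doc, dict) or "indicators" not in doc or "grades" not in doc:
        raise SchemaError("schema document must define 'indicators' and 'grades'")
    indicators = [
        Indicator(
            code=str(d["code"]),
            category=str(d["category"]),
            attribute=str(d["attribute"]),
            description=str(d.get("description", "")),
        )
        for d in doc["indicators"]
    ]
    codes = [i.code for i in indicators]
    dupes = {c for c in codes if codes.count(c) > 1}
    if dupes:
        raise SchemaError(f"duplicate indicator codes: {sorted(dupes)}")
    return indicators, _build_grade_scheme(doc)


def dump_schema(
    indicators: Sequence[Indicator], gs: GradeScheme, path: str | Path
) -> None:
    """Write a schema back to YAML (round-trips with :func:`load_schema`)."""
    doc = {
        "indicators": [
            {
                "code": i.code,
                "category": i.category,
                "attribute": i.attribute,
                "description": i.description,
            }
            for i in indicators
        ],
        "grades": [
            {
                "label": g.label,
                "lower": g.lower,
                "upper": g.upper,
                "description": g.description,
            }
            for g in gs.grades
        ],
        "hyper_entropy_constant": gs.hyper_entropy_constant,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_schema() -> tuple[list[Indicator], GradeScheme]:
    """The bundled 14-indicator DPSIR schema and five-grade scheme."""
    ref = resources.files("dpsircloud.data").joinpath("schema_default.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    indicators = [
        Indicator(
            code=str(d["code"]),
            category=str(d["category"]),
            attribute=str(d["attribute"]),
            description=str(d.get("description", "")),
        )
        for d in doc["indicators"]
    ]
    return indicators, _build_grade_scheme(doc)


def validate_scores(
    m: ScoreMatrix, schema: Iterable[Indicator]
) -> ScoreMatrix:
    """Check a score matrix against a schema; reject rather than repair.

    The matrix must contain exactly the schema's indicator codes; columns are
    reordered to schema order. Values must be finite and within [0, 1]; at
    least 2 experts and 2 indicators are required (dispersion information is
    needed downstream by both the entropy weights and the backward cloud).
    """
    codes = [i.code for i in schema]
    have = list(map(str, m.scores.columns))
    missing = [c for c in codes if c not in have]
    if missing:
        raise ScoreValidationError(
            f"{m.phase.name}: missing indicator column(s): {missing}"
        )
    extra = [c for c in have if c not in codes]
    if extra:
        raise ScoreValidationError(
            f"{m.phase.name}: unknown indicator column(s): {extra}"
        )
    df = m.scores[codes]
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ScoreValidationError(
            f"{m.phase.name}: need >=2 experts and >=2 indicators, "
            f"got shape {df.shape}"
        )
    vals = df.to_numpy(dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ScoreValidationError(
            f"{m.phase.name}: missing/non-finite score for expert "
            f"{df.index[i]!r}, indicator {df.columns[j]!r}"
        )
    out = (vals < 0) | (vals > 1)
    if out.any():
        i, j = map(int, np.argwhere(out)[0])
        raise ScoreValidationError(
            f"{m.phase.name}: score {vals[i, j]} out of [0, 1] for expert "
            f"{df.index[i]!r}, indicator {df.columns[j]!r}"
        )
    return ScoreMatrix(phase=m.phase, scores=df)
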