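"""Synthetic expert panels and the bundled published case tables.

Real elicitation data for the case study (10 experts scoring 14 DPSIR
indicators per phase) are unpublished, so the package ships two
substitutes:

* a panel generator that draws expert scores from per-indicator bands,
  emulating a panel whose members broadly agree on each indicator's level
  but disagree within a band — the structure the entropy weighting and
  backward cloud estimation assume; and
* the published per-indicator (signed weight, Ex, En, He) tables for the
  construction and long-term operation periods, stored verbatim as
  delimited text, for table-replay assessment and cross-checks.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError
from .indicators import Phase, ScoreMatrix, default_schema

__all__ = ["PanelSpec", "generate_panel", "fixture_tables", "default_panel_spec"]

FixtureRow = tuple[str, float, float, float, float]


@dataclass
class PanelSpec:
    """Specification of a synthetic expert panel.

    ``bands`` maps phase name -> {indicator code: (center, half_width)}.
    Scores are drawn per expert per indicator from the band, truncated to
    the band's intersection with [0, 1]; ``noise_scale`` multiplies every
    half-width (0 makes all experts score the centers exactly).
    ``distribution`` is "uniform" (default) or "normal" (center-anchored,
    sd = effective half-width / 2, then truncated).
    """

    bands: Mapping[str, Mapping[str, tuple[float, float]]]
    n_experts: int = 10
    noise_scale: float = 1.0
    distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ValueError("need at least 2 experts")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.distribution not in ("uniform", "normal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        for phase, phase_bands in self.bands.items():
            for code, (c, h) in phase_bands.items():
                if h < 0:
                    raise ValueError(f"{phase}/{code}: half-width must be >= 0")
                if not 0.0 <= c <= 1.0:
                    raise ValueError(f"{phase}/{code}: center {c} outside [0, 1]")


def generate_panel(spec: PanelSpec, phase: Phase) -> ScoreMatrix:
    """Draw one phase's expert score matrix from the spec's bands.

    Deterministic under ``spec.seed`` (the phase name is folded into the
    stream so CP/SOP/LOP panels from one spec are independent draws).
    """
    if phase.name not in spec.bands:
        raise KeyError(f"spec has no bands for phase {phase.name!r}")
    phase_bands = spec.bands[phase.name]
    codes = list(phase_bands)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, *(ord(ch) for ch in phase.name)])
    )
    cols = {}
    for code in codes:
        c, h = phase_bands[code]
        h = h * spec.noise_scale
        lo, hi = max(0.0, c - h), min(1.0, c + h)
        if spec.distribution == "uniform":
            draw = rng.uniform(lo, hi, size=spec.n_experts)
        else:
            draw = np.clip(rng.normal(c, h / 2.0 if h > 0 else 0.0,
                                      size=spec.n_experts), lo, hi)
        cols[code] = draw
    experts = [f"E{i + 1}" for i in range(spec.n_experts)]
    return ScoreMatrix(
        phase=phase, scores=pd.DataFrame(cols, index=pd.Index(experts, name="expert"))
    )


def _load_table(name: str) -> list[FixtureRow]:
    ref = resources.files("dpsircloud.data").joinpath(name)
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        (str(r.code), float(r.weight), float(r.ex), float(r.en), float(r.he))
        for r in df.itertuples()
    ]


def fixture_tables() -> dict[str, list[FixtureRow]]:
    """Published per-indicator tables as (code, weight, Ex, En, He) rows.

    Keys:

    * ``"CP"`` — construction period, exactly as printed;
    * ``"LOP"`` — long-term operation period, exactly as printed (R3's
      weight appears positive there);
    * ``"LOP_corrected"`` — LOP with R3's weight sign flipped to negative,
      consistent with the neutral-indicator rule (R3's mean score 0.33 is
      below 0.5) and with the published comprehensive expectation 0.3332.
    """
    cp = _load_table("table_cp.tsv")
    lop = _load_table("table_lop.tsv")
    corrected = [
        (c, -abs(w), ex, en, he) if c == "R3" else (c, w, ex, en, he)
        for c, w, ex, en, he in lop
    ]
    return {"CP": cp, "LOP": lop, "LOP_corrected": corrected}


def default_panel_spec(
    half_width: float = 0.15, n_experts: int = 10, seed: int = 0
) -> PanelSpec:
    """A realistic two-phase panel spec anchored to the published case.

    Band centers are the published per-indicator cloud expectations for CP
    and LOP; a common half-width of 0.15 yields backward-cloud entropies
    around 0.09, matching the dispersion the published tables show
    (En 0.07–0.14).
    """
    schema, _ = default_schema()
    codes = {i.code for i in schema}
    tables = fixture_tables()
    bands = {
        phase: {code: (ex, half_width) for code, _, ex, _, _ in rows}
        for phase, rows in (("CP", tables["CP"]), ("LOP", tables["LOP"]))
    }
    for phase_bands in bands.values():
        missing = codes - set(phase_bands)
        if missing:
            raise SchemaError(f"fixture table missing codes: {sorted(missing)}")
    return PanelSpec(bands=bands, n_experts=n_experts, seed=seed)
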