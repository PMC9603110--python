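"""Monte Carlo assessment of the short-term operation period (SOP).

The short-term operation phase of a restoration project sits between two
phases experts can score with confidence: the construction period (CP) and
the long-term operation period (LOP). Its own state is hard to elicit
directly, so it is simulated under two assumptions:

* the SOP score of every expert on every indicator lies between that
  expert's CP and LOP scores for the indicator (the phase is a transition
  between the two observable states), and
* within that cell-wise interval the score is uniformly distributed (no
  grade inside the band is privileged).

Each iteration draws a full expert score matrix cell-wise from
U[min(cp, lop), max(cp, lop)] and runs the complete assessment chain on it
— entropy weights with attribute signs, backward clouds, signed
aggregation — collecting the comprehensive cloud expectation. The
distribution of that expectation is summarized by its mean and a
normal-approximation confidence interval, and graded by maximum
membership.

The per-iteration pipeline is evaluated vectorized across iterations; it is
numerically identical to running :func:`dpsircloud.report.assess_matrix` on
each simulated matrix (asserted in the test suite).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .clouds import membership_vector
from .errors import DegeneracyError, DegeneracyWarning
from .indicators import GradeScheme, Indicator, ScoreMatrix, SOP, validate_scores
from .report import _classify
from .weighting import SignedWeightVector

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SimulationSummary",
    "simulate_phase",
    "confidence_interval",
    "summarize_simulation",
]

_SQRT_HALF_PI = float(np.sqrt(np.pi / 2.0))


@dataclass
class SimulationConfig:
    """Configuration for the SOP Monte Carlo run.

    ``cp`` and ``lop`` are the bounding score matrices (same experts, same
    indicators); ``n_sims`` defaults to 10,000 iterations and ``ci_level``
    to a 95% confidence interval.
    """

    cp: ScoreMatrix
    lop: ScoreMatrix
    n_sims: int = 10_000
    seed: int = 0
    ci_level: float = 0.95
    keep_scores: bool = False

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class SimulationResult:
    """Distribution of the comprehensive cloud expectation across iterations."""

    ex_samples: np.ndarray
    mean: float
    sd: float
    ci: tuple[float, float]
    memberships: dict[str, float]
    grade: str
    n_sims: int
    seed: int
    ci_level: float
    scores: np.ndarray | None = field(default=None, repr=False)


@dataclass
class SimulationSummary:
    """Report of the simulated phase: memberships evaluated at the CI lower
    bound, the mean, and the CI upper bound; grade at the mean."""

    phase: str
    mean: float
    sd: float
    ci: tuple[float, float]
    memberships_lower: dict[str, float]
    memberships_mean: dict[str, float]
    memberships_upper: dict[str, float]
    grade: str
    n_sims: int
    seed: int
    ci_level: float

    def to_dict(self) -> dict:
        return {
            "phase": self.phase,
            "mean": self.mean,
            "sd": self.sd,
            "ci_lower": self.ci[0],
            "ci_upper": self.ci[1],
            "ci_level": self.ci_level,
            "memberships_lower": dict(self.memberships_lower),
            "memberships_mean": dict(self.memberships_mean),
            "memberships_upper": dict(self.memberships_upper),
            "grade": self.grade,
            "n_sims": self.n_sims,
            "seed": self.seed,
        }


def confidence_interval(
    samples: Sequence[float] | np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation CI for the mean: mean +/- z * sd / sqrt(n)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples for a confidence interval")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    half = z * float(x.std(ddof=1)) / np.sqrt(x.size)
    m = float(x.mean())
    return (m - half, m + half)


def _pipeline_vectorized(
    X: np.ndarray,
    attr_sign: np.ndarray,
    fixed_weights: np.ndarray | None,
) -> np.ndarray:
    """Comprehensive Ex per iteration for a (S, m, k) score stack.

    Mirrors the scalar chain: benefit-oriented min-max normalization per
    column, normalized Shannon entropy over experts, magnitude weights,
    attribute/neutral signs, cloud expectation = column mean, signed sum.
    """
    S, m, k = X.shape
    means = X.mean(axis=1)  # (S, k) == per-indicator cloud Ex
    if fixed_weights is not None:
        return (means * fixed_weights[None, :]).sum(axis=1)

    mn = X.min(axis=1, keepdims=True)
    rng = X.max(axis=1, keepdims=True) - mn
    with np.errstate(invalid="ignore", divide="ignore"):
        Y = np.where(rng > 0, (X - mn) / rng, 0.0)
        colsum = Y.sum(axis=1, keepdims=True)
        p = np.where(colsum > 0, Y / colsum, 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    E = -plogp.sum(axis=1) / np.log(m)  # (S, k)
    E = np.where(colsum[:, 0, :] > 0, E, 1.0)  # constant column -> max entropy

    denom = k - E.sum(axis=1)  # (S,)
    if (denom <= 1e-9).any():
        raise DegeneracyError(
            "an iteration produced all-uninformative columns (every entropy "
            "= 1); entropy weights are undefined"
        )
    w = (1.0 - E) / denom[:, None]
    signs = np.where(attr_sign == 0, np.where(means >= 0.5, 1.0, -1.0), attr_sign)
    return (means * w * signs).sum(axis=1)


def simulate_phase(
    cfg: SimulationConfig,
    schema: Sequence[Indicator],
    gs: GradeScheme,
    fixed_weights: SignedWeightVector | None = None,
) -> SimulationResult:
    """Monte Carlo simulation of the short-term operation period.

    Draws ``cfg.n_sims`` score matrices cell-wise uniform between the CP and
    LOP scores and runs the full weighting + cloud pipeline on each,
    re-computing entropy weights per iteration (pass ``fixed_weights`` to
    freeze a signed weight vector instead, e.g. for envelope analyses).
    Deterministic under ``cfg.seed``.
    """
    cp = validate_scores(cfg.cp, schema)
    lop = validate_scores(cfg.lop, schema)
    if cp.experts != lop.experts:
        raise ValueError(
            f"CP and LOP matrices must share experts: {cp.experts} vs {lop.experts}"
        )
    A = cp.values
    B = lop.values
    lo = np.minimum(A, B)
    hi = np.maximum(A, B)
    if np.array_equal(lo, hi):
        warnings.warn(
            "CP and LOP matrices are identical: the simulation collapses to "
            "a point and the CI has zero width",
            DegeneracyWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(cfg.seed)
    S = cfg.n_sims
    u = rng.random(size=(S, *A.shape))
    X = lo[None, :, :] + u * (hi - lo)[None, :, :]

    attr_sign = np.array(
        [
            1.0 if i.attribute == "positive" else -1.0 if i.attribute == "negative" else 0.0
            for i in schema
        ]
    )
    fw = fixed_weights.effective if fixed_weights is not None else None
    ex = _pipeline_vectorized(X, attr_sign, fw)

    mean = float(ex.mean())
    sd = float(ex.std(ddof=1)) if S > 1 else 0.0
    if S > 1:
        ci = confidence_interval(ex, cfg.ci_level)
    else:
        ci = (mean, mean)
    mv = membership_vector(mean, gs)
    grade = _classify(mean, mv, gs)
    return SimulationResult(
        ex_samples=ex,
        mean=mean,
        sd=sd,
        ci=ci,
        memberships=mv,
        grade=grade,
        n_sims=S,
        seed=cfg.seed,
        ci_level=cfg.ci_level,
        scores=X if cfg.keep_scores else None,
    )


def summarize_simulation(
    r: SimulationResult, gs: GradeScheme, phase_name: str = SOP.name
) -> SimulationSummary:
    """Summarize a simulation: memberships at the CI bounds and the mean,
    grade by maximum membership at the mean expectation."""
    lo, hi = r.ci
    mv_mean = membership_vector(r.mean, gs)
    return SimulationSummary(
        phase=phase_name,
        mean=r.mean,
        sd=r.sd,
        ci=r.ci,
        memberships_lower=membership_vector(lo, gs),
        memberships_mean=mv_mean,
        memberships_upper=membership_vector(hi, gs),
        grade=_classify(r.mean, mv_mean, gs),
        n_sims=r.n_sims,
        seed=r.seed,
        ci_level=r.ci_level,
    )
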