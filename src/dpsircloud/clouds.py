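"""Normal cloud model: standard clouds, backward/forward generators,
signed aggregation, grade membership.

A cloud represents a qualitative concept on a quantitative domain by three
numbers: the expectation Ex (where the concept is centred), the entropy En
(its fuzziness/dispersion) and the hyper-entropy He (the uncertainty of En,
visually the "thickness" of the droplet band). Droplets are random
realizations (x, y) where y is the certainty degree of x for the concept.

Grade membership is evaluated deterministically with the Gaussian kernel
mu = exp(-(Ex - Ex_j)^2 / (2 En_j^2)) against each grade's standard cloud;
the grade is assigned by maximum membership.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._util import round_half_up
from .errors import AllZeroMembershipError, DegeneracyWarning
from .indicators import GradeScheme
from .weighting import SignedWeightVector

__all__ = [
    "Cloud",
    "DropletField",
    "standard_clouds",
    "estimate_cloud",
    "generate_droplets",
    "aggregate_cloud",
    "membership",
    "membership_vector",
    "classify_grade",
]

_MAX_REJECTIONS = 1000

# mean absolute deviation of a Gaussian is sigma*sqrt(2/pi); the backward
# estimator inverts that relation
_HALF_PI_SQRT = float(np.sqrt(np.pi / 2.0))


@dataclass(frozen=True)
class Cloud:
    """Normal cloud (Ex, En, He) on the score scale."""

    ex: float
    en: float
    he: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ex) and np.isfinite(self.en) and np.isfinite(self.he)):
            raise ValueError("cloud parameters must be finite")
        if self.en < 0 or self.he < 0:
            raise ValueError("En and He must be >= 0")

    def rounded(self, ndigits: int = 4) -> "Cloud":
        return Cloud(
            round_half_up(self.ex, ndigits),
            round_half_up(self.en, ndigits),
            round_half_up(self.he, ndigits),
        )


@dataclass(frozen=True)
class DropletField:
    """Forward-generator output: arrays of x, certainty y and the entropy
    draw en_prime used for each droplet."""

    x: np.ndarray
    y: np.ndarray
    en_prime: np.ndarray

    def __len__(self) -> int:
        return self.x.size

    def to_array(self) -> np.ndarray:
        """(n, 2) array of (x, y) pairs for export."""
        return np.column_stack([self.x, self.y])


def standard_clouds(gs: GradeScheme) -> list[Cloud]:
    """Standard cloud per grade interval (Cmin, Cmax):

    Ex = (Cmax + Cmin)/2, En = (Cmax - Cmin)/6, He = k.

    En spans the interval with three standard deviations on either side of
    its midpoint, so neighbouring grades overlap only in their tails.
    """
    k = gs.hyper_entropy_constant
    return [
        Cloud(ex=(g.upper + g.lower) / 2.0, en=(g.upper - g.lower) / 6.0, he=k)
        for g in gs.grades
    ]


def estimate_cloud(samples: Sequence[float] | np.ndarray) -> Cloud:
    """Backward cloud generator: estimate (Ex, En, He) from samples.

    Ex is the sample mean; En = sqrt(pi/2) * mean|x - Ex| (the Gaussian
    mean-absolute-deviation inversion); He = sqrt(S^2 - En^2) with S^2 the
    unbiased variance. Sampling noise can push S^2 below En^2, in which case
    He is clamped to 0 with a DegeneracyWarning.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to estimate a cloud")
    ex = float(x.mean())
    s2 = float(x.var(ddof=1))
    en = float(_HALF_PI_SQRT * np.abs(x - ex).mean())
    diff = s2 - en * en
    if diff < 0:
        warnings.warn(
            f"sample variance {s2:.3g} below En^2 {en * en:.3g}; "
            "hyper-entropy clamped to 0",
            DegeneracyWarning,
            stacklevel=2,
        )
        he = 0.0
    else:
        he = float(np.sqrt(diff))
    return Cloud(ex=ex, en=en, he=he)


def generate_droplets(c: Cloud, n: int, seed: int | np.random.Generator) -> DropletField:
    """Forward cloud generator: n droplets from cloud ``c``.

    Per droplet: En' ~ Normal(En, He), x ~ Normal(Ex, En'),
    y = exp(-(x - Ex)^2 / (2 En'^2)). Deterministic under a fixed seed.
    Draws with En' <= 0 (possible when He is large relative to En) are
    rejected and resampled, preserving the Normal(En, He) law on the
    positive half-line; more than 1000 consecutive all-rejected rounds abort.
    """
    if n < 1:
        raise ValueError("droplet count must be >= 1")
    if c.en == 0 and c.he > 0:
        raise ValueError("En = 0 with He > 0 gives no valid entropy draws")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if c.en == 0:  # degenerate point cloud
        x = np.full(n, c.ex)
        return DropletField(x=x, y=np.ones(n), en_prime=np.zeros(n))
    if c.he == 0:
        en_prime = np.full(n, c.en)
    else:
        en_prime = np.empty(n)
        filled = 0
        rejections = 0
        while filled < n:
            draw = rng.normal(c.en, c.he, size=n - filled)
            ok = draw > 0
            kept = int(ok.sum())
            if kept == 0:
                rejections += 1
                if rejections > _MAX_REJECTIONS:
                    raise RuntimeError(
                        f"forward generator: >{_MAX_REJECTIONS} consecutive "
                        f"all-rejected rounds for En'={c.en}, He={c.he}; "
                        "the positive mass of Normal(En, He) is negligible"
                    )
                continue
            rejections = 0
            en_prime[filled : filled + kept] = draw[ok]
            filled += kept
    x = rng.normal(c.ex, en_prime)
    y = np.exp(-((x - c.ex) ** 2) / (2.0 * en_prime**2))
    return DropletField(x=x, y=y, en_prime=en_prime)


def aggregate_cloud(
    clouds: Sequence[Cloud], w: SignedWeightVector | Sequence[float] | np.ndarray
) -> Cloud:
    """Signed weighted aggregation of per-indicator clouds.

    Ex = sum(Ex_i * w_i) with signed weights w_i (negative indicators
    subtract benefit); En = sqrt(sum((En_i w_i)^2)); He likewise. En/He
    combine in quadrature, so the comprehensive fuzziness never exceeds the
    magnitude-weighted norm of the parts.
    """
    weights = w.effective if isinstance(w, SignedWeightVector) else np.asarray(w, float)
    if len(clouds) != weights.size:
        raise ValueError(
            f"{len(clouds)} clouds vs {weights.size} weights: lengths must match"
        )
    ex = np.array([c.ex for c in clouds])
    en = np.array([c.en for c in clouds])
    he = np.array([c.he for c in clouds])
    return Cloud(
        ex=float((ex * weights).sum()),
        en=float(np.sqrt(((en * weights) ** 2).sum())),
        he=float(np.sqrt(((he * weights) ** 2).sum())),
    )


def membership(ex: float, std: Cloud) -> float:
    """Gaussian-kernel membership of a comprehensive expectation in a grade.

    mu = exp(-(ex - Ex_j)^2 / (2 En_j^2)), evaluated deterministically from
    the standard cloud's (Ex, En); He plays no role here. A degenerate
    standard cloud (En = 0) gives mu = 1 at its centre and 0 elsewhere.
    """
    if std.en == 0:
        return 1.0 if ex == std.ex else 0.0
    return float(np.exp(-((ex - std.ex) ** 2) / (2.0 * std.en**2)))


def membership_vector(ex: float, gs: GradeScheme) -> dict[str, float]:
    """Membership of ``ex`` in every grade of the scheme, keyed by label."""
    return {
        g.label: membership(ex, std)
        for g, std in zip(gs.grades, standard_clouds(gs))
    }


def classify_grade(mv: Mapping[str, float], gs: GradeScheme) -> str:
    """Maximum-membership grade assignment.

    Exact ties break toward the higher (more severe) grade. If every
    membership is zero the kernel carries no information and an
    :class:`AllZeroMembershipError` is raised, advising a fallback to the
    interval containing the expectation.
    """
    if not mv:
        raise ValueError("empty membership vector")
    labels = [g.label for g in gs.grades if g.label in mv]
    if len(labels) != len(mv):
        unknown = set(mv) - set(gs.labels)
        raise ValueError(f"membership labels not in grade scheme: {sorted(unknown)}")
    best = max(labels, key=lambda lab: (mv[lab], labels.index(lab)))
    if mv[best] == 0.0:
        raise AllZeroMembershipError(
            "all grade memberships are zero; classify by the interval "
            "containing the expectation instead (GradeScheme.containing)"
        )
    return best
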