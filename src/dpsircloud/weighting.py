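"""Signed entropy weights for DPSIR indicators.

The entropy weight method is an objective weighting scheme: an indicator
whose scores disagree more across experts carries more information and gets
a larger weight magnitude. Signs are then attached from the indicator
attributes so that environment-damaging (negative) indicators subtract from
the comprehensive score instead of being folded into a positive scale:

1. min–max normalize every column (benefit orientation for all columns;
   direction is carried entirely by the weight sign),
2. per-column information entropy E_j = -(ln n)^-1 * sum_i p_ij ln p_ij
   with p_ij the column-normalized shares,
3. magnitudes w_j = (1 - E_j) / (k - sum_j E_j),
4. signs: positive attribute -> +1, negative -> -1, neutral -> the sign of
   the panel's raw mean score minus 0.5 (ties to +1).

A constant column carries no discriminating information: it normalizes to
zeros, is assigned the maximal entropy 1 and hence weight 0, with a
:class:`~dpsircloud.errors.DegeneracyWarning`.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegeneracyError, DegeneracyWarning
from .indicators import Indicator, ScoreMatrix

__all__ = [
    "SignedWeightVector",
    "normalize_positive",
    "normalize_negative",
    "information_entropy",
    "entropy_weights",
    "assign_signs",
    "compute_signed_weights",
]

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SignedWeightVector:
    """Entropy-derived weight magnitudes with attribute-derived signs.

    Magnitudes are non-negative and sum to 1; the effective weight of an
    indicator is ``sign * magnitude``.
    """

    codes: tuple[str, ...]
    magnitudes: np.ndarray
    signs: np.ndarray

    def __post_init__(self) -> None:
        mags = np.asarray(self.magnitudes, dtype=float)
        signs = np.asarray(self.signs, dtype=float)
        object.__setattr__(self, "magnitudes", mags)
        object.__setattr__(self, "signs", signs)
        if mags.shape != signs.shape or mags.shape != (len(self.codes),):
            raise ValueError("codes, magnitudes and signs must align")
        if (mags < -_SUM_TOL).any():
            raise ValueError("weight magnitudes must be >= 0")
        if abs(mags.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"weight magnitudes must sum to 1, got {mags.sum()!r}"
            )
        if not np.isin(signs, (-1.0, 1.0)).all():
            raise ValueError("signs must be +1 or -1")

    @property
    def effective(self) -> np.ndarray:
        """Signed weights, ``sign * magnitude``."""
        return self.signs * self.magnitudes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": self.codes,
                "magnitude": self.magnitudes,
                "sign": self.signs.astype(int),
                "effective": self.effective,
            }
        ).set_index("code")


def normalize_positive(column: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benefit-oriented min–max normalization: (x - min) / (max - min).

    A constant column maps to all zeros (with a DegeneracyWarning): the
    column then contributes maximal entropy and zero weight downstream.
    """
    x = np.asarray(column, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    rng = x.max() - x.min()
    if rng == 0:
        warnings.warn(
            "constant column normalized to zeros", DegeneracyWarning, stacklevel=2
        )
        return np.zeros_like(x)
    return (x - x.min()) / rng


def normalize_negative(column: Sequence[float] | np.ndarray) -> np.ndarray:
    """Cost-oriented min–max normalization: (max - x) / (max - min).

    Provided for completeness; the default pipeline normalizes every column
    with :func:`normalize_positive` and carries direction in the weight sign.
    """
    x = np.asarray(column, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    rng = x.max() - x.min()
    if rng == 0:
        warnings.warn(
            "constant column normalized to zeros", DegeneracyWarning, stacklevel=2
        )
        return np.zeros_like(x)
    return (x.max() - x) / rng


def information_entropy(
    normalized_column: Sequence[float] | np.ndarray, n: int | None = None
) -> float:
    """Normalized Shannon entropy of a column of non-negative shares.

    E = -(ln n)^-1 * sum_i p_i ln p_i with p_i = y_i / sum(y), using the
    convention 0*ln(0) = 0. ``n`` defaults to the column length (the number
    of evaluation objects, i.e. experts). An all-zero column has undefined
    shares and is assigned the maximal entropy 1 (uniform convention), with
    a DegeneracyWarning.
    """
    y = np.asarray(normalized_column, dtype=float)
    if (y < 0).any():
        raise ValueError("normalized values must be >= 0")
    if n is None:
        n = y.size
    if n < 2:
        raise ValueError("need n >= 2 evaluation objects")
    total = y.sum()
    if total == 0:
        warnings.warn(
            "all-zero column assigned maximal entropy 1",
            DegeneracyWarning,
            stacklevel=2,
        )
        return 1.0
    p = y / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(n))


def entropy_weights(
    E: Sequence[float] | np.ndarray, k_count: int | None = None
) -> np.ndarray:
    """Weight magnitudes from per-indicator entropies: w_j = (1-E_j)/(k-sum E).

    Raises :class:`DegeneracyError` when every entropy equals 1 — the scores
    then carry no discriminating information and the weights are undefined.
    """
    e = np.asarray(E, dtype=float)
    k = e.size if k_count is None else int(k_count)
    denom = k - e.sum()
    if denom <= _SUM_TOL:
        raise DegeneracyError(
            "all indicator entropies equal 1: the scores carry no "
            "discriminating information, entropy weights are undefined"
        )
    return (1.0 - e) / denom


def assign_signs(
    magnitudes: Sequence[float] | np.ndarray,
    schema: Sequence[Indicator],
    m: ScoreMatrix,
) -> SignedWeightVector:
    """Attach attribute-derived signs to weight magnitudes.

    Positive attribute -> +1; negative -> -1; neutral -> +1 when the raw
    mean score is >= 0.5 and -1 below (the comparison is on the raw score
    scale, equivalently the indicator cloud's Ex; a mean of exactly 0.5
    takes the documented +1 tie-break).
    """
    mags = np.asarray(magnitudes, dtype=float)
    codes = tuple(i.code for i in schema)
    if mags.shape != (len(codes),):
        raise ValueError("magnitudes must align with the schema")
    means = m.scores[list(codes)].to_numpy(dtype=float).mean(axis=0)
    signs = np.empty(len(codes))
    for j, ind in enumerate(schema):
        if ind.attribute == "positive":
            signs[j] = 1.0
        elif ind.attribute == "negative":
            signs[j] = -1.0
        else:
            signs[j] = 1.0 if means[j] >= 0.5 else -1.0
    return SignedWeightVector(codes=codes, magnitudes=mags, signs=signs)


def compute_signed_weights(
    m: ScoreMatrix, schema: Sequence[Indicator]
) -> SignedWeightVector:
    """Full weighting chain for one phase's score matrix.

    Normalizes every column benefit-oriented, computes per-column entropies
    over the expert axis, converts them to magnitudes and attaches signs.
    """
    X = m.scores[[i.code for i in schema]].to_numpy(dtype=float)
    n_experts, n_ind = X.shape
    entropies = np.empty(n_ind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegeneracyWarning)
        for j in range(n_ind):
            Y = normalize_positive(X[:, j])
            entropies[j] = information_entropy(Y, n=n_experts)
    mags = entropy_weights(entropies, k_count=n_ind)
    return assign_signs(mags, schema, m)
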