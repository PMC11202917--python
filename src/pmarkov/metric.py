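"""The EDC-based distance δ_P between parts, and its BIC special case d_P.

For parts Γ_i, Γ_j of a partition P, δ_P(i, j) is the pooled-versus-separate
log-likelihood gap scaled by the normalizer v_n:

    δ_P(i, j) = v_n · [ L(Γ_i) + L(Γ_j) − L(Γ_i ∪ Γ_j) ],
    v_n⁻¹     = w_n · [ γ((|Δ|−1)|P|α) − γ((|Δ|−1)(|P|−1)α) ],

where L(Γ) = Σ_a N(Γ,a)·ln(N(Γ,a)/N(Γ)) and the pooled part uses
N(Γ_ij, a) = N(Γ_i, a) + N(Γ_j, a).  δ_P is a metric on the parts of a good
partition (nonnegative, zero iff the empirical rows coincide, symmetric,
triangle inequality), and merging Γ_i with Γ_j increases the EDC score
exactly when δ_P(i, j) < 1 — the threshold-1 rule driving the agglomerative
estimator.  With γ = identity and w_n = ln n, δ_P is the BIC-based metric
d_P with prefactor 1/(α(|Δ|−1)ln n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .counts import PartCounts
from .criteria import PenaltySpec, loglik_row
from .sequence_io import Alphabet

__all__ = [
    "PairDistance",
    "Normalizer",
    "relative_entropy",
    "normalizer",
    "delta",
    "d_bic",
    "distance_matrix",
]


@dataclass(frozen=True)
class PairDistance:
    part_i: str
    part_j: str
    value: float

    @property
    def merge_favored(self) -> bool:
        """True iff pooling the two parts improves the EDC score (δ < 1)."""
        return self.value < 1.0


@dataclass(frozen=True)
class Normalizer:
    v_n: float


def relative_entropy(p, q) -> float:
    """Kullback–Leibler divergence Σ_a p(a)·ln(p(a)/q(a)), with 0·ln0 = 0.

    Requires q(a) > 0 wherever p(a) > 0.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if np.any((p > 0) & (q == 0)):
        raise ValueError("relative entropy undefined: q has a zero where p is positive")
    return float(xlogy(p, p).sum() - xlogy(p, q).sum())


def normalizer(spec: PenaltySpec, n: int, n_parts: int, alphabet: Alphabet) -> Normalizer:
    """v_n with v_n⁻¹ = w_n·[γ((|Δ|−1)|P|α) − γ((|Δ|−1)(|P|−1)α)].

    |P| is the cardinality of the current partition, before the candidate
    merge.  For γ = identity the bracket collapses to (|Δ|−1)·α regardless
    of |P|.
    """
    if n_parts < 2:
        raise ValueError(f"the normalizer needs at least 2 parts, got {n_parts}")
    g = spec.gamma_fn()
    d = alphabet.size - 1
    bracket = g(d * n_parts * spec.alpha) - g(d * (n_parts - 1) * spec.alpha)
    if bracket <= 0:
        raise ValueError("gamma is not strictly increasing: nonpositive normalizer bracket")
    return Normalizer(1.0 / (spec.w(n) * bracket))


def _pair_bracket(row_i: np.ndarray, row_j: np.ndarray) -> float:
    """L(Γ_i) + L(Γ_j) − L(Γ_i ∪ Γ_j) from raw count rows."""
    return loglik_row(row_i) + loglik_row(row_j) - loglik_row(row_i + row_j)


def delta(
    part_i: str,
    part_j: str,
    part_counts: PartCounts,
    spec: PenaltySpec,
    n: int,
    n_parts: int | None = None,
) -> PairDistance:
    """δ_P between two labeled parts of ``part_counts``.

    ``n_parts`` defaults to the number of parts in ``part_counts``; pass the
    current |P| explicitly when scoring inside an agglomeration step on a
    subset of parts (it matters only for non-identity γ).
    """
    if part_i == part_j:
        raise ValueError("delta is defined for distinct parts only")
    if n_parts is None:
        n_parts = part_counts.n_parts
    i = part_counts.labels.index(part_i)
    j = part_counts.labels.index(part_j)
    row_i, row_j = part_counts.matrix[i], part_counts.matrix[j]
    if row_i.sum() == 0 or row_j.sum() == 0:
        raise ValueError("delta undefined for parts with zero total count")
    v = normalizer(spec, n, n_parts, part_counts.alphabet).v_n
    return PairDistance(part_i, part_j, v * _pair_bracket(row_i, row_j))


def d_bic(
    part_i: str,
    part_j: str,
    part_counts: PartCounts,
    n: int,
    alpha: float = 2.0,
) -> PairDistance:
    """The BIC-based metric d_P: δ_P with γ = identity and w_n = ln n."""
    spec = PenaltySpec(family="log_n", alpha=alpha, gamma="identity")
    return delta(part_i, part_j, part_counts, spec, n, part_counts.n_parts)


def distance_matrix(
    part_counts: PartCounts,
    spec: PenaltySpec,
    n: int,
    n_parts: int | None = None,
) -> pd.DataFrame:
    """Full symmetric δ_P matrix over the parts; diagonal 0 by convention."""
    k = part_counts.n_parts
    if k < 2:
        raise ValueError("a distance matrix needs at least 2 parts")
    if n_parts is None:
        n_parts = k
    v = normalizer(spec, n, n_parts, part_counts.alphabet).v_n
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            val = v * _pair_bracket(part_counts.matrix[i], part_counts.matrix[j])
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=list(part_counts.labels), columns=list(part_counts.labels))
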