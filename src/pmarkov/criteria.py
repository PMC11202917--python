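"""Penalized-likelihood model-selection scores: BIC and its EDC generalization.

For a partition P of the state space, the maximum of the modified
log-likelihood of the sample is

    L(P) = Σ_{a∈Δ, Γ∈P} N_n(Γ, a) · ln( N_n(Γ, a) / N_n(Γ) ),

with the convention 0·ln 0 = 0.  The efficient determination criterion scores

    EDC(P) = L(P) − γ( (|Δ|−1)·|P|·α ) · w_n,

with α > 0 a constant, γ strictly increasing, and {w_n} a positive sequence.
γ = identity and w_n = ln n recover BIC with penalty (|Δ|−1)|P|α·ln n.

Strong consistency of the EDC-selected partition holds for penalty sequences
with w_n/n → 0 and w_n/ln ln n → ∞ (e.g. n^a for a∈(0,1), ln n, n^a·ln n),
and also for the boundary choice w_n = ln ln n itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
from scipy.special import xlogy

from .counts import Partition, PartCounts, TransitionCounts, aggregate_counts
from .sequence_io import Alphabet

__all__ = [
    "PenaltySpec",
    "CriterionValue",
    "loglik_term",
    "penalty_value",
    "edc_score",
    "check_penalty_admissible",
]

_FAMILIES = ("log_n", "loglog_n", "power", "power_log", "custom")


def _gamma_from_name(name: str) -> Callable[[float], float]:
    if name == "identity":
        return lambda x: x
    if name.startswith("power:"):
        k = float(name.split(":", 1)[1])
        if k <= 0:
            raise ValueError(f"gamma power exponent must be > 0, got {k}")
        return lambda x: x**k
    raise ValueError(f"unknown gamma spec {name!r} (use 'identity' or 'power:k')")


@dataclass(frozen=True)
class PenaltySpec:
    """The triple (w_n family, γ, α) parameterizing EDC and the δ_P metric.

    Parameters
    ----------
    family:
        One of ``log_n`` (w_n = ln n), ``loglog_n`` (w_n = ln ln n, requires
        n ≥ 16 so the penalty exceeds 1), ``power`` (w_n = n^a, a∈(0,1)),
        ``power_log`` (w_n = n^a · ln n, a∈(0,1)) or ``custom``.
    alpha:
        The positive constant multiplying the parameter count.
    exponent:
        The ``a`` of the power families.
    gamma:
        ``"identity"`` or ``"power:k"`` — the strictly increasing function
        applied to the scalar (|Δ|−1)·|P|·α.
    custom_w, custom_gamma:
        Callables for ``family="custom"`` / a bespoke γ; ``custom_gamma``
        overrides ``gamma`` and is checked for monotonicity on a grid.
    """

    family: str = "log_n"
    alpha: float = 2.0
    exponent: float | None = None
    gamma: str = "identity"
    custom_w: Callable[[int], float] | None = None
    custom_gamma: Callable[[float], float] | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown penalty family {self.family!r}; choose from {_FAMILIES}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.family in ("power", "power_log"):
            if self.exponent is None or not (0.0 < self.exponent < 1.0):
                raise ValueError(
                    f"family {self.family!r} needs an exponent in (0, 1), got {self.exponent}"
                )
        if self.family == "custom" and self.custom_w is None:
            raise ValueError("family 'custom' requires custom_w")
        if self.custom_gamma is not None:
            grid = np.linspace(0.5, 200.0, 64)
            vals = [self.custom_gamma(x) for x in grid]
            if not all(b > a for a, b in zip(vals, vals[1:])):
                raise ValueError("custom_gamma is not strictly increasing on (0.5, 200)")
        else:
            _gamma_from_name(self.gamma)  # validate eagerly

    def gamma_fn(self) -> Callable[[float], float]:
        if self.custom_gamma is not None:
            return self.custom_gamma
        return _gamma_from_name(self.gamma)

    def w(self, n: int) -> float:
        """The penalty sequence w_n evaluated at sample size n."""
        if n < 3:
            raise ValueError(f"penalty sequences require n >= 3, got n={n}")
        if self.family == "log_n":
            return math.log(n)
        if self.family == "loglog_n":
            if n < 16:
                raise ValueError(f"loglog_n penalty requires n >= 16 (got n={n}) so that w_n > 1")
            return math.log(math.log(n))
        if self.family == "power":
            return float(n) ** self.exponent
        if self.family == "power_log":
            return float(n) ** self.exponent * math.log(n)
        w = float(self.custom_w(n))
        if w <= 0:
            raise ValueError(f"custom w_n must be positive, got {w} at n={n}")
        return w

    def describe(self) -> dict:
        d: dict = {"family": self.family, "alpha": self.alpha, "gamma": self.gamma}
        if self.exponent is not None:
            d["exponent"] = self.exponent
        return d


class CriterionValue(NamedTuple):
    """A penalized score split into its two terms; value = loglik − penalty."""

    loglik: float
    penalty: float
    value: float


def loglik_row(row: np.ndarray) -> float:
    """Σ_a N(Γ,a)·ln(N(Γ,a)/N(Γ)) for one part's count row (0·ln0 = 0)."""
    total = row.sum()
    if total == 0:
        raise ValueError("log-likelihood term undefined for a part with zero total")
    return float(xlogy(row, row).sum() - xlogy(total, total))


def loglik_term(part_counts: PartCounts) -> float:
    """The maximized modified log-likelihood Σ_{a,Γ} N(Γ,a)·ln(N(Γ,a)/N(Γ)).

    Always ≤ 0; equals 0 iff every part's counts sit on a single symbol.
    """
    totals = part_counts.totals
    if np.any(totals == 0):
        zero = [lab for lab, t in zip(part_counts.labels, totals) if t == 0]
        raise ValueError(f"log-likelihood term undefined for zero-count parts: {zero}")
    m = part_counts.matrix
    return float(xlogy(m, m).sum() - xlogy(totals, totals).sum())


def penalty_value(spec: PenaltySpec, n: int, n_parts: int, alphabet: Alphabet) -> float:
    """γ((|Δ|−1)·|P|·α) · w_n."""
    if n_parts < 1:
        raise ValueError(f"n_parts must be >= 1, got {n_parts}")
    g = spec.gamma_fn()
    return g((alphabet.size - 1) * n_parts * spec.alpha) * spec.w(n)


def edc_score(
    counts: TransitionCounts, partition: Partition, spec: PenaltySpec
) -> CriterionValue:
    """EDC(x, P) = loglik(P) − γ((|Δ|−1)|P|α)·w_n.

    With γ = identity and family ``log_n`` this is exactly BIC.
    """
    pc = aggregate_counts(counts, partition)
    ll = loglik_term(pc)
    pen = penalty_value(spec, counts.n, partition.n_parts, counts.state_space.alphabet)
    return CriterionValue(ll, pen, ll - pen)


_PROBE_NS = (10**3, 10**4, 10**6, 10**8, 10**10, 10**12)


def check_penalty_admissible(spec: PenaltySpec) -> str:
    """Classify a penalty sequence for consistency of the selected partition.

    Returns ``"eq9"`` when w_n/n → 0 and w_n/ln ln n → ∞ hold (log_n, power,
    power_log families), ``"loglog_extension"`` for w_n = ln ln n — which
    fails the second limit but is separately proved consistent — and
    ``"inadmissible"`` otherwise.  Custom sequences are probed numerically on
    n = 10^3..10^12; that verdict is heuristic, not a proof.
    """
    if spec.family in ("log_n", "power", "power_log"):
        return "eq9"
    if spec.family == "loglog_n":
        return "loglog_extension"
    ratios_n = [spec.w(n) / n for n in _PROBE_NS]
    ratios_ll = [spec.w(n) / math.log(math.log(n)) for n in _PROBE_NS]
    to_zero = all(b < a for a, b in zip(ratios_n, ratios_n[1:])) and ratios_n[-1] < 1e-2
    to_inf = all(b > a for a, b in zip(ratios_ll, ratios_ll[1:])) and ratios_ll[-1] > 1e2
    return "eq9" if (to_zero and to_inf) else "inadmissible"
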