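"""Order-o state space, transition counting, and partition-level aggregation.

The state space of an order-``o`` chain over alphabet Δ is Ω = Δ^o, the set of
all length-``o`` contexts.  For a sample x_1..x_n the transition count
N_n(s, a) is the number of positions t in (o, n] where the o symbols before t
spell the state s and x_t = a; N_n(s) = Σ_a N_n(s, a).  Given a partition
P = {Γ_1, ..., Γ_|P|} of the states, counts aggregate additively over parts:

    N_n(Γ, a) = Σ_{s∈Γ} N_n(s, a),      N_n(Γ) = Σ_{s∈Γ} N_n(s),

and N_n(Γ, a) / N_n(Γ) is the maximum-likelihood estimate of the shared
transition probability P(a | Γ) whenever N_n(Γ) > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .sequence_io import Alphabet, Sequence

__all__ = [
    "StateSpace",
    "TransitionCounts",
    "Partition",
    "PartCounts",
    "build_state_space",
    "max_admissible_order",
    "count_transitions",
    "aggregate_counts",
    "mle_probs",
]


@dataclass(frozen=True)
class StateSpace:
    """All |Δ|^o length-o states, in lexicographic order of the alphabet."""

    alphabet: Alphabet
    order: int
    states: tuple[str, ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.states)})

    @property
    def n_states(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        return self._index[state]

    def __contains__(self, state: str) -> bool:
        return state in self._index


def build_state_space(alphabet: Alphabet, order: int) -> StateSpace:
    """Enumerate Ω = Δ^order lexicographically in alphabet order."""
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    states = tuple("".join(p) for p in product(alphabet.symbols, repeat=order))
    return StateSpace(alphabet, order, states)


def max_admissible_order(n: int, alphabet: Alphabet) -> int:
    """Upper bound floor(log_|Δ| n) on the memory length for a sample of size n.

    Orders strictly below this bound leave, on average, more than one visit
    per context; fits should use some o < bound.
    """
    if n <= alphabet.size:
        raise ValueError(f"sample size n={n} must exceed the alphabet size {alphabet.size}")
    # guard against float underestimation of exact powers (log_4 16 = 2.0)
    bound = int(math.floor(math.log(n) / math.log(alphabet.size) + 1e-12))
    return bound


@dataclass(frozen=True)
class TransitionCounts:
    """Per-state next-symbol counts for one sequence.

    ``matrix[i, j]`` is N_n(state_i, symbol_j); rows sum to N_n(state_i).
    The first ``order`` symbols only ever serve as initial context, so the
    total count mass is ``n - order`` for an unsplit sequence.
    """

    state_space: StateSpace
    n: int
    matrix: np.ndarray  # (n_states, |Δ|) integer array

    def N(self, state: str, symbol: str) -> int:
        return int(
            self.matrix[self.state_space.index(state), self.state_space.alphabet.index(symbol)]
        )

    def N_state(self, state: str) -> int:
        return int(self.matrix[self.state_space.index(state)].sum())

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def observed_states(self) -> tuple[str, ...]:
        mask = self.matrix.sum(axis=1) > 0
        return tuple(s for s, m in zip(self.state_space.states, mask) if m)

    def unobserved_states(self) -> tuple[str, ...]:
        mask = self.matrix.sum(axis=1) == 0
        return tuple(s for s, m in zip(self.state_space.states, mask) if m)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame: rows = states, columns = symbols + total."""
        df = pd.DataFrame(
            self.matrix,
            index=list(self.state_space.states),
            columns=list(self.state_space.alphabet.symbols),
        )
        df["total"] = df.sum(axis=1)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="state")


def count_transitions(seq: Sequence, state_space: StateSpace) -> TransitionCounts:
    """Tally N_n(s, a) over every position t in (o, n] of the sequence."""
    o = state_space.order
    n = seq.length
    if n <= o:
        raise ValueError(f"sequence {seq.id!r} has length {n} <= order {o}")
    alpha = state_space.alphabet
    codes = np.fromiter((alpha.index(c) for c in seq.symbols), dtype=np.int64, count=n)
    k = alpha.size
    # rolling base-k encoding of the o-symbol context ending at position t-1
    state_idx = np.zeros(n - o, dtype=np.int64)
    for shift in range(o):
        state_idx = state_idx * k + codes[shift : shift + n - o]
    matrix = np.zeros((state_space.n_states, k), dtype=np.int64)
    np.add.at(matrix, (state_idx, codes[o:]), 1)
    return TransitionCounts(state_space, n, matrix)


@dataclass(frozen=True)
class Partition:
    """Labeled, pairwise-disjoint, nonempty groups of states."""

    parts: tuple[frozenset[str], ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if len(self.parts) != len(self.labels):
            raise ValueError("parts and labels differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("part labels are not unique")
        seen: set[str] = set()
        for label, part in zip(self.labels, self.parts):
            if not part:
                raise ValueError(f"part {label!r} is empty")
            overlap = seen & part
            if overlap:
                raise ValueError(f"parts are not disjoint: {sorted(overlap)} repeated")
            seen |= part

    @classmethod
    def from_sets(cls, parts, labels=None) -> "Partition":
        parts = tuple(frozenset(p) for p in parts)
        if labels is None:
            labels = tuple(f"G{i + 1}" for i in range(len(parts)))
        return cls(parts, tuple(labels))

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def domain(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for p in self.parts:
            out |= p
        return out

    def as_set(self) -> frozenset[frozenset[str]]:
        """Label-free view, for comparing partitions."""
        return frozenset(self.parts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "part": list(self.labels),
                "states": [", ".join(sorted(p)) for p in self.parts],
            }
        )


@dataclass(frozen=True)
class PartCounts:
    """Counts aggregated over the parts of a partition."""

    alphabet: Alphabet
    labels: tuple[str, ...]
    matrix: np.ndarray  # (n_parts, |Δ|) integer array

    @property
    def n_parts(self) -> int:
        return len(self.labels)

    @property
    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def N_part(self, label: str, symbol: str) -> int:
        return int(self.matrix[self.labels.index(label), self.alphabet.index(symbol)])

    def N_total(self, label: str) -> int:
        return int(self.matrix[self.labels.index(label)].sum())


def aggregate_counts(counts: TransitionCounts, partition: Partition) -> PartCounts:
    """Sum per-state counts over each part (mass-preserving)."""
    space = counts.state_space
    unknown = partition.domain() - set(space.states)
    if unknown:
        raise ValueError(f"partition references states outside the state space: {sorted(unknown)}")
    matrix = np.zeros((partition.n_parts, space.alphabet.size), dtype=np.int64)
    for i, part in enumerate(partition.parts):
        for s in part:
            matrix[i] += counts.matrix[space.index(s)]
    return PartCounts(space.alphabet, partition.labels, matrix)


def mle_probs(part_counts: PartCounts) -> dict[str, dict[str, float]]:
    """Maximum-likelihood transition rows N(Γ,a)/N(Γ); undefined on empty parts."""
    totals = part_counts.totals
    zero = [lab for lab, t in zip(part_counts.labels, totals) if t == 0]
    if zero:
        raise ValueError(f"MLE undefined for parts with zero total count: {zero}")
    probs = part_counts.matrix / totals[:, None]
    return {
        lab: {a: float(p) for a, p in zip(part_counts.alphabet.symbols, row)}
        for lab, row in zip(part_counts.labels, probs)
    }
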