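"""Agglomerative estimation of the minimal partition of a Markov chain.

States of an order-o chain are equivalent when they share their next-symbol
transition distribution; the partition into equivalence classes (the minimal
partition) is the estimation target.  The estimator starts from the singleton
partition of the observed states — always a good partition — and greedily
merges the pair of parts with the smallest δ_P while that smallest value is
below 1.  Each such merge strictly increases the EDC score, and the stop
condition means no single merge can improve it further.

The greedy scheme is a heuristic for the EDC argmax over all partitions; the
exhaustive argmax is available for tiny state sets as an oracle
(:func:`exhaustive_best_partition`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence as TypingSequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .counts import (
    Partition,
    PartCounts,
    TransitionCounts,
    aggregate_counts,
    build_state_space,
    count_transitions,
    mle_probs,
)
from .criteria import (
    CriterionValue,
    PenaltySpec,
    check_penalty_admissible,
    edc_score,
)
from .metric import normalizer
from .sequence_io import Alphabet, Sequence

__all__ = [
    "MergeStep",
    "PMMModel",
    "initial_partition",
    "agglomerate",
    "fit",
    "exhaustive_best_partition",
    "TieError",
]


@dataclass(frozen=True)
class MergeStep:
    """One accepted merge: the two parts, their δ, and |P| before merging."""

    part_i: tuple[str, ...]
    part_j: tuple[str, ...]
    delta: float
    n_parts_before: int


@dataclass(frozen=True)
class PMMModel:
    """A fitted partition Markov model.

    ``partition`` covers exactly the observed states; parts carry display
    labels G1, G2, ... assigned by decreasing part size, ties by the
    lexicographically smallest member state.  ``probs`` holds the
    per-part maximum-likelihood transition rows.
    """

    alphabet: Alphabet
    order: int
    n: int
    penalty: PenaltySpec
    partition: Partition
    probs: dict[str, dict[str, float]]
    part_totals: dict[str, int]
    scores: CriterionValue
    unobserved_states: tuple[str, ...]
    merge_trace: tuple[MergeStep, ...] = field(default_factory=tuple)

    @property
    def n_parts(self) -> int:
        return self.partition.n_parts

    def to_dict(self) -> dict:
        return {
            "alphabet": list(self.alphabet.symbols),
            "order": self.order,
            "n": self.n,
            "penalty": self.penalty.describe(),
            "parts": [
                {
                    "label": lab,
                    "states": sorted(part),
                    "probs": self.probs[lab],
                    "N_total": self.part_totals[lab],
                }
                for lab, part in zip(self.partition.labels, self.partition.parts)
            ],
            "edc": {
                "loglik": self.scores.loglik,
                "penalty": self.scores.penalty,
                "value": self.scores.value,
            },
            "unobserved_states": list(self.unobserved_states),
            "merge_trace": [
                {
                    "part_i": list(m.part_i),
                    "part_j": list(m.part_j),
                    "delta": m.delta,
                    "n_parts_before": m.n_parts_before,
                }
                for m in self.merge_trace
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def partition_table(self) -> pd.DataFrame:
        """Label → member states, one row per part (largest first)."""
        return self.partition.to_frame()

    def probability_table(self) -> pd.DataFrame:
        """Label → P(a|Γ) for each alphabet symbol."""
        rows = {lab: self.probs[lab] for lab in self.partition.labels}
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "part"
        return df[list(self.alphabet.symbols)]


def initial_partition(counts: TransitionCounts) -> Partition:
    """One singleton part per observed state, labeled by the state string."""
    observed = counts.observed_states()
    if not observed:
        raise ValueError("no observed states: the sequence is shorter than order + 1")
    return Partition.from_sets([{s} for s in observed], labels=observed)


def _display_order(parts: list[frozenset[str]]) -> list[frozenset[str]]:
    return sorted(parts, key=lambda p: (-len(p), min(p)))


def _pair_deltas(rows: np.ndarray, v: float) -> np.ndarray:
    """δ for every unordered pair of the (P×|Δ|) count rows, as a P×P matrix."""
    totals = rows.sum(axis=1)
    L = xlogy(rows, rows).sum(axis=1) - xlogy(totals, totals)
    pooled = rows[:, None, :] + rows[None, :, :]
    pooled_tot = pooled.sum(axis=2)
    L_pool = xlogy(pooled, pooled).sum(axis=2) - xlogy(pooled_tot, pooled_tot)
    return v * (L[:, None] + L[None, :] - L_pool)


def agglomerate(
    counts: TransitionCounts,
    spec: PenaltySpec,
    force: bool = False,
) -> PMMModel:
    """Fit the partition by greedy minimum-δ merging with threshold 1.

    Each round recomputes δ over all current pairs (the normalizer v_n uses
    the current |P|), merges the smallest-δ pair — ties broken by the
    lexicographically smallest (min state of part i, min state of part j) —
    while that δ is below 1, and stops otherwise.  The EDC score strictly
    increases at every accepted merge.

    Penalty sequences that guarantee no consistency are refused unless
    ``force=True``.
    """
    if check_penalty_admissible(spec) == "inadmissible" and not force:
        raise ValueError(
            "penalty sequence is inadmissible for consistent estimation; "
            "pass force=True to fit anyway"
        )
    space = counts.state_space
    observed = counts.observed_states()
    if not observed:
        raise ValueError("no observed states")
    parts: list[frozenset[str]] = [frozenset({s}) for s in observed]
    rows = np.stack([counts.matrix[space.index(s)] for s in observed]).astype(np.int64)
    trace: list[MergeStep] = []

    while len(parts) > 1:
        k = len(parts)
        v = normalizer(spec, counts.n, k, space.alphabet).v_n
        dmat = _pair_deltas(rows, v)
        best: tuple[float, str, str, int, int] | None = None
        for i in range(k):
            mi = min(parts[i])
            for j in range(i + 1, k):
                mj = min(parts[j])
                lo, hi = (mi, mj) if mi < mj else (mj, mi)
                key = (float(dmat[i, j]), lo, hi)
                if best is None or key < best[:3]:
                    best = (*key, i, j)
        d_min, _, _, i, j = best
        if not d_min < 1.0:
            break
        trace.append(
            MergeStep(tuple(sorted(parts[i])), tuple(sorted(parts[j])), d_min, k)
        )
        merged = parts[i] | parts[j]
        merged_row = rows[i] + rows[j]
        keep = [t for t in range(k) if t not in (i, j)]
        parts = [parts[t] for t in keep] + [merged]
        rows = np.vstack([rows[keep], merged_row[None, :]])

    ordered = _display_order(parts)
    labels = tuple(f"G{i + 1}" for i in range(len(ordered)))
    partition = Partition.from_sets(ordered, labels=labels)
    part_counts = aggregate_counts(counts, partition)
    probs = mle_probs(part_counts)
    totals = {lab: int(t) for lab, t in zip(part_counts.labels, part_counts.totals)}
    scores = edc_score(counts, partition, spec)
    return PMMModel(
        alphabet=space.alphabet,
        order=space.order,
        n=counts.n,
        penalty=spec,
        partition=partition,
        probs=probs,
        part_totals=totals,
        scores=scores,
        unobserved_states=counts.unobserved_states(),
        merge_trace=tuple(trace),
    )


def fit(
    seq: Sequence,
    order: int,
    spec: PenaltySpec,
    alphabet: Alphabet | None = None,
    force: bool = False,
) -> PMMModel:
    """Count transitions at the given order and agglomerate: the end-to-end fit."""
    if alphabet is None:
        from .sequence_io import DNA

        alphabet = DNA
    space = build_state_space(alphabet, order)
    counts = count_transitions(seq, space)
    return agglomerate(counts, spec, force=force)


class TieError(ValueError):
    """Raised when the exhaustive EDC search has multiple maximizers."""

    def __init__(self, maximizers):
        self.maximizers = maximizers
        super().__init__(
            f"EDC argmax is not unique: {len(maximizers)} partitions tie for the maximum"
        )


def _set_partitions(items: TypingSequence[str]) -> Iterator[list[list[str]]]:
    """All partitions of a sequence of items (Bell(n) of them)."""
    if len(items) == 1:
        yield [[items[0]]]
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1 :]
        yield [[first]] + smaller


def exhaustive_best_partition(
    counts: TransitionCounts, spec: PenaltySpec, max_states: int = 8
) -> Partition:
    """The EDC argmax over ALL partitions of the observed states.

    Enumerates every set partition (Bell-number growth, hence the guard on
    the number of observed states); serves as the oracle against which the
    greedy agglomeration is validated on tiny instances.  Raises
    :class:`TieError` when the maximum is attained by several partitions.
    """
    observed = counts.observed_states()
    if len(observed) > max_states:
        raise ValueError(
            f"{len(observed)} observed states: exhaustive search is limited to {max_states}"
        )
    if not observed:
        raise ValueError("no observed states")
    best_val = -np.inf
    maximizers: list[Partition] = []
    for blocks in _set_partitions(list(observed)):
        part = Partition.from_sets(
            _display_order([frozenset(b) for b in blocks]),
            labels=[f"G{i + 1}" for i in range(len(blocks))],
        )
        val = edc_score(counts, part, spec).value
        if val > best_val:
            best_val, maximizers = val, [part]
        elif val == best_val:
            maximizers.append(part)
    if len(maximizers) > 1:
        raise TieError(maximizers)
    return maximizers[0]
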