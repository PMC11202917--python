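"""Generative partition Markov models: specification, sampling, recovery runs.

A generative PMM is a partition of the full state space Ω = Δ^o together with
one next-symbol distribution per part; every state in a part shares that row.
The sampler starts from a uniformly random initial context, runs a burn-in to
wash out the initialization, and emits n symbols.  All randomness derives
from a single integer seed, so every draw is bit-reproducible.

``recovery_experiment`` closes the loop: sample from a known minimal PMM,
fit with the agglomerative estimator, and report how often the true
partition is recovered exactly — the empirical face of the strong-consistency
guarantees for admissible penalty sequences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .clustering import PMMModel, agglomerate
from .counts import Partition, StateSpace, build_state_space, count_transitions
from .criteria import PenaltySpec
from .sequence_io import Alphabet, Sequence

__all__ = [
    "PMMSpec",
    "RecoverySummary",
    "random_pmm",
    "sample_sequence",
    "recovery_experiment",
]


def _tv(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())


@dataclass(frozen=True)
class PMMSpec:
    """A generative PMM: partition of all of Ω plus one probability row per part."""

    alphabet: Alphabet
    order: int
    partition: Partition
    rows: dict[str, np.ndarray]  # part label -> probability vector over Δ

    def __post_init__(self):
        space = build_state_space(self.alphabet, self.order)
        if self.partition.domain() != set(space.states):
            raise ValueError("the partition must cover the full state space Ω exactly")
        for lab in self.partition.labels:
            row = np.asarray(self.rows[lab], dtype=float)
            if row.shape != (self.alphabet.size,):
                raise ValueError(f"row for part {lab!r} has wrong length")
            if np.any(row < 0) or abs(row.sum() - 1.0) > 1e-9:
                raise ValueError(f"row for part {lab!r} is not a probability vector")

    @property
    def n_parts(self) -> int:
        return self.partition.n_parts

    def is_minimal(self, tol: float = 0.0) -> bool:
        """True when all part rows are pairwise distinct (beyond ``tol`` in TV)."""
        labs = self.partition.labels
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                if _tv(np.asarray(self.rows[labs[i]]), np.asarray(self.rows[labs[j]])) <= tol:
                    return False
        return True

    def min_separation(self) -> float:
        """Smallest pairwise total-variation distance between part rows."""
        labs = self.partition.labels
        if len(labs) < 2:
            return float("inf")
        return min(
            _tv(np.asarray(self.rows[labs[i]]), np.asarray(self.rows[labs[j]]))
            for i in range(len(labs))
            for j in range(i + 1, len(labs))
        )

    def state_rows(self, space: StateSpace) -> np.ndarray:
        """(|Ω| × |Δ|) matrix mapping each state to its part's row."""
        out = np.zeros((space.n_states, self.alphabet.size))
        for lab, part in zip(self.partition.labels, self.partition.parts):
            row = np.asarray(self.rows[lab], dtype=float)
            for s in part:
                out[space.index(s)] = row
        return out

    def to_dict(self) -> dict:
        return {
            "alphabet": list(self.alphabet.symbols),
            "order": self.order,
            "parts": [
                {
                    "label": lab,
                    "states": sorted(part),
                    "row": [float(x) for x in np.asarray(self.rows[lab])],
                }
                for lab, part in zip(self.partition.labels, self.partition.parts)
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PMMSpec":
        d = json.loads(Path(path).read_text())
        alphabet = Alphabet(d["alphabet"])
        parts = [frozenset(e["states"]) for e in d["parts"]]
        labels = [e["label"] for e in d["parts"]]
        rows = {e["label"]: np.asarray(e["row"], dtype=float) for e in d["parts"]}
        return cls(alphabet, d["order"], Partition.from_sets(parts, labels), rows)


def random_pmm(
    alphabet: Alphabet,
    order: int,
    n_parts: int,
    min_separation: float = 0.2,
    seed: int | None = None,
    max_tries: int = 1000,
) -> PMMSpec:
    """Draw a random minimal PMM with TV-separated part rows.

    States are assigned to parts uniformly at random with every part kept
    nonempty; rows are drawn from a flat Dirichlet and redrawn as a set until
    all pairwise total-variation distances reach ``min_separation``.
    """
    space = build_state_space(alphabet, order)
    if not 1 <= n_parts <= space.n_states:
        raise ValueError(f"n_parts must be in [1, {space.n_states}], got {n_parts}")
    if not 0.0 < min_separation <= 1.0:
        raise ValueError(f"min_separation must be in (0, 1], got {min_separation}")
    rng = np.random.default_rng(seed)

    # each part seeded with one state, remainder assigned uniformly
    states = list(space.states)
    perm = rng.permutation(len(states))
    assignment = np.empty(len(states), dtype=np.int64)
    for k in range(n_parts):
        assignment[perm[k]] = k
    if len(states) > n_parts:
        assignment[perm[n_parts:]] = rng.integers(0, n_parts, size=len(states) - n_parts)

    rows = None
    for _ in range(max_tries):
        cand = rng.dirichlet(np.ones(alphabet.size), size=n_parts)
        ok = all(
            _tv(cand[i], cand[j]) >= min_separation
            for i in range(n_parts)
            for j in range(i + 1, n_parts)
        )
        if ok:
            rows = cand
            break
    if rows is None:
        raise RuntimeError(
            f"could not draw {n_parts} rows with pairwise TV >= {min_separation} "
            f"in {max_tries} tries"
        )
    labels = [f"G{k + 1}" for k in range(n_parts)]
    parts = [frozenset(states[i] for i in np.flatnonzero(assignment == k)) for k in range(n_parts)]
    return PMMSpec(
        alphabet,
        order,
        Partition.from_sets(parts, labels),
        {lab: rows[k] for k, lab in enumerate(labels)},
    )


def sample_sequence(
    spec: PMMSpec,
    n: int,
    seed: int | None = None,
    burn_in: int = 1000,
    id: str = "sim",
) -> Sequence:
    """Sample n symbols from the PMM after a burn-in from a uniform initial context."""
    if n <= spec.order:
        raise ValueError(f"n={n} must exceed the order {spec.order}")
    if burn_in < 0:
        raise ValueError("burn_in must be nonnegative")
    rng = np.random.default_rng(seed)
    space = build_state_space(spec.alphabet, spec.order)
    cum = np.cumsum(spec.state_rows(space), axis=1)
    cum[:, -1] = 1.0  # guard against rounding in the last bin
    k = spec.alphabet.size
    n_states = space.n_states

    state = int(rng.integers(0, n_states))
    steps = burn_in + n
    u = rng.random(steps)
    symbols = np.empty(steps, dtype=np.int64)
    cum_list = cum  # (n_states, k)
    for t in range(steps):
        row = cum_list[state]
        a = int(np.searchsorted(row, u[t], side="right"))
        if a >= k:
            a = k - 1
        symbols[t] = a
        state = (state * k + a) % n_states
    body = "".join(spec.alphabet.symbols[a] for a in symbols[burn_in:])
    return Sequence(id, body)


@dataclass(frozen=True)
class RecoverySummary:
    """Outcome of repeated sample-and-refit runs against a known truth."""

    replicates: int
    exact_matches: int
    part_count_histogram: dict[int, int]
    models: tuple[PMMModel, ...]

    @property
    def fraction_exact(self) -> float:
        return self.exact_matches / self.replicates


def _truth_restricted(spec: PMMSpec, observed: set[str]) -> frozenset[frozenset[str]]:
    out = []
    for part in spec.partition.parts:
        inter = part & observed
        if inter:
            out.append(frozenset(inter))
    return frozenset(out)


def recovery_experiment(
    spec: PMMSpec,
    n: int,
    penalty: PenaltySpec,
    replicates: int,
    seed: int | None = None,
    burn_in: int = 1000,
    keep_models: bool = False,
) -> RecoverySummary:
    """Sample ``replicates`` sequences from ``spec``, fit each, compare to truth.

    The fitted partition counts as an exact recovery when it equals the true
    partition restricted to the states actually observed in that sample.
    Requires a minimal spec (pairwise-distinct rows), otherwise the "truth"
    is not identifiable.
    """
    if not spec.is_minimal():
        raise ValueError("recovery_experiment requires a minimal PMM (distinct part rows)")
    space = build_state_space(spec.alphabet, spec.order)
    root = np.random.default_rng(seed)
    sub_seeds = root.integers(0, 2**31 - 1, size=replicates)
    exact = 0
    hist: dict[int, int] = {}
    models: list[PMMModel] = []
    for r in range(replicates):
        seq = sample_sequence(spec, n, seed=int(sub_seeds[r]), burn_in=burn_in, id=f"rep{r}")
        counts = count_transitions(seq, space)
        model = agglomerate(counts, penalty)
        fitted = model.partition.as_set()
        truth = _truth_restricted(spec, set(counts.observed_states()))
        if fitted == truth:
            exact += 1
        hist[model.n_parts] = hist.get(model.n_parts, 0) + 1
        if keep_models:
            models.append(model)
    return RecoverySummary(replicates, exact, hist, tuple(models))
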