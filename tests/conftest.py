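"""Shared fixtures: random count configurations and tiny FASTA files."""

from __future__ import annotations

import numpy as np
import pytest

from pmarkov import Alphabet, Partition, PartCounts, TransitionCounts, build_state_space

ALPHA2 = Alphabet("ac")
ALPHA4 = Alphabet("acgt")


def random_config(rng: np.random.Generator, n_symbols: int = 4, n_parts: int = 4,
                  max_count: int = 50):
    """A random count configuration on ``n_parts`` parts over ``n_symbols`` symbols.

    Returns ``(counts, partition, part_counts)`` where ``counts`` is a
    TransitionCounts whose observed states are in one-to-one correspondence
    with the parts (each part a singleton), so that part-level quantities can
    be cross-checked against full criterion evaluations on the same numbers.
    Every part row is guaranteed a positive total.
    """
    alphabet = ALPHA2 if n_symbols == 2 else ALPHA4
    order = 3 if n_symbols == 2 else 2  # k^order >= n_parts for n_parts <= 8/16
    space = build_state_space(alphabet, order)
    assert space.n_states >= n_parts
    rows = rng.integers(0, max_count + 1, size=(n_parts, n_symbols))
    for i in range(n_parts):
        while rows[i].sum() == 0:
            rows[i] = rng.integers(0, max_count + 1, size=n_symbols)
    matrix = np.zeros((space.n_states, n_symbols), dtype=np.int64)
    matrix[:n_parts] = rows
    n = int(matrix.sum()) + order
    counts = TransitionCounts(space, n, matrix)
    states = space.states[:n_parts]
    partition = Partition.from_sets([{s} for s in states], labels=states)
    part_counts = PartCounts(alphabet, tuple(states), rows.astype(np.int64))
    return counts, partition, part_counts


@pytest.fixture
def make_config():
    return random_config


@pytest.fixture
def fasta_file(tmp_path):
    """Write a FASTA file from (id, body) pairs; returns the path factory."""

    def _write(records, name="input.fasta", width=None):
        lines = []
        for rid, body in records:
            lines.append(f">{rid}")
            if width:
                lines += [body[i:i + width] for i in range(0, len(body), width)]
            else:
                lines.append(body)
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
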