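"""Shared fixtures and brute-force oracles.

The oracles here deliberately avoid the package's interval arithmetic:
per-bp set arithmetic over toy genomes (<= 100 kb) is the independent route
that every interval operation is checked against.
"""

from __future__ import annotations

import numpy as np
import pytest

from regvar.intervals import GenomicInterval, RegulatoryTrack


def bp_set(intervals) -> set[tuple[str, int]]:
    """Every (chrom, bp) covered by a collection of intervals — the oracle."""
    out: set[tuple[str, int]] = set()
    for iv in intervals:
        out.update((iv.chrom, p) for p in range(iv.start, iv.end))
    return out


def track_bp_set(track: RegulatoryTrack) -> set[tuple[str, int]]:
    return bp_set(track.intervals)


def random_intervals(rng: np.random.Generator, n: int, chroms=("chr1",),
                     chrom_size: int = 10_000, max_len: int = 500):
    """Random toy intervals for oracle-based property tests."""
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, chrom_size - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, chrom_size)))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150618)
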