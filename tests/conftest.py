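"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from msna.pairwise_band import ScoringParams


def naive_occurrences(text: str, pattern: str) -> set[int]:
    """Brute-force string scan: every start position of pattern in text."""
    return {
        i
        for i in range(len(text) - len(pattern) + 1)
        if text[i : i + len(pattern)] == pattern
    }


def enumerate_best_score(a: str, b: str, scoring: ScoringParams) -> int:
    """Exhaustive enumeration of all global alignments (tiny inputs only)."""
    best = -(10**9)

    def rec(i: int, j: int, score: int) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j] and a[i] != "N"
            rec(i + 1, j + 1, score + (scoring.match if hit else scoring.mismatch))
        if i < len(a):
            rec(i + 1, j, score + scoring.gap)
        if j < len(b):
            rec(i, j + 1, score + scoring.gap)

    rec(0, 0, 0)
    return best


def random_dna_py(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture
def scoring() -> ScoringParams:
    return ScoringParams()
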