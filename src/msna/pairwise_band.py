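"""Full and diagonal-banded Needleman-Wunsch global alignment.

The banded variant fills only cells (i, j) with ``|j - i| <= d + k`` where
``d`` is the number of extra diagonals on each side of the main diagonal and
``k = |len(a) - len(b)|`` is the length-difference slack. The cell budget is
therefore at most ``(2d + 2k + 1) * (min(m, n) + 1)`` — linear in the sequence
length when d and k are small, which is the regime of highly similar DNA.

Three band-selection routes are provided:

* ``estimate_band_dotplot`` — an exact word-match dot plot; populated
  diagonals delimit the offset range the optimal path can occupy,
* ``min_band_oracle`` — the smallest d whose banded score equals the full
  score (doubling then bisection; valid because the banded score is
  non-decreasing in d),
* the knowledge base (see :mod:`msna.knowledge_base`), converting a stored
  diagonals percentage via ``d = ceil(pct/100 * max(m, n))``.

``align_banded_adaptive`` doubles the band whenever the traceback path
touches the band boundary — the standard sufficiency heuristic for banded
alignment — so a too-narrow initial band degrades cost, never correctness.

Scoring is linear-gap with integer match/mismatch/gap parameters; ``N``
mismatches everything, including another ``N``. Traceback ties break
diagonal, then up (gap in b), then left (gap in a), so outputs are
deterministic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ScoringParams",
    "BandSpec",
    "PairwiseAlignment",
    "BandInfeasibleError",
    "align_full",
    "align_banded",
    "align_banded_adaptive",
    "estimate_band_dotplot",
    "min_band_oracle",
]

_NEG = -(2**30)

# residue codes: ACGT -> 0..3, U -> 3; N gets a distinct code per side so that
# N never matches anything (not even another N)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
_CODE[ord("U")] = 3


def _encode(s: str, n_code: int) -> np.ndarray:
    raw = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    out = _CODE[raw]
    is_n = raw == ord("N")
    out = out.copy()
    out[is_n] = n_code
    if (out < 0).any():
        bad = s[int(np.argmax(out < 0))]
        raise ValueError(f"illegal alignment character {bad!r}")
    return out


@dataclass(frozen=True)
class ScoringParams:
    """Linear-gap scoring: match reward, mismatch penalty, per-gap penalty."""

    match: int = 1
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap >= 0:
            raise ValueError("gap penalty must be negative")


@dataclass(frozen=True)
class BandSpec:
    """Band geometry: d extra diagonals each side plus length-difference slack k."""

    d: int
    k: int

    def __post_init__(self) -> None:
        if self.d < 0 or self.k < 0:
            raise ValueError("band parameters must be non-negative")

    @property
    def half_width(self) -> int:
        return self.d + self.k


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment plus its score and DP-cell audit count."""

    aligned_a: str
    aligned_b: str
    score: int
    cells_filled: int
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")


class BandInfeasibleError(ValueError):
    """The band excludes every path from the origin to the terminus."""


def rescore(aligned_a: str, aligned_b: str, scoring: ScoringParams) -> int:
    """Score a gapped pair column by column (N never matches)."""
    total = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            raise ValueError("column with gaps in both rows")
        if x == "-" or y == "-":
            total += scoring.gap
        elif x == y and x != "N":
            total += scoring.match
        else:
            total += scoring.mismatch
    return total


@njit(cache=True)
def _nw_full_kernel(a, b, match, mismatch, gap):  # pragma: no cover - numba
    m = a.shape[0]
    n = b.shape[0]
    H = np.empty((m + 1, n + 1), np.int32)
    P = np.empty((m + 1, n + 1), np.int8)
    H[0, 0] = 0
    P[0, 0] = -1
    for j in range(1, n + 1):
        H[0, j] = gap * j
        P[0, j] = 2
    for i in range(1, m + 1):
        H[i, 0] = gap * i
        P[i, 0] = 1
        ai = a[i - 1]
        for j in range(1, n + 1):
            best = H[i - 1, j - 1] + (match if ai == b[j - 1] else mismatch)
            ptr = 0
            s = H[i - 1, j] + gap
            if s > best:
                best = s
                ptr = 1
            s = H[i, j - 1] + gap
            if s > best:
                best = s
                ptr = 2
            H[i, j] = best
            P[i, j] = ptr
    return H, P


@njit(cache=True)
def _nw_banded_kernel(a, b, match, mismatch, gap, bw):  # pragma: no cover - numba
    m = a.shape[0]
    n = b.shape[0]
    W = 2 * bw + 1
    NEG = -(2**30)
    H = np.full((m + 1, W), NEG, np.int32)
    P = np.full((m + 1, W), -1, np.int8)
    cells = 0
    for i in range(m + 1):
        jlo = i - bw
        if jlo < 0:
            jlo = 0
        jhi = i + bw
        if jhi > n:
            jhi = n
        for j in range(jlo, jhi + 1):
            c = j - i + bw
            cells += 1
            if i == 0 and j == 0:
                H[0, c] = 0
                continue
            best = NEG
            ptr = -1
            if i > 0 and j > 0:
                prev = H[i - 1, c]  # diagonal keeps the same offset column
                if prev > NEG // 2:
                    s = prev + (match if a[i - 1] == b[j - 1] else mismatch)
                    if s > best:
                        best = s
                        ptr = 0
            if i > 0 and c + 1 < W:
                prev = H[i - 1, c + 1]
                if prev > NEG // 2:
                    s = prev + gap
                    if s > best:
                        best = s
                        ptr = 1
            if j > 0 and c - 1 >= 0:
                prev = H[i, c - 1]
                if prev > NEG // 2:
                    s = prev + gap
                    if s > best:
                        best = s
                        ptr = 2
            H[i, c] = best
            P[i, c] = ptr
    return H, P, cells


def _traceback_full(a: str, b: str, P: np.ndarray) -> tuple[str, str]:
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


def align_full(a: str, b: str, scoring: ScoringParams = ScoringParams()) -> PairwiseAlignment:
    """Optimal global alignment over the full (m+1) x (n+1) matrix."""
    if not a or not b:
        raise ValueError("both strings must be non-empty")
    ea = _encode(a, 4)
    eb = _encode(b, 5)
    H, P = _nw_full_kernel(ea, eb, scoring.match, scoring.mismatch, scoring.gap)
    ra, rb = _traceback_full(a, b, P)
    return PairwiseAlignment(
        aligned_a=ra,
        aligned_b=rb,
        score=int(H[len(a), len(b)]),
        cells_filled=(len(a) + 1) * (len(b) + 1),
    )


def _traceback_banded(a: str, b: str, P: np.ndarray, bw: int) -> tuple[str, str, bool]:
    """Traceback in offset coordinates; also reports band-boundary contact."""
    i, j = len(a), len(b)
    ra: list[str] = []
    rb: list[str] = []
    touched = False
    while i > 0 or j > 0:
        off = j - i
        if abs(off) == bw and bw < max(len(a), len(b)):
            touched = True
        p = P[i, off + bw]
        if p == 0:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
        elif p == 2:
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
        else:  # pragma: no cover - guarded by feasibility check
            raise BandInfeasibleError("traceback left the band")
    return "".join(reversed(ra)), "".join(reversed(rb)), touched


def align_banded(
    a: str,
    b: str,
    scoring: ScoringParams = ScoringParams(),
    band: BandSpec | None = None,
) -> PairwiseAlignment:
    """Global alignment restricted to the diagonal band ``|j - i| <= d + k``.

    Requires ``band.k == |len(a) - len(b)|`` (the terminus is otherwise
    unreachable). When the band covers the whole matrix this is exactly
    :func:`align_full`. ``meta['band_touched']`` records whether the optimal
    path ran along the band boundary.
    """
    if not a or not b:
        raise ValueError("both strings must be non-empty")
    if band is None:
        raise ValueError("band must be provided")
    k_true = abs(len(a) - len(b))
    if band.k != k_true:
        raise ValueError(f"band.k={band.k} but |len(a)-len(b)|={k_true}")
    bw = band.half_width
    m, n = len(a), len(b)
    if bw >= max(m, n):
        full = align_full(a, b, scoring)
        return PairwiseAlignment(
            aligned_a=full.aligned_a,
            aligned_b=full.aligned_b,
            score=full.score,
            cells_filled=full.cells_filled,
            meta={"band_touched": False, "band_d": band.d},
        )
    ea = _encode(a, 4)
    eb = _encode(b, 5)
    H, P, cells = _nw_banded_kernel(
        ea, eb, scoring.match, scoring.mismatch, scoring.gap, bw
    )
    end_c = n - m + bw
    if end_c < 0 or end_c >= 2 * bw + 1 or H[m, end_c] <= _NEG // 2:
        raise BandInfeasibleError(
            f"band d={band.d}, k={band.k} admits no path for lengths {m}, {n}"
        )
    ra, rb, touched = _traceback_banded(a, b, P, bw)
    return PairwiseAlignment(
        aligned_a=ra,
        aligned_b=rb,
        score=int(H[m, end_c]),
        cells_filled=int(cells),
        meta={"band_touched": touched, "band_d": band.d},
    )


def align_banded_adaptive(
    a: str,
    b: str,
    scoring: ScoringParams = ScoringParams(),
    d0: int = 0,
) -> PairwiseAlignment:
    """Banded alignment with automatic band doubling.

    Starts at ``d0`` and doubles d while the traceback path touches the band
    boundary (or the band is infeasible), stopping once the path lies strictly
    inside the band or the band covers the matrix. ``cells_filled`` accumulates
    over all attempts — retries are honest compute cost.
    """
    k = abs(len(a) - len(b))
    d = max(0, d0)
    total_cells = 0
    attempts = 0
    while True:
        try:
            res = align_banded(a, b, scoring, BandSpec(d=d, k=k))
        except BandInfeasibleError:
            res = None
        attempts += 1
        if res is not None:
            total_cells += res.cells_filled
            if not res.meta.get("band_touched", False):
                return PairwiseAlignment(
                    aligned_a=res.aligned_a,
                    aligned_b=res.aligned_b,
                    score=res.score,
                    cells_filled=total_cells,
                    meta={"band_d": d, "band_attempts": attempts},
                )
        if d + k >= max(len(a), len(b)):
            # band already covers the matrix; res cannot be None here
            assert res is not None
            return PairwiseAlignment(
                aligned_a=res.aligned_a,
                aligned_b=res.aligned_b,
                score=res.score,
                cells_filled=total_cells,
                meta={"band_d": d, "band_attempts": attempts},
            )
        d = max(1, 2 * d)


def estimate_band_dotplot(
    a: str,
    b: str,
    word_size: int = 8,
    min_hits: int = 1,
    margin: int | None = None,
) -> BandSpec:
    """Estimate the band from an exact word-match dot plot.

    Every shared ``word_size``-mer marks diagonal ``j - i``. The returned d is
    the offset that maximizes the cumulative excess of observed hits over the
    expected chance-hit mass, scanning outward from the main diagonal, plus a
    safety ``margin`` (defaults to ``word_size``). Setting ``min_hits`` above
    1 restricts the scan to diagonals carrying at least that many matches
    (falling back to all hit diagonals when none qualifies). With no word
    matches at all the full matrix is returned with a warning.
    """
    if word_size < 1:
        raise ValueError("word_size must be >= 1")
    if not a or not b:
        raise ValueError("both strings must be non-empty")
    if margin is None:
        margin = word_size
    k = abs(len(a) - len(b))
    word_size = min(word_size, len(a), len(b))  # clamp for very short inputs
    words: dict[str, list[int]] = {}
    for j in range(len(b) - word_size + 1):
        words.setdefault(b[j : j + word_size], []).append(j)
    diag_hits: dict[int, int] = {}
    for i in range(len(a) - word_size + 1):
        for j in words.get(a[i : i + word_size], ()):
            diag = j - i
            diag_hits[diag] = diag_hits.get(diag, 0) + 1
    if not diag_hits:
        warnings.warn(
            "no word matches in dot plot; falling back to the full matrix",
            stacklevel=2,
        )
        return BandSpec(d=max(len(a), len(b)), k=k)
    if min_hits > 1 and any(h >= min_hits for h in diag_hits.values()):
        counted = {dg: h for dg, h in diag_hits.items() if h >= min_hits}
    else:
        counted = diag_hits
    # scan outward from the main diagonal and keep the offset that maximizes
    # the cumulative excess of observed hits over the hits two random
    # sequences of these lengths would share by chance; the true alignment
    # path piles hits near the main diagonal while chance hits are spread
    # thinly over all diagonals, so the excess peaks at the edge of the
    # genuinely supported offset range
    expected_total = len(a) * len(b) / 4**word_size
    # the per-diagonal charge is 4x the random-DNA rate: sequences related
    # through a common ancestor share its internal repeats, so off-diagonal
    # hits run well above the random model
    expected_per_diag = 4.0 * expected_total / (len(a) + len(b) + 1)
    # a wider offset is accepted only when its excess clears the previous
    # best by more than the chance-hit scale, so isolated spurious repeats
    # far from the main diagonal cannot drag the band out
    threshold = 3.0 + expected_total**0.5
    max_off = max(abs(dg) for dg in counted)
    best = 0.0
    cum = 0.0
    d_signal = 0
    for off in range(max_off + 1):
        if off == 0:
            cum += counted.get(0, 0) - expected_per_diag
        else:
            cum += (
                counted.get(off, 0)
                + counted.get(-off, 0)
                - 2.0 * expected_per_diag
            )
        if cum > best + threshold:
            best = cum
            d_signal = off
    full = max(len(a), len(b))
    return BandSpec(d=min(d_signal + margin, full), k=k)


def min_band_oracle(
    a: str,
    b: str,
    scoring: ScoringParams = ScoringParams(),
    guard: int = 20_000,
) -> int:
    """Smallest d whose banded score equals the full-matrix optimum.

    Found by doubling then bisection; correct because enlarging d only adds
    admissible paths, so the banded score is non-decreasing in d.
    """
    if max(len(a), len(b)) > guard:
        raise ValueError(f"sequences exceed the {guard} bp full-DP guard")
    target = align_full(a, b, scoring).score
    k = abs(len(a) - len(b))

    def banded_score(d: int) -> int:
        try:
            return align_banded(a, b, scoring, BandSpec(d=d, k=k)).score
        except BandInfeasibleError:
            return _NEG

    if banded_score(0) == target:
        return 0
    lo = 0  # known insufficient
    hi = 1
    while banded_score(hi) != target:
        lo = hi
        hi *= 2
        if hi >= max(len(a), len(b)):
            hi = max(len(a), len(b))
            break
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if banded_score(mid) == target:
            hi = mid
        else:
            lo = mid
    return hi


def diagonals_pct_to_d(pct: float, length: int) -> int:
    """Convert a knowledge-base diagonals percentage into an integer band d."""
    if pct < 0:
        raise ValueError("diagonals percentage must be >= 0")
    return math.ceil(pct / 100.0 * length)
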