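"""The band knowledge base: (length-difference %, identity %) -> diagonals %.

Each entry maps the similarity features of a sequence-pair (or segment-pair)
to the percentage of DP diagonals that sufficed for an optimal banded
alignment at that similarity level. Retrieval is exact-match first, then
nearest neighbor: candidates must lie within ``tolerance_pct`` (default 3
percentage points) of the query on *both* feature axes, and the closest by
unweighted Euclidean distance wins (ties: first-loaded entry). A query with
no candidate is a MISS (``None``), which triggers the dot-plot learning path
in the pipeline; the new observation is then stored with :meth:`learn`.

The package ships a small reference knowledge base (``load_reference_kb``)
trained by the method's authors on simulated mitochondrial-genome data; it
is data, not a derivable artifact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .suffix_index import SimilarityFeatures

__all__ = [
    "KBEntry",
    "KnowledgeBase",
    "load_kb",
    "save_kb",
    "load_reference_kb",
    "select_query_features",
]

_HEADER = ["length_diff_pct", "identity_pct", "diagonals_pct"]
DEFAULT_TOLERANCE_PCT = 3.0


@dataclass(frozen=True)
class KBEntry:
    length_diff_pct: float
    identity_pct: float
    diagonals_pct: float

    def __post_init__(self) -> None:
        for name in ("length_diff_pct", "identity_pct", "diagonals_pct"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite")
        if self.length_diff_pct < 0:
            raise ValueError("length_diff_pct must be >= 0")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct must be in [0, 100]")
        if not (0.0 < self.diagonals_pct <= 100.0):
            raise ValueError("diagonals_pct must be in (0, 100]")

    @property
    def key(self) -> tuple[float, float]:
        return (self.length_diff_pct, self.identity_pct)


@dataclass
class KnowledgeBase:
    entries: list[KBEntry] = field(default_factory=list)
    tolerance_pct: float = DEFAULT_TOLERANCE_PCT

    def __post_init__(self) -> None:
        keys = [e.key for e in self.entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (length_diff_pct, identity_pct) keys")

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, query: SimilarityFeatures) -> Optional[float]:
        """Exact-then-nearest-neighbor retrieval; ``None`` signals a MISS."""
        qd, qi = query.length_diff_pct, query.identity_pct
        for e in self.entries:
            if e.length_diff_pct == qd and e.identity_pct == qi:
                return e.diagonals_pct
        best: Optional[KBEntry] = None
        best_dist = float("inf")
        for e in self.entries:
            dd = abs(e.length_diff_pct - qd)
            di = abs(e.identity_pct - qi)
            if dd > self.tolerance_pct or di > self.tolerance_pct:
                continue
            dist = dd * dd + di * di
            if dist < best_dist:  # strict: first-loaded entry wins ties
                best_dist = dist
                best = e
        return best.diagonals_pct if best is not None else None

    def learn(self, features: SimilarityFeatures, diagonals_pct: float) -> None:
        """Store an observation; an existing exact key is replaced in place."""
        entry = KBEntry(
            length_diff_pct=features.length_diff_pct,
            identity_pct=features.identity_pct,
            diagonals_pct=diagonals_pct,
        )
        for i, e in enumerate(self.entries):
            if e.key == entry.key:
                self.entries[i] = entry
                return
        self.entries.append(entry)


def load_kb(path, tolerance_pct: float = DEFAULT_TOLERANCE_PCT) -> KnowledgeBase:
    """Load a knowledge base from its CSV file (header + one row per entry)."""
    entries = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty knowledge-base file") from None
        if [h.strip() for h in header] != _HEADER:
            raise ValueError(f"{path}: expected header {','.join(_HEADER)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                entries.append(
                    KBEntry(
                        length_diff_pct=float(row[0]),
                        identity_pct=float(row[1]),
                        diagonals_pct=float(row[2]),
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {row!r}: {exc}") from None
    return KnowledgeBase(entries=entries, tolerance_pct=tolerance_pct)


def save_kb(kb: KnowledgeBase, path) -> None:
    """Write the knowledge base as CSV, preserving entry order losslessly."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for e in kb.entries:
            writer.writerow(
                [_fmt(e.length_diff_pct), _fmt(e.identity_pct), _fmt(e.diagonals_pct)]
            )


def _fmt(v: float) -> str:
    return format(v, ".10g")


def load_reference_kb(tolerance_pct: float = DEFAULT_TOLERANCE_PCT) -> KnowledgeBase:
    """The packaged reference knowledge base (simulated mt-genome training data)."""
    ref = resources.files("msna.data").joinpath("table1_kb.csv")
    with resources.as_file(ref) as path:
        return load_kb(path, tolerance_pct=tolerance_pct)


def select_query_features(
    features: Iterable[SimilarityFeatures],
) -> SimilarityFeatures:
    """Worst-case dataset query: max length-difference with min identity.

    The components may come from different pairs; the conservative combination
    guarantees the retrieved band is wide enough for every pairwise alignment
    in the dataset.
    """
    feats = list(features)
    if not feats:
        raise ValueError("need at least one feature pair")
    return SimilarityFeatures(
        identity_pct=min(f.identity_pct for f in feats),
        length_diff_pct=max(f.length_diff_pct for f in feats),
    )
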