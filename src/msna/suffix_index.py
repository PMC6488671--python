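"""Suffix trees and segment-level similarity features.

The tree is built with Ukkonen's online algorithm (amortized linear time,
suffix links, active-point bookkeeping) over a single sequence plus a
terminal sentinel. It supports:

* exact occurrence queries (``find_occurrences``) in time linear in the
  pattern length,
* verbatim segment matching between a sequence pair (``match_segments``),
* a pre-alignment identity estimate based on greedy non-overlapping
  maximal-exact-match coverage (``pair_similarity``) — the feature pair
  (identity %, length-difference %) that keys the band knowledge base.

``build_partitioned`` is the vertically partitioned variant: suffix start
positions are bucketed by their prefix (the map key) and one subtree per
bucket is built independently, mirroring a per-key map task. Query answers
are identical to the monolithic tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

from .seqio import Segment, Sequence

__all__ = [
    "SuffixIndex",
    "PartitionedSuffixIndex",
    "MatchRecord",
    "SimilarityFeatures",
    "build",
    "build_partitioned",
    "find_occurrences",
    "match_segments",
    "pair_similarity",
    "coverage_identity",
]

SENTINEL = "$"
DEFAULT_MIN_SEED = 8


@dataclass(frozen=True)
class SimilarityFeatures:
    """The knowledge-base query key for a sequence (or segment) pair."""

    identity_pct: float
    length_diff_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct must be in [0, 100]")
        if self.length_diff_pct < 0.0:
            raise ValueError("length_diff_pct must be >= 0")


@dataclass(frozen=True)
class MatchRecord:
    """Outcome of searching one segment against the partner sequence's tree."""

    segment: Segment
    matched: bool
    identity_pct: float
    length_diff_pct: float

    def __post_init__(self) -> None:
        if self.matched and self.identity_pct != 100.0:
            raise ValueError("a verbatim-matched segment has identity 100")


class _Node:
    __slots__ = ("children", "start", "end", "link", "suffix_index")

    def __init__(self, start: int, end: Optional[int]):
        self.children: dict[str, _Node] = {}
        self.start = start
        self.end = end  # None while a leaf during construction
        self.link: Optional[_Node] = None
        self.suffix_index = -1


class SuffixIndex:
    """Ukkonen suffix tree over ``text + sentinel``.

    ``text`` is the raw string (no sentinel); queries are answered against it.
    """

    def __init__(self, text: str, sentinel: str = SENTINEL):
        if not text:
            raise ValueError("text must be non-empty")
        if sentinel in text:
            raise ValueError(f"sentinel {sentinel!r} occurs in text")
        self.text = text
        self._t = text + sentinel
        self.root = _Node(-1, -1)
        self._build()
        self._finalize()

    # -- construction -------------------------------------------------------

    def _build(self) -> None:
        t = self._t
        root = self.root
        active_node = root
        active_edge = -1
        active_length = 0
        remainder = 0
        # leaves share a global, growing end; represented by end=None
        self._leaf_end = -1

        for i, ch in enumerate(t):
            self._leaf_end = i
            remainder += 1
            last_new_node: Optional[_Node] = None
            while remainder > 0:
                if active_length == 0:
                    active_edge = i
                edge_ch = t[active_edge]
                nxt = active_node.children.get(edge_ch)
                if nxt is None:
                    active_node.children[edge_ch] = _Node(i, None)
                    if last_new_node is not None:
                        last_new_node.link = active_node
                        last_new_node = None
                else:
                    edge_len = (
                        self._leaf_end + 1 if nxt.end is None else nxt.end
                    ) - nxt.start
                    if active_length >= edge_len:
                        # walk down
                        active_node = nxt
                        active_edge += edge_len
                        active_length -= edge_len
                        continue
                    if t[nxt.start + active_length] == ch:
                        # current character already present: rule 3, stop early
                        active_length += 1
                        if last_new_node is not None and active_node is not root:
                            last_new_node.link = active_node
                            last_new_node = None
                        break
                    # split the edge
                    split = _Node(nxt.start, nxt.start + active_length)
                    active_node.children[edge_ch] = split
                    split.children[ch] = _Node(i, None)
                    nxt.start += active_length
                    split.children[t[nxt.start]] = nxt
                    if last_new_node is not None:
                        last_new_node.link = split
                    last_new_node = split
                remainder -= 1
                if active_node is root and active_length > 0:
                    active_length -= 1
                    active_edge = i - remainder + 1
                elif active_node is not root:
                    active_node = active_node.link if active_node.link else root

    def _finalize(self) -> None:
        """Fix leaf edge ends and assign leaf suffix indices (iterative DFS)."""
        n = len(self._t)
        self.leaf_count = 0
        stack: list[tuple[_Node, int]] = [(self.root, 0)]
        while stack:
            node, depth = stack.pop()
            if node is not self.root:
                if node.end is None:
                    node.end = n
                depth += node.end - node.start
            if not node.children:
                node.suffix_index = n - depth
                self.leaf_count += 1
            else:
                for child in node.children.values():
                    stack.append((child, depth))

    # -- queries ------------------------------------------------------------

    def _walk(self, pattern: str) -> Optional[tuple[_Node, int]]:
        """Descend by ``pattern``; return (node, chars matched on its edge) or None."""
        t = self._t
        node = self.root
        i = 0
        while i < len(pattern):
            child = node.children.get(pattern[i])
            if child is None:
                return None
            edge = t[child.start : child.end]
            j = 0
            while j < len(edge) and i < len(pattern):
                if edge[j] != pattern[i]:
                    return None
                i += 1
                j += 1
            node = child
            if i == len(pattern):
                return node, j
        return None

    def contains(self, pattern: str) -> bool:
        """True iff ``pattern`` occurs in the indexed text."""
        if not pattern:
            raise ValueError("pattern must be non-empty")
        return self._walk(pattern) is not None

    def find_occurrences(self, pattern: str) -> set[int]:
        """All 0-based start positions of ``pattern`` in the text."""
        if not pattern:
            raise ValueError("pattern must be non-empty")
        hit = self._walk(pattern)
        if hit is None:
            return set()
        node, _ = hit
        out: set[int] = set()
        stack = [node]
        while stack:
            v = stack.pop()
            if not v.children:
                out.add(v.suffix_index)
            else:
                stack.extend(v.children.values())
        return out

    def longest_prefix_match(self, query: str, start: int = 0) -> int:
        """Length of the longest prefix of ``query[start:]`` occurring in the text."""
        t = self._t
        node = self.root
        i = start
        n = len(query)
        while i < n:
            child = node.children.get(query[i])
            if child is None:
                break
            edge_start, edge_end = child.start, child.end
            j = edge_start
            while j < edge_end and i < n and t[j] == query[i]:
                i += 1
                j += 1
            if j < edge_end:
                break
            node = child
        return i - start


def build(text: str, sentinel: str = SENTINEL) -> SuffixIndex:
    """Build a suffix tree over ``text`` (Ukkonen's algorithm)."""
    return SuffixIndex(text, sentinel)


class _TrieNode:
    __slots__ = ("children", "positions")

    def __init__(self):
        self.children: dict[str, _TrieNode] = {}
        self.positions: list[int] = []


class PartitionedSuffixIndex:
    """Vertically partitioned suffix index: one independently built subtree per
    prefix key.

    Suffix start positions are grouped by the first ``prefix_length`` characters
    of the suffix (the map key); each bucket's subtree is a compact trie built
    only from that bucket's suffixes. The union of the per-key answers equals
    the monolithic tree's answers for every pattern.
    """

    def __init__(
        self,
        text: str,
        prefix_length: int,
        sentinel: str = SENTINEL,
        map_backend: Optional[Callable] = None,
    ):
        if not text:
            raise ValueError("text must be non-empty")
        if prefix_length < 1:
            raise ValueError("prefix_length must be >= 1")
        if sentinel in text:
            raise ValueError(f"sentinel {sentinel!r} occurs in text")
        self.text = text
        self.prefix_length = prefix_length
        t = text + sentinel
        buckets: dict[str, list[int]] = {}
        for p in range(len(t)):
            buckets.setdefault(t[p : p + prefix_length], []).append(p)
        items = sorted(buckets.items())
        if map_backend is None:
            built = [self._build_bucket(t, starts) for _, starts in items]
        else:
            built = map_backend(_build_bucket_task, [(t, starts) for _, starts in items])
        self.subtrees: dict[str, _TrieNode] = {
            key: root for (key, _), root in zip(items, built)
        }

    @staticmethod
    def _build_bucket(t: str, starts: list[int]) -> _TrieNode:
        return _build_bucket_task((t, starts))

    @property
    def keys(self) -> set[str]:
        return set(self.subtrees)

    def find_occurrences(self, pattern: str) -> set[int]:
        if not pattern:
            raise ValueError("pattern must be non-empty")
        out: set[int] = set()
        for key, root in self.subtrees.items():
            if len(key) >= len(pattern):
                if not key.startswith(pattern):
                    continue
            elif not pattern.startswith(key):
                # bucket key shorter than prefix_length means the whole suffix
                # is the key; a longer pattern cannot be its prefix
                continue
            out |= self._search(root, pattern)
        return out

    def _search(self, root: _TrieNode, pattern: str) -> set[int]:
        t = self.text + SENTINEL
        node = root
        i = 0
        while i < len(pattern):
            child = node.children.get(pattern[i])
            if child is None:
                return set()
            # compact tries here store single-char edges
            i += 1
            node = child
        out: set[int] = set()
        stack = [node]
        while stack:
            v = stack.pop()
            out.update(v.positions)
            stack.extend(v.children.values())
        return out


def _build_bucket_task(args: tuple[str, list[int]]) -> _TrieNode:
    """Build one bucket's subtree from its suffix start positions (a map task)."""
    t, starts = args
    root = _TrieNode()
    for p in starts:
        node = root
        for ch in t[p:]:
            node = node.children.setdefault(ch, _TrieNode())
        node.positions.append(p)
    return root


def build_partitioned(
    text: str,
    prefix_length: int,
    map_backend: Optional[Callable] = None,
) -> PartitionedSuffixIndex:
    """Build the vertically partitioned (per-prefix-key) suffix index."""
    return PartitionedSuffixIndex(text, prefix_length, map_backend=map_backend)


def find_occurrences(index, pattern: str) -> set[int]:
    """Occurrence positions of ``pattern`` (monolithic or partitioned index)."""
    return index.find_occurrences(pattern)


def coverage_identity(index: SuffixIndex, query: str, min_seed: int = DEFAULT_MIN_SEED) -> float:
    """Percent of ``query`` covered by greedy non-overlapping maximal exact
    matches (length >= ``min_seed``) against the indexed text.

    This is the pre-alignment identity estimate: exact shared substrings are
    found in the tree without any dynamic programming.
    """
    if not query:
        raise ValueError("query must be non-empty")
    covered = 0
    i = 0
    n = len(query)
    while i < n:
        length = index.longest_prefix_match(query, i)
        if length >= min_seed:
            covered += length
            i += length
        else:
            i += 1
    return 100.0 * covered / n


def _counterpart_length(partner_len: int, index: int, segment_size: int) -> int:
    """Length of the partner sequence's positional counterpart segment."""
    start = index * segment_size
    if start >= partner_len:
        return 0
    return min(segment_size, partner_len - start)


def match_segments(
    index: SuffixIndex,
    segments: Iterable[Segment],
    partner_len: int,
    segment_size: int,
    min_seed: int = DEFAULT_MIN_SEED,
) -> list[MatchRecord]:
    """Search each segment of A against the tree over B.

    ``matched`` is True iff the segment occurs verbatim anywhere in B. For
    unmatched segments the identity is the exact-match coverage estimate; the
    length-difference feature compares the segment with its positional
    counterpart in B (the final segment therefore carries the whole-sequence
    length surplus).
    """
    records = []
    for seg in segments:
        matched = index.contains(seg.residues)
        if matched:
            identity = 100.0
        else:
            identity = coverage_identity(index, seg.residues, min_seed)
        other = _counterpart_length(partner_len, seg.index, segment_size)
        longest = max(len(seg), other)
        length_diff = 100.0 * abs(len(seg) - other) / longest if longest else 0.0
        records.append(
            MatchRecord(
                segment=seg,
                matched=matched,
                identity_pct=identity,
                length_diff_pct=length_diff,
            )
        )
    return records


def pair_similarity(
    a: Sequence,
    b: Sequence,
    min_seed: int = DEFAULT_MIN_SEED,
) -> SimilarityFeatures:
    """Similarity features of a sequence pair.

    identity % is the exact-match coverage of the shorter sequence against the
    tree of the longer (deterministic symmetric convention); length-difference
    % is ``100 * |len(a) - len(b)| / max(len(a), len(b))``.
    """
    if len(a.residues) >= len(b.residues):
        longer, shorter = a, b
    else:
        longer, shorter = b, a
    index = build(longer.residues)
    identity = coverage_identity(index, shorter.residues, min_seed)
    length_diff = (
        100.0 * abs(len(a) - len(b)) / max(len(a), len(b))
    )
    return SimilarityFeatures(identity_pct=identity, length_diff_pct=length_diff)
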