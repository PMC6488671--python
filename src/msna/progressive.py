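"""Progressive multiple alignment driven by segment matching and a band KB.

Pipeline (``run_msa``):

1. compute similarity features (exact-match coverage identity %, length
   difference %) for every sequence pair;
2. form the dataset-level knowledge-base query — highest length difference
   combined with lowest identity — and look up the diagonals percentage; on a
   MISS, run the dot-plot estimator on the most distant segment pair and
   store the new observation (the online learning path);
3. order all pairs by distance (100 - identity) into the guide order and
   align progressively: the closest pair first, every later sequence against
   the already-aligned representative it is most similar to;
4. pairwise alignments run segment-wise — verbatim-identical positional
   segments are copied with zero DP cells, the rest go through banded
   Needleman-Wunsch at the KB band (doubling on band-boundary contact) — and
   per-segment results are combined in (sequence, segment-index) key order,
   so any map backend yields byte-identical output;
5. gaps the newcomer forces into its representative propagate into every
   existing row ("once a gap, always a gap");
6. one refinement pass re-aligns each row against the profile consensus and
   keeps the result only when its sum-of-pairs score against the remaining
   rows does not decrease.

The run report records per-stage DP cell counts, the KB hit/miss outcome and
the band actually used, which is the compute-cost audit trail the cell-count
scaling analyses rely on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import numpy as np

from ._backend import make_backend, serial_backend
from .knowledge_base import KnowledgeBase, select_query_features
from .pairwise_band import (
    PairwiseAlignment,
    ScoringParams,
    align_banded_adaptive,
    diagonals_pct_to_d,
    estimate_band_dotplot,
)
from .seqio import GAP, Sequence, degap, partition_segments
from .suffix_index import (
    SimilarityFeatures,
    build,
    match_segments,
    pair_similarity,
)

__all__ = [
    "Join",
    "MSAResult",
    "MsaConfig",
    "build_guide_order",
    "align_pair_segmented",
    "merge_into_profile",
    "refine",
    "run_msa",
]


@dataclass(frozen=True)
class Join:
    """One guide-order edge: a sequence-id pair and its distance (100 - identity)."""

    pair: tuple[str, str]
    distance: float


@dataclass
class MSAResult:
    """Equal-length gapped rows keyed by sequence id (insertion order = guide order)."""

    rows: dict[str, str]
    meta: dict = field(default_factory=dict)

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def validate(self, inputs: Optional[Iterable[Sequence]] = None) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if inputs is not None:
            by_id = {s.id: s.residues for s in inputs}
            for sid, row in self.rows.items():
                if degap(row) != by_id.get(sid):
                    raise ValueError(f"row {sid!r} does not degap to its input")


@dataclass
class MsaConfig:
    """Tunables of the progressive pipeline (defaults match the library CLI)."""

    segment_size: int = 1000
    scoring: ScoringParams = ScoringParams()
    kb: Optional[KnowledgeBase] = None
    word_size: int = 8
    min_seed: int = 8
    workers: int = 1
    refine_pass: bool = True


def build_guide_order(
    similarities: dict[tuple[str, str], SimilarityFeatures],
) -> list[Join]:
    """All pairs sorted by ascending distance; ties break lexicographically."""
    ids: set[str] = set()
    for pair in similarities:
        ids.update(pair)
    ordered_ids = sorted(ids)
    norm: dict[tuple[str, str], SimilarityFeatures] = {}
    for (x, y), f in similarities.items():
        norm[(min(x, y), max(x, y))] = f
    for i, x in enumerate(ordered_ids):
        for y in ordered_ids[i + 1 :]:
            if (x, y) not in norm:
                raise ValueError(f"missing similarity features for pair ({x}, {y})")
    joins = [
        Join(pair=pair, distance=100.0 - f.identity_pct) for pair, f in norm.items()
    ]
    joins.sort(key=lambda j: (j.distance, j.pair))
    return joins


def _segment_task(args) -> tuple[str, str, int, int]:
    """Map task for one (sequence name, segment index) key.

    Returns (aligned_a, aligned_b, score, cells_filled). Identical positional
    segments are copied verbatim with zero DP cells; one-sided tails are
    gap-filled; everything else is banded-aligned with adaptive doubling.
    """
    sa, sb, d0, match, mismatch, gap = args
    scoring = ScoringParams(match=match, mismatch=mismatch, gap=gap)
    if sa and sa == sb:
        return (sa, sb, scoring.match * len(sa), 0)
    if not sb:
        return (sa, GAP * len(sa), scoring.gap * len(sa), 0)
    if not sa:
        return (GAP * len(sb), sb, scoring.gap * len(sb), 0)
    res = align_banded_adaptive(sa, sb, scoring, d0)
    return (res.aligned_a, res.aligned_b, res.score, res.cells_filled)


def align_pair_segmented(
    a: Sequence,
    b: Sequence,
    band_pct: float,
    scoring: ScoringParams = ScoringParams(),
    segment_size: int = 1000,
    map_backend: Optional[Callable] = None,
    match_records=None,
) -> PairwiseAlignment:
    """Segment-wise banded pairwise alignment of two sequences.

    The band for each segment pair is ``d = ceil(band_pct/100 * seglen)``
    (doubled automatically on band-boundary contact). ``match_records``
    (from :func:`msna.suffix_index.match_segments`) are only consulted for
    the report; the verbatim fast path is decided by positional equality,
    which is what keeps concatenation exact.
    """
    if map_backend is None:
        map_backend = serial_backend
    segs_a = partition_segments(a, segment_size)
    segs_b = partition_segments(b, segment_size)
    n_keys = max(len(segs_a), len(segs_b))
    tasks = []
    for idx in range(n_keys):
        sa = segs_a[idx].residues if idx < len(segs_a) else ""
        sb = segs_b[idx].residues if idx < len(segs_b) else ""
        d0 = diagonals_pct_to_d(band_pct, max(len(sa), len(sb), 1))
        tasks.append((sa, sb, d0, scoring.match, scoring.mismatch, scoring.gap))
    results = map_backend(_segment_task, tasks)
    aligned_a = "".join(r[0] for r in results)
    aligned_b = "".join(r[1] for r in results)
    matched = sum(1 for t, r in zip(tasks, results) if t[0] and t[0] == t[1])
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=sum(r[2] for r in results),
        cells_filled=sum(r[3] for r in results),
        meta={
            "segments": n_keys,
            "segments_matched": matched,
            "segments_aligned": sum(1 for r in results if r[3] > 0),
            "match_records": match_records,
        },
    )


def merge_into_profile(
    profile: MSAResult,
    representative_id: str,
    newcomer_id: str,
    alignment: PairwiseAlignment,
) -> MSAResult:
    """Add a newcomer row via its pairwise alignment with a profile member.

    ``alignment.aligned_a`` must degap to the representative's original
    sequence. Gaps the pairwise alignment inserts into the representative
    become new columns in every existing row; gaps already present in the
    profile become gaps in the newcomer row.
    """
    if representative_id not in profile.rows:
        raise ValueError(f"representative {representative_id!r} not in profile")
    if newcomer_id in profile.rows:
        raise ValueError(f"newcomer {newcomer_id!r} already aligned")
    prow = profile.rows[representative_id]
    if degap(alignment.aligned_a) != degap(prow):
        raise ValueError("alignment.aligned_a does not degap to the representative")
    others = [sid for sid in profile.rows]
    out: dict[str, list[str]] = {sid: [] for sid in others}
    new_row: list[str] = []
    pi = 0
    for x, y in zip(alignment.aligned_a, alignment.aligned_b):
        if x != GAP:
            while prow[pi] == GAP:  # copy profile-only gap columns first
                for sid in others:
                    out[sid].append(profile.rows[sid][pi])
                new_row.append(GAP)
                pi += 1
            for sid in others:
                out[sid].append(profile.rows[sid][pi])
            new_row.append(y)
            pi += 1
        else:
            for sid in others:  # once a gap, always a gap
                out[sid].append(GAP)
            new_row.append(y)
    while pi < len(prow):  # trailing profile-only gap columns
        for sid in others:
            out[sid].append(profile.rows[sid][pi])
        new_row.append(GAP)
        pi += 1
    rows = {sid: "".join(chars) for sid, chars in out.items()}
    rows[newcomer_id] = "".join(new_row)
    return MSAResult(rows=rows)


def _drop_all_gap_columns(msa: MSAResult) -> MSAResult:
    if not msa.rows:
        return msa
    ids = list(msa.rows)
    keep = [
        c
        for c in range(msa.ncols)
        if any(msa.rows[sid][c] != GAP for sid in ids)
    ]
    rows = {sid: "".join(msa.rows[sid][c] for c in keep) for sid in ids}
    return MSAResult(rows=rows, meta=dict(msa.meta))


def _row_pair_score(r1: str, r2: str, scoring: ScoringParams) -> int:
    """Sum-of-pairs score of two gapped rows (gap-gap columns score zero)."""
    x = np.frombuffer(r1.encode("ascii"), dtype=np.uint8)
    y = np.frombuffer(r2.encode("ascii"), dtype=np.uint8)
    gx = x == ord(GAP)
    gy = y == ord(GAP)
    both = ~gx & ~gy
    one = gx ^ gy
    eq = both & (x == y) & (x != ord("N"))
    return int(
        scoring.match * eq.sum()
        + scoring.mismatch * (both & ~eq).sum()
        + scoring.gap * one.sum()
    )


def _consensus(rows: list[str], cols: list[int]) -> str:
    """Majority residue per column (ties: lexicographically smallest)."""
    out = []
    for c in cols:
        counts = Counter(r[c] for r in rows if r[c] != GAP)
        best = min(counts, key=lambda ch: (-counts[ch], ch))
        out.append(best)
    return "".join(out)


def refine(
    msa: MSAResult,
    scoring: ScoringParams = ScoringParams(),
    order: Optional[list[str]] = None,
    word_size: int = 8,
    band_pct: Optional[float] = None,
) -> MSAResult:
    """One leave-one-out refinement pass.

    All-gap columns are removed; then each row (in guide order) is degapped
    and re-aligned (banded, using the same dataset-level band policy as the
    merges when ``band_pct`` is given, else a per-row dot-plot estimate)
    against the consensus of the remaining rows; the candidate replaces the
    row only if its summed pair score against the remaining rows does not
    decrease. Deterministic; a fixed point for already-consistent alignments.
    ``meta['cells_filled']`` audits the DP cost of the pass.
    """
    msa = _drop_all_gap_columns(msa)
    ids = list(msa.rows)
    if order is None:
        order = ids
    cells = 0
    if len(ids) < 2:
        msa.meta["cells_filled"] = 0
        return msa
    rows = dict(msa.rows)
    for sid in order:
        if sid not in rows:
            continue
        others = [o for o in ids if o != sid]
        ncols = len(rows[sid])
        keep = [
            c for c in range(ncols) if any(rows[o][c] != GAP for o in others)
        ]
        if not keep:
            continue
        cons = _consensus([rows[o] for o in others], keep)
        if len(keep) == ncols and rows[sid] == cons:
            continue  # row already matches the profile everywhere: no DP
        seq = degap(rows[sid])
        if band_pct is not None:
            d0 = diagonals_pct_to_d(band_pct, max(len(seq), len(cons)))
        else:
            d0 = estimate_band_dotplot(seq, cons, word_size=word_size).d
        aln = align_banded_adaptive(seq, cons, scoring, d0)
        cells += aln.cells_filled
        cand: dict[str, list[str]] = {o: [] for o in others}
        cand_row: list[str] = []
        kc = 0
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if y != GAP:
                col = keep[kc]
                kc += 1
                for o in others:
                    cand[o].append(rows[o][col])
                cand_row.append(x)
            else:
                for o in others:
                    cand[o].append(GAP)
                cand_row.append(x)
        cand_rows = {o: "".join(cand[o]) for o in others}
        cand_rows[sid] = "".join(cand_row)
        old_score = sum(_row_pair_score(rows[sid], rows[o], scoring) for o in others)
        new_score = sum(
            _row_pair_score(cand_rows[sid], cand_rows[o], scoring) for o in others
        )
        if new_score >= old_score:
            rows = {i: cand_rows[i] for i in ids}  # original row order
    refined = _drop_all_gap_columns(MSAResult(rows=rows))
    refined.meta["cells_filled"] = cells
    return refined


def _most_distant_segment_pair(
    a: Sequence,
    b: Sequence,
    segment_size: int,
    min_seed: int,
) -> tuple[str, str]:
    """Segment strings of the most distant positional segment pair of (a, b)."""
    index = build(b.residues)
    records = match_segments(
        index, partition_segments(a, segment_size), len(b), segment_size, min_seed
    )
    # band selection concerns the full-size segments that dominate the DP
    # cost; a short tail would make the dot plot degenerate
    full_size = [r for r in records if len(r.segment) == segment_size]
    rec = min(
        full_size or records,
        key=lambda r: (r.identity_pct, -r.length_diff_pct, r.segment.index),
    )
    start = rec.segment.index * segment_size
    counterpart = b.residues[start : start + segment_size]
    if not counterpart:  # partner has no positional segment; use its tail
        counterpart = b.residues[-segment_size:]
    return rec.segment.residues, counterpart


def run_msa(
    sequences: list[Sequence],
    config: MsaConfig = MsaConfig(),
) -> tuple[MSAResult, dict]:
    """Full pipeline: features -> KB band -> guide order -> merges -> refine."""
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    by_id = {s.id: s for s in sequences}
    backend = make_backend(config.workers)

    feats: dict[tuple[str, str], SimilarityFeatures] = {}
    for i, x in enumerate(sequences):
        for y in sequences[i + 1 :]:
            key = (min(x.id, y.id), max(x.id, y.id))
            feats[key] = pair_similarity(x, y, config.min_seed)

    kb = config.kb if config.kb is not None else KnowledgeBase()
    kb_size_before = len(kb)
    query = select_query_features(feats.values())
    band_pct = kb.lookup(query)
    kb_hit = band_pct is not None
    dotlet_runs = 0
    if not kb_hit:
        pair = min(
            feats,
            key=lambda p: (feats[p].identity_pct, -feats[p].length_diff_pct, p),
        )
        sa, sb = _most_distant_segment_pair(
            by_id[pair[0]], by_id[pair[1]], config.segment_size, config.min_seed
        )
        est = estimate_band_dotplot(sa, sb, word_size=config.word_size)
        longest = max(len(sa), len(sb))
        d_est = min(est.d + est.k, longest)
        band_pct = min(100.0, 100.0 * max(d_est, 1) / longest)
        kb.learn(query, band_pct)
        dotlet_runs = 1

    order = build_guide_order(feats)
    profile: Optional[MSAResult] = None
    aligned: set[str] = set()
    merges: list[dict] = []

    def pairwise(rep_id: str, new_id: str) -> PairwiseAlignment:
        return align_pair_segmented(
            by_id[rep_id],
            by_id[new_id],
            band_pct,
            config.scoring,
            config.segment_size,
            map_backend=backend,
        )

    def merge(new_id: str) -> None:
        nonlocal profile
        rep_id = max(
            sorted(aligned),
            key=lambda r: feats[(min(r, new_id), max(r, new_id))].identity_pct,
        )
        pw = pairwise(rep_id, new_id)
        profile = merge_into_profile(profile, rep_id, new_id, pw)
        aligned.add(new_id)
        merges.append(
            {
                "newcomer": new_id,
                "representative": rep_id,
                "cells_filled": pw.cells_filled,
                "segments_matched": pw.meta["segments_matched"],
                "segments_aligned": pw.meta["segments_aligned"],
            }
        )

    for join in order:
        x, y = join.pair
        if profile is None:
            pw = pairwise(x, y)
            profile = MSAResult(rows={x: pw.aligned_a, y: pw.aligned_b})
            aligned.update((x, y))
            merges.append(
                {
                    "newcomer": y,
                    "representative": x,
                    "cells_filled": pw.cells_filled,
                    "segments_matched": pw.meta["segments_matched"],
                    "segments_aligned": pw.meta["segments_aligned"],
                }
            )
        else:
            for sid in sorted((x, y)):
                if sid not in aligned:
                    merge(sid)
    assert profile is not None

    refine_cells = 0
    if config.refine_pass:
        profile = refine(
            profile,
            config.scoring,
            order=list(profile.rows),
            word_size=config.word_size,
            band_pct=band_pct,
        )
        refine_cells = profile.meta.get("cells_filled", 0)
    else:
        profile = _drop_all_gap_columns(profile)

    profile.validate(sequences)
    report = {
        "n_sequences": len(sequences),
        "segment_size": config.segment_size,
        "query_features": {
            "identity_pct": query.identity_pct,
            "length_diff_pct": query.length_diff_pct,
        },
        "kb_hit": kb_hit,
        "dotlet_runs": dotlet_runs,
        "kb_size_before": kb_size_before,
        "kb_size_after": len(kb),
        "band_pct": band_pct,
        "merges": merges,
        "merge_cells_filled": sum(m["cells_filled"] for m in merges),
        "refine_cells_filled": refine_cells,
        "total_cells_filled": sum(m["cells_filled"] for m in merges) + refine_cells,
        "columns": profile.ncols,
    }
    return profile, report
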