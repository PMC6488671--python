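"""Synthetic families of similar DNA sequences with known true alignments.

A family is one base sequence (by default seeded uniform random DNA; any
user-supplied sequence, e.g. a mitochondrial-genome slice, can stand in) and
``n - 1`` siblings derived from it by independent random substitutions and
indels. The mutation trace of every sibling is kept, so the true pairwise
and multiple alignments are known exactly — they are the reference that SP
scoring uses, with no external gold data.

Identity targeting: a substitution always draws one of the three alternative
bases, insertions/deletions are placed uniformly with geometric lengths
(mean ``indel_mean``). The per-pair identity realized in the true alignment
is matched columns / columns with at least one residue, so the substitution
rate is solved from

    identity ~= (1 - del) * (1 - sub) / (1 + ins * indel_mean)

with ``ins = del = 0.05 * (100 - target)/100`` — a correction without which
the realized identity undershoots the target by ~3 points at the low end of
the 20–95 % grid.

``build_training_kb`` reproduces the knowledge-base training protocol: for
each of a series of simulated datasets, take the most distant segment pair,
find the minimal sufficient band with the full-DP oracle, and store the
diagonals percentage against the pair's similarity features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .knowledge_base import KnowledgeBase
from .pairwise_band import ScoringParams, min_band_oracle
from .progressive import MSAResult
from .seqio import GAP, Sequence, partition_segments
from .suffix_index import SimilarityFeatures, build, match_segments

__all__ = [
    "SynthConfig",
    "SynthFamily",
    "mutate",
    "generate_family",
    "build_training_kb",
    "random_dna",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(length: int, rng: np.random.Generator) -> str:
    if length < 1:
        raise ValueError("length must be >= 1")
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings for one family."""

    length: int = 6570
    n_sequences: int = 2
    target_identity_pct: float = 95.0
    sub_rate: float = 0.0405
    ins_rate: float = 0.0025
    del_rate: float = 0.0025
    indel_mean: float = 3.0
    seed: int = 0
    base_sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.n_sequences < 2:
            raise ValueError("need at least two sequences")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.indel_mean < 1.0:
            raise ValueError("indel_mean must be >= 1")

    @classmethod
    def from_target(
        cls,
        target_identity_pct: float,
        length: int = 6570,
        n_sequences: int = 2,
        seed: int = 0,
        with_indels: bool = True,
        indel_mean: float = 3.0,
        base_sequence: Optional[str] = None,
    ) -> "SynthConfig":
        """Solve mutation rates so base-vs-sibling identity hits the target."""
        if not (0.0 <= target_identity_pct <= 100.0):
            raise ValueError("target identity must be in [0, 100]")
        t = target_identity_pct / 100.0
        indel = 0.05 * (1.0 - t) if with_indels else 0.0
        sub = 1.0 - t * (1.0 + indel * indel_mean) / (1.0 - indel) if indel else 1.0 - t
        sub = min(max(sub, 0.0), 1.0)
        return cls(
            length=length,
            n_sequences=n_sequences,
            target_identity_pct=target_identity_pct,
            sub_rate=sub,
            ins_rate=indel,
            del_rate=indel,
            indel_mean=indel_mean,
            seed=seed,
            base_sequence=base_sequence,
        )


@dataclass
class SynthFamily:
    """Sequences plus their true alignment and realized pairwise identities."""

    sequences: list[Sequence]
    truth: MSAResult
    realized_identity: dict[tuple[str, str], float] = field(default_factory=dict)
    config: Optional[SynthConfig] = None


def mutate(
    base: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    indel_mean: float,
    rng: np.random.Generator,
) -> tuple[str, str, str]:
    """Mutate ``base``; return (mutant, aligned_base, aligned_mutant).

    The aligned pair is the true pairwise alignment implied by the edit
    trace: substitutions keep their column, deletions leave a gap in the
    mutant row, insertions add gap columns to the base row. Deterministic
    for a given generator state.
    """
    for name, v in (("sub_rate", sub_rate), ("ins_rate", ins_rate), ("del_rate", del_rate)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    m = len(base)
    draws = rng.random((m, 3))
    out_b: list[str] = []
    out_m: list[str] = []
    alt = "ACGT"
    for p, ch in enumerate(base):
        if ins_rate and draws[p, 0] < ins_rate:
            length = int(rng.geometric(1.0 / indel_mean))
            ins = random_dna(length, rng)
            out_b.append(GAP * length)
            out_m.append(ins)
        if del_rate and draws[p, 1] < del_rate:
            out_b.append(ch)
            out_m.append(GAP)
        elif sub_rate and draws[p, 2] < sub_rate:
            choices = [c for c in alt if c != ch] or list(alt)
            out_b.append(ch)
            out_m.append(choices[int(rng.integers(len(choices)))])
        else:
            out_b.append(ch)
            out_m.append(ch)
    aligned_base = "".join(out_b)
    aligned_mut = "".join(out_m)
    return aligned_mut.replace(GAP, ""), aligned_base, aligned_mut


def _trace_parts(aligned_base: str, aligned_mut: str) -> tuple[list[str], dict[int, str]]:
    """Split a true pairwise alignment into per-base-position characters and
    insertion strings keyed by the base position they precede."""
    per_pos: list[str] = []
    insertions: dict[int, str] = {}
    p = 0
    for x, y in zip(aligned_base, aligned_mut):
        if x == GAP:
            insertions[p] = insertions.get(p, "") + y
        else:
            per_pos.append(y)
            p += 1
    return per_pos, insertions


def generate_family(config: SynthConfig) -> SynthFamily:
    """Generate a family: the base sequence plus mutated siblings, with truth.

    Insertions from different siblings at the same base position get separate
    column blocks ordered by sibling index (a generator convention; they are
    not homologous, so no cross-sibling column sharing is claimed).
    """
    rng = np.random.default_rng(config.seed)
    base = config.base_sequence or random_dna(config.length, rng)
    m = len(base)
    n_mut = config.n_sequences - 1
    traces = []
    sequences = [Sequence("seq0", base)]
    for i in range(n_mut):
        child = np.random.default_rng(int(rng.integers(2**31)))
        mutant, ab, am = mutate(
            base,
            config.sub_rate,
            config.ins_rate,
            config.del_rate,
            config.indel_mean,
            child,
        )
        sequences.append(Sequence(f"seq{i + 1}", mutant))
        traces.append(_trace_parts(ab, am))

    cols: list[list[str]] = []
    n_rows = config.n_sequences
    for p in range(m):
        for mi, (_, insertions) in enumerate(traces):
            ins = insertions.get(p)
            if ins:
                for ch in ins:
                    col = [GAP] * n_rows
                    col[mi + 1] = ch
                    cols.append(col)
        col = [base[p]]
        for per_pos, _ in traces:
            col.append(per_pos[p])
        cols.append(col)

    rows = {
        seq.id: "".join(cols[c][r] for c in range(len(cols)))
        for r, seq in enumerate(sequences)
    }
    truth = MSAResult(rows=rows)
    truth.validate(sequences)

    realized: dict[tuple[str, str], float] = {}
    ids = [s.id for s in sequences]
    arrs = {
        sid: np.frombuffer(rows[sid].encode("ascii"), dtype=np.uint8) for sid in ids
    }
    gap_code = ord(GAP)
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            ax, ay = arrs[x], arrs[y]
            any_res = (ax != gap_code) | (ay != gap_code)
            both = (ax != gap_code) & (ay != gap_code)
            matches = int((both & (ax == ay)).sum())
            realized[(x, y)] = 100.0 * matches / int(any_res.sum())
    return SynthFamily(
        sequences=sequences, truth=truth, realized_identity=realized, config=config
    )


def build_training_kb(
    n_datasets: int = 50,
    identity_range: tuple[float, float] = (50.0, 99.0),
    scoring: ScoringParams = ScoringParams(),
    seed: int = 0,
    length: int = 1200,
    segment_size: int = 300,
    min_seed: int = 8,
    tolerance_pct: float = 3.0,
) -> KnowledgeBase:
    """Build a knowledge base from simulated pairs across an identity range.

    For each dataset the most distant positional segment pair is located via
    the suffix tree, the minimal sufficient band d* is found with the full-DP
    oracle, and ``diagonals_pct = 100 * max(d*, 1) / segment length`` (one
    diagonal is the floor: identical pairs still need the main diagonal) is
    stored under the pair's similarity features.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    lo, hi = identity_range
    kb = KnowledgeBase(tolerance_pct=tolerance_pct)
    for i in range(n_datasets):
        t = lo if n_datasets == 1 else lo + (hi - lo) * i / (n_datasets - 1)
        cfg = SynthConfig.from_target(
            t, length=length, n_sequences=2, seed=seed * n_datasets + i
        )
        fam = generate_family(cfg)
        a, b = fam.sequences
        index = build(b.residues)
        records = match_segments(
            index,
            partition_segments(a, segment_size),
            len(b),
            segment_size,
            min_seed,
        )
        full_size = [r for r in records if len(r.segment) == segment_size]
        rec = min(
            full_size or records,
            key=lambda r: (r.identity_pct, -r.length_diff_pct, r.segment.index),
        )
        start = rec.segment.index * segment_size
        counterpart = b.residues[start : start + segment_size]
        if not counterpart:
            counterpart = b.residues[-segment_size:]
        d_star = min_band_oracle(rec.segment.residues, counterpart, scoring)
        longest = max(len(rec.segment.residues), len(counterpart))
        diagonals_pct = min(100.0, 100.0 * max(d_star, 1) / longest)
        kb.learn(
            SimilarityFeatures(
                identity_pct=rec.identity_pct,
                length_diff_pct=rec.length_diff_pct,
            ),
            diagonals_pct,
        )
    return kb
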