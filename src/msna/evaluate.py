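"""Average sum-of-pairs (SP) scoring against a reference alignment.

For every column *i* of the test alignment, each row pair contributes a pair
value: 2 if the two residues are correctly aligned (the reference pairs the
same two residue instances in one of its columns), 1 if exactly one of the
two rows has a gap, and 0 otherwise. The column score S_i is the pair-value
total normalized by ``2 * nC2`` so it lies in [0, 1]; reference columns are
scored the same way against themselves (every residue pairing there is
correct by construction). The reported accuracy is

    avg SP = sum_i S_i / sum_i S_ri

which equals 1 exactly when the test reproduces every reference residue
pairing (and its gap placement pattern).
"""

from __future__ import annotations

import numpy as np

from .seqio import ALPHABET, GAP

__all__ = ["column_pair_score", "average_sp_score", "sp_report"]

_LEGAL = ALPHABET | {GAP}


def column_pair_score(x: str, y: str, correctly_aligned: bool = True) -> int:
    """Pair value of one column for one row pair.

    ``correctly_aligned`` states whether the reference pairs these two residue
    instances; it is irrelevant when either symbol is a gap.
    """
    if x not in _LEGAL or y not in _LEGAL:
        raise ValueError(f"illegal column symbols ({x!r}, {y!r})")
    if x == GAP and y == GAP:
        return 0
    if x == GAP or y == GAP:
        return 1
    return 2 if correctly_aligned else 0


def _ordinal_matrix(rows: list[str]) -> np.ndarray:
    """Per-row residue ordinals along alignment columns (-1 at gaps)."""
    n = len(rows)
    length = len(rows[0])
    out = np.full((n, length), -1, dtype=np.int64)
    for r, row in enumerate(rows):
        arr = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
        residue = arr != ord(GAP)
        out[r, residue] = np.arange(int(residue.sum()))
    return out


def _column_numerators(test_rows, ref_rows) -> tuple[np.ndarray, np.ndarray]:
    n = len(test_rows)
    ot = _ordinal_matrix(test_rows)
    orf = _ordinal_matrix(ref_rows)
    num_t = np.zeros(ot.shape[1], dtype=np.int64)
    num_r = np.zeros(orf.shape[1], dtype=np.int64)
    for p in range(n):
        for q in range(p + 1, n):
            rp, rq = orf[p], orf[q]
            both_r = (rp >= 0) & (rq >= 0)
            one_r = (rp >= 0) ^ (rq >= 0)
            num_r += 2 * both_r + one_r
            n_res_p = int(rp.max()) + 1 if (rp >= 0).any() else 0
            partner = np.full(n_res_p, -1, dtype=np.int64)
            partner[rp[both_r]] = rq[both_r]
            tp, tq = ot[p], ot[q]
            both_t = (tp >= 0) & (tq >= 0)
            one_t = (tp >= 0) ^ (tq >= 0)
            correct = np.zeros(ot.shape[1], dtype=bool)
            idx = np.flatnonzero(both_t)
            correct[idx] = partner[tp[idx]] == tq[idx]
            num_t += 2 * correct + one_t
    return num_t, num_r


def _check_compatible(test, reference) -> list[str]:
    ids = list(test.rows)
    if set(ids) != set(reference.rows):
        raise ValueError("test and reference alignments hold different sequences")
    for sid in ids:
        if test.rows[sid].replace(GAP, "") != reference.rows[sid].replace(GAP, ""):
            raise ValueError(f"row {sid!r} degaps differently in test and reference")
    return ids


def average_sp_score(test, reference) -> float:
    """Average SP score of ``test`` against ``reference`` (both MSAResult)."""
    ids = _check_compatible(test, reference)
    if len(ids) < 2:
        raise ValueError("SP score needs at least two sequences")
    num_t, num_r = _column_numerators(
        [test.rows[i] for i in ids], [reference.rows[i] for i in ids]
    )
    denom = num_r.sum()
    if denom == 0:
        raise ValueError("reference alignment has no scorable pairs")
    return float(num_t.sum() / denom)


def sp_report(test, reference) -> dict:
    """SP score with column/pair bookkeeping, for the ``msna score`` command."""
    ids = _check_compatible(test, reference)
    n = len(ids)
    score = average_sp_score(test, reference)
    return {
        "avg_sp_score": score,
        "columns": len(test.rows[ids[0]]),
        "reference_columns": len(reference.rows[ids[0]]),
        "pairs": n * (n - 1) // 2,
        "sequences": n,
    }
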