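"""Guide order, segment-wise pairwise alignment, profile merging, refinement,
and the end-to-end progressive pipeline."""

import pytest

from msna.knowledge_base import KnowledgeBase
from msna.pairwise_band import PairwiseAlignment, ScoringParams
from msna.progressive import (
    MsaConfig,
    MSAResult,
    align_pair_segmented,
    build_guide_order,
    merge_into_profile,
    refine,
    run_msa,
)
from msna.seqio import Sequence, degap
from msna.suffix_index import SimilarityFeatures
from msna.synth_data import SynthConfig, build_training_kb, generate_family


def feats(identity, length_diff=0.0):
    return SimilarityFeatures(identity_pct=identity, length_diff_pct=length_diff)


class TestGuideOrder:
    def test_sorted_by_distance(self):
        order = build_guide_order(
            {
                ("A", "B"): feats(99.9),
                ("A", "C"): feats(99.5),
                ("B", "C"): feats(99.7),
            }
        )
        assert [j.pair for j in order] == [("A", "B"), ("B", "C"), ("A", "C")]
        assert [round(j.distance, 4) for j in order] == [0.1, 0.3, 0.5]

    def test_two_sequences_single_join(self):
        order = build_guide_order({("X", "Y"): feats(90.0)})
        assert len(order) == 1 and order[0].pair == ("X", "Y")

    def test_equal_distances_break_lexicographically(self):
        order = build_guide_order(
            {
                ("A", "C"): feats(95.0),
                ("A", "B"): feats(95.0),
                ("B", "C"): feats(95.0),
            }
        )
        assert [j.pair for j in order] == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_missing_pair_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            build_guide_order({("A", "B"): feats(99.0), ("A", "C"): feats(98.0)})


class TestAlignPairSegmented:
    def test_identical_sequences_zero_cells(self):
        a = Sequence("a", "ACGTACGTACGTACGT")
        b = Sequence("b", "ACGTACGTACGTACGT")
        res = align_pair_segmented(a, b, band_pct=1.0, segment_size=4)
        assert res.cells_filled == 0
        assert res.aligned_a == res.aligned_b == a.residues

    def test_single_substitution_touches_one_segment(self, rng):
        from conftest import random_dna_py

        base = random_dna_py(rng, 64)
        mutated = base[:37] + ("A" if base[37] != "A" else "C") + base[38:]
        res = align_pair_segmented(
            Sequence("a", base), Sequence("b", mutated), band_pct=10.0, segment_size=16
        )
        assert res.meta["segments_aligned"] == 1
        assert res.meta["segments_matched"] == 3
        d = 2  # ceil(10% of 16)
        assert res.cells_filled <= 4 * (2 * d + 1) * 17
        assert degap(res.aligned_a) == base and degap(res.aligned_b) == mutated

    def test_backend_parallelism_does_not_change_output(self):
        from msna._backend import ProcessPoolBackend

        cfg = SynthConfig.from_target(95.0, length=400, n_sequences=2, seed=21)
        fam = generate_family(cfg)
        a, b = fam.sequences
        serial = align_pair_segmented(a, b, band_pct=2.0, segment_size=100)
        parallel = align_pair_segmented(
            a, b, band_pct=2.0, segment_size=100,
            map_backend=ProcessPoolBackend(4),
        )
        assert (serial.aligned_a, serial.aligned_b, serial.score) == (
            parallel.aligned_a,
            parallel.aligned_b,
            parallel.score,
        )


class TestMergeIntoProfile:
    def test_merge_identical_sequence(self):
        profile = MSAResult(rows={"a": "AC-GT", "b": "ACTGT"})
        pw = PairwiseAlignment("ACGT", "ACGT", 4, 0)
        merged = merge_into_profile(profile, "a", "c", pw)
        assert merged.ncols == 5
        assert merged.rows["c"] == merged.rows["a"] == "AC-GT"

    def test_new_gap_column_propagates_to_all_rows(self):
        profile = MSAResult(rows={"a": "ACGT", "b": "ACGT"})
        pw = PairwiseAlignment("AC-GT", "ACTGT", 2, 30)
        merged = merge_into_profile(profile, "a", "c", pw)
        assert merged.rows == {"a": "AC-GT", "b": "AC-GT", "c": "ACTGT"}

    def test_profile_gaps_enter_newcomer_row(self):
        profile = MSAResult(rows={"a": "A--CGT", "b": "ATTCGT"})
        pw = PairwiseAlignment("ACGT", "ACGT", 4, 0)
        merged = merge_into_profile(profile, "a", "c", pw)
        assert merged.rows["c"] == "A--CGT"

    def test_unknown_representative_rejected(self):
        with pytest.raises(ValueError, match="not in profile"):
            merge_into_profile(
                MSAResult(rows={"a": "AC"}), "z", "c", PairwiseAlignment("AC", "AC", 2, 0)
            )

    def test_degap_round_trip_after_sequential_merges(self):
        cfg = SynthConfig.from_target(95.0, length=300, n_sequences=11, seed=5)
        fam = generate_family(cfg)
        msa, _ = run_msa(fam.sequences, MsaConfig(segment_size=100, refine_pass=False))
        for seq in fam.sequences:
            assert degap(msa.rows[seq.id]) == seq.residues


class TestRefine:
    def test_all_gap_column_removed(self):
        msa = MSAResult(rows={"a": "AC-GT", "b": "AC-GT"})
        refined = refine(msa)
        assert refined.rows == {"a": "ACGT", "b": "ACGT"}

    def test_identical_rows_fixed_point_zero_cells(self):
        msa = MSAResult(rows={"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "ACGTACGTAC"})
        refined = refine(msa)
        assert refined.rows == msa.rows
        assert refined.meta["cells_filled"] == 0

    def test_sp_score_never_decreases(self):
        from msna.progressive import _row_pair_score

        scoring = ScoringParams()

        def total_sp(m):
            ids = list(m.rows)
            return sum(
                _row_pair_score(m.rows[x], m.rows[y], scoring)
                for i, x in enumerate(ids)
                for y in ids[i + 1 :]
            )

        cfg = SynthConfig.from_target(95.0, length=600, n_sequences=10, seed=9)
        fam = generate_family(cfg)
        unrefined, _ = run_msa(
            fam.sequences, MsaConfig(segment_size=200, refine_pass=False)
        )
        refined = refine(unrefined, scoring, band_pct=2.0)
        assert total_sp(refined) >= total_sp(unrefined)
        for seq in fam.sequences:
            assert degap(refined.rows[seq.id]) == seq.residues


class TestRunMsa:
    def test_two_identical_sequences(self):
        seqs = [Sequence("a", "ACGT" * 10), Sequence("b", "ACGT" * 10)]
        msa, report = run_msa(seqs, MsaConfig(segment_size=16))
        assert msa.rows == {"a": "ACGT" * 10, "b": "ACGT" * 10}
        assert report["total_cells_filled"] == 0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            run_msa([Sequence("a", "ACGT")], MsaConfig())

    def test_trained_kb_hit_skips_dotlet(self):
        kb = build_training_kb(
            n_datasets=30, identity_range=(55.0, 99.0), seed=2, length=800,
            segment_size=200,
        )
        cfg = SynthConfig.from_target(95.0, length=600, n_sequences=5, seed=8)
        fam = generate_family(cfg)
        size_before = len(kb)
        _, report = run_msa(fam.sequences, MsaConfig(segment_size=200, kb=kb))
        assert report["kb_hit"] is True
        assert report["dotlet_runs"] == 0
        assert len(kb) == size_before

    def test_empty_kb_miss_runs_dotlet_once_and_learns(self):
        kb = KnowledgeBase()
        cfg = SynthConfig.from_target(95.0, length=600, n_sequences=5, seed=8)
        fam = generate_family(cfg)
        _, report = run_msa(fam.sequences, MsaConfig(segment_size=200, kb=kb))
        assert report["kb_hit"] is False
        assert report["dotlet_runs"] == 1
        assert report["kb_size_after"] == report["kb_size_before"] + 1 == len(kb)

    def test_deterministic_across_worker_counts(self):
        cfg = SynthConfig.from_target(95.0, length=500, n_sequences=6, seed=11)
        fam = generate_family(cfg)
        serial, rep1 = run_msa(fam.sequences, MsaConfig(segment_size=150, workers=1))
        pooled, rep4 = run_msa(fam.sequences, MsaConfig(segment_size=150, workers=4))
        assert serial.rows == pooled.rows
        assert rep1["total_cells_filled"] == rep4["total_cells_filled"]

    def test_conservation_all_stages(self):
        cfg = SynthConfig.from_target(70.0, length=500, n_sequences=6, seed=14)
        fam = generate_family(cfg)
        msa, _ = run_msa(fam.sequences, MsaConfig(segment_size=200))
        assert len({len(r) for r in msa.rows.values()}) == 1
        for seq in fam.sequences:
            assert degap(msa.rows[seq.id]) == seq.residues

    def test_cost_drops_as_identity_rises(self):
        """The compute-cost trend: kilobase families at 95/70/45 % identity
        cost strictly more DP cells as identity falls, and the full grid is
        non-increasing in rank (Spearman)."""
        from scipy.stats import spearmanr

        cells = []
        grid = (95.0, 70.0, 45.0, 35.0, 20.0)
        for target in grid:
            total = 0
            for seed in (31, 32, 33):
                cfg = SynthConfig.from_target(target, length=1500, n_sequences=8, seed=seed)
                fam = generate_family(cfg)
                _, report = run_msa(fam.sequences, MsaConfig(segment_size=750))
                total += report["total_cells_filled"]
            cells.append(total)
        assert cells[0] < cells[1] < cells[2]
        rho, _ = spearmanr(grid, cells)
        assert rho <= -0.7

    def test_recovers_truth_against_ungapped_baseline(self):
        """On indel-containing families the pipeline's SP accuracy beats the
        naive ungapped stacking baseline."""
        from msna.evaluate import average_sp_score

        cfg = SynthConfig.from_target(95.0, length=800, n_sequences=4, seed=17)
        fam = generate_family(cfg)
        msa, _ = run_msa(fam.sequences, MsaConfig(segment_size=400))
        sp = average_sp_score(msa, fam.truth)
        width = max(len(s.residues) for s in fam.sequences)
        stacked = MSAResult(
            rows={
                s.id: s.residues + "-" * (width - len(s.residues))
                for s in fam.sequences
            }
        )
        sp_stacked = average_sp_score(stacked, fam.truth)
        assert sp > sp_stacked
        assert sp >= 0.9
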