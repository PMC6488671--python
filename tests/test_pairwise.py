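"""Full and banded Needleman-Wunsch, the dot-plot band estimator, and the
minimal-band oracle."""

import warnings

import pytest

from conftest import enumerate_best_score, random_dna_py
from msna.pairwise_band import (
    BandInfeasibleError,
    BandSpec,
    ScoringParams,
    align_banded,
    align_banded_adaptive,
    align_full,
    estimate_band_dotplot,
    min_band_oracle,
    rescore,
)


class TestAlignFull:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 4),
            ("ACGT", "AGT", 1),
            ("AA", "TT", -2),
            ("A", "A", 1),
            ("A", "T", -1),
        ],
    )
    def test_known_scores(self, a, b, expected, scoring):
        res = align_full(a, b, scoring)
        assert res.score == expected
        assert res.cells_filled == (len(a) + 1) * (len(b) + 1)

    def test_matches_exhaustive_enumeration(self, rng, scoring):
        for _ in range(80):
            a = random_dna_py(rng, rng.randint(1, 5))
            b = random_dna_py(rng, rng.randint(1, 5))
            res = align_full(a, b, scoring)
            assert res.score == enumerate_best_score(a, b, scoring)
            assert rescore(res.aligned_a, res.aligned_b, scoring) == res.score

    def test_degap_round_trip_and_no_double_gap(self, rng, scoring):
        for _ in range(30):
            a = random_dna_py(rng, rng.randint(1, 60))
            b = random_dna_py(rng, rng.randint(1, 60))
            res = align_full(a, b, scoring)
            assert res.aligned_a.replace("-", "") == a
            assert res.aligned_b.replace("-", "") == b
            assert all(
                (x, y) != ("-", "-") for x, y in zip(res.aligned_a, res.aligned_b)
            )

    def test_score_symmetry(self, rng, scoring):
        for _ in range(20):
            a = random_dna_py(rng, rng.randint(1, 40))
            b = random_dna_py(rng, rng.randint(1, 40))
            assert align_full(a, b, scoring).score == align_full(b, a, scoring).score

    def test_n_matches_nothing(self, scoring):
        assert align_full("N", "N", scoring).score == -1

    def test_deterministic_traceback(self, scoring):
        r1 = align_full("ACGTACGT", "ACGACGT", scoring)
        r2 = align_full("ACGTACGT", "ACGACGT", scoring)
        assert (r1.aligned_a, r1.aligned_b) == (r2.aligned_a, r2.aligned_b)


class TestAlignBanded:
    def test_identity_main_diagonal_only(self, scoring):
        a = "ACGTACGTAC"
        res = align_banded(a, a, scoring, BandSpec(d=0, k=0))
        assert res.score == align_full(a, a, scoring).score == len(a)
        assert res.cells_filled == len(a) + 1

    def test_band_covering_matrix_equals_full(self, rng, scoring):
        for _ in range(20):
            a = random_dna_py(rng, rng.randint(1, 40))
            b = random_dna_py(rng, rng.randint(1, 40))
            band = BandSpec(d=max(len(a), len(b)), k=abs(len(a) - len(b)))
            banded = align_banded(a, b, scoring, band)
            full = align_full(a, b, scoring)
            assert banded.score == full.score
            assert (banded.aligned_a, banded.aligned_b) == (
                full.aligned_a,
                full.aligned_b,
            )

    def test_wrong_k_rejected(self, scoring):
        with pytest.raises(ValueError, match="band.k"):
            align_banded("ACGT", "AC", scoring, BandSpec(d=1, k=0))

    def test_cells_bound(self, rng, scoring):
        for _ in range(20):
            a = random_dna_py(rng, rng.randint(5, 80))
            b = random_dna_py(rng, rng.randint(5, 80))
            k = abs(len(a) - len(b))
            d = rng.randint(0, 10)
            res = align_banded(a, b, scoring, BandSpec(d=d, k=k))
            assert res.cells_filled <= (2 * (d + k) + 1) * (min(len(a), len(b)) + 1)

    def test_oracle_equivalence_sweep(self, rng, scoring):
        for _ in range(60):
            a = random_dna_py(rng, rng.randint(5, 120))
            b = random_dna_py(rng, rng.randint(5, 120))
            k = abs(len(a) - len(b))
            d_star = min_band_oracle(a, b, scoring)
            full = align_full(a, b, scoring).score
            assert align_banded(a, b, scoring, BandSpec(d=d_star, k=k)).score == full
            if d_star > 0:
                worse = align_banded(
                    a, b, scoring, BandSpec(d=d_star - 1, k=k)
                ).score
                assert worse < full

    def test_score_monotone_in_d(self, rng, scoring):
        for _ in range(15):
            a = random_dna_py(rng, rng.randint(10, 60))
            b = random_dna_py(rng, rng.randint(10, 60))
            k = abs(len(a) - len(b))
            scores = [
                align_banded(a, b, scoring, BandSpec(d=d, k=k)).score
                for d in range(0, max(len(a), len(b)) + 1, 3)
            ]
            assert scores == sorted(scores)


class TestAdaptive:
    def test_valid_alignment_and_score_consistency(self, rng, scoring):
        for _ in range(30):
            a = random_dna_py(rng, rng.randint(5, 100))
            b = random_dna_py(rng, rng.randint(5, 100))
            res = align_banded_adaptive(a, b, scoring, d0=0)
            assert res.aligned_a.replace("-", "") == a
            assert res.aligned_b.replace("-", "") == b
            assert rescore(res.aligned_a, res.aligned_b, scoring) == res.score
            assert res.score <= align_full(a, b, scoring).score

    def test_optimal_in_similar_pair_regime(self, scoring):
        """Seeded with the dot-plot band, adaptive doubling reaches the
        full-matrix optimum for mutated sibling pairs."""
        from msna.synth_data import SynthConfig, generate_family

        for seed in range(8):
            cfg = SynthConfig.from_target(90.0, length=500, n_sequences=2, seed=seed)
            fam = generate_family(cfg)
            a, b = (s.residues for s in fam.sequences)
            d0 = estimate_band_dotplot(a, b).d
            res = align_banded_adaptive(a, b, scoring, d0=d0)
            assert res.score == align_full(a, b, scoring).score

    def test_escalates_when_terminus_sits_on_boundary(self, rng, scoring):
        # unequal lengths with d0=0 put the terminus on the band edge, which
        # always forces at least one doubling; cells accumulate over attempts
        a = random_dna_py(rng, 50)
        b = a[:20] + a[25:]  # 5-base deletion
        res = align_banded_adaptive(a, b, scoring, d0=0)
        assert res.meta["band_attempts"] > 1
        assert res.cells_filled > (2 * 5 + 1) * 46


class TestDotplot:
    def test_self_plot_returns_margin(self, rng):
        x = random_dna_py(rng, 300)
        band = estimate_band_dotplot(x, x, word_size=8)
        assert band.d == 8
        assert band.k == 0

    def test_single_insertion_offset_detected(self, rng):
        x = random_dna_py(rng, 400)
        y = x[:200] + random_dna_py(rng, 10) + x[200:]
        band = estimate_band_dotplot(x, y, word_size=8)
        assert 10 <= band.d <= 10 + 8
        assert band.k == 10

    def test_unrelated_sequences_full_fallback(self, rng):
        a = random_dna_py(rng, 500)
        b = random_dna_py(rng, 500)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            band = estimate_band_dotplot(a, b, word_size=12)
        if band.d == 500:  # no chance 12-mer was shared
            assert any("no word matches" in str(w.message) for w in caught)
        else:  # a rare chance word keeps the band finite but small
            assert band.d <= 500

    def test_deterministic(self, rng):
        x = random_dna_py(rng, 200)
        y = x[:90] + x[100:]
        assert estimate_band_dotplot(x, y) == estimate_band_dotplot(x, y)


class TestMinBandOracle:
    def test_identical_strings_need_no_band(self, scoring):
        assert min_band_oracle("ACGTACGTAC", "ACGTACGTAC", scoring) == 0

    def test_single_deletion(self, scoring):
        d = min_band_oracle("ACGTACGT", "ACGACGT", scoring)
        full = align_full("ACGTACGT", "ACGACGT", scoring).score
        assert align_banded("ACGTACGT", "ACGACGT", scoring, BandSpec(d=d, k=1)).score == full

    def test_guard(self, scoring):
        with pytest.raises(ValueError, match="guard"):
            min_band_oracle("A" * 30, "A" * 30, scoring, guard=10)


def test_linear_cells_for_similar_pairs():
    """Banded cost per base stays bounded while the full matrix grows
    quadratically, for substitution-only 95%-identity pairs."""
    import numpy as np

    from msna.synth_data import SynthConfig, generate_family

    ratios = []
    sizes = (500, 1000, 2000, 4000)
    cells = []
    for m in sizes:
        cfg = SynthConfig.from_target(
            95.0, length=m, n_sequences=2, seed=13, with_indels=False
        )
        fam = generate_family(cfg)
        a, b = (s.residues for s in fam.sequences)
        band = estimate_band_dotplot(a, b, word_size=12)
        res = align_banded(a, b, ScoringParams(), band)
        ratios.append(res.cells_filled / m)
        cells.append(res.cells_filled)
    assert max(ratios) <= 2 * min(ratios)
    slope = np.polyfit(np.log(sizes), np.log(cells), 1)[0]
    assert slope <= 1.2
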