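"""Unanimity test, paired signed-rank / sign tests, per-species Fisher."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from barcodepci import (
    DegenerateTestError,
    SpeciesTable2x2,
    sign_test_compare,
    signed_rank_compare,
    species_fisher_exact,
    unanimity_test,
    unanimity_test_from_flags,
)
from barcodepci.stats import bonferroni


def hypergeom_moments_by_enumeration(A, B, C, D):
    """Exact mean and variance of the top-left cell given all margins."""
    N, r1, c1 = A + B + C + D, A + C, A + B
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    weights = {
        a: math.comb(c1, a) * math.comb(N - c1, r1 - a) for a in range(lo, hi + 1)
    }
    total = sum(weights.values())
    mean = Fraction(sum(a * w for a, w in weights.items()), total)
    var = sum(Fraction((a - mean) ** 2) * w for a, w in weights.items()) / total
    return mean, var


class TestSpeciesTable:
    def test_balanced_table_arithmetic(self):
        t = SpeciesTable2x2("s", 1, 1, 1, 1)
        assert t.expected == 1 and t.observed == 1
        assert t.variance == Fraction(16, 48) == Fraction(1, 3)

    def test_zero_margin_gives_zero_variance(self):
        assert SpeciesTable2x2("s", 2, 3, 0, 0).variance == 0

    def test_variance_matches_hypergeometric_enumeration(self):
        # every table with N <= 8
        for A, B, C, D in itertools.product(range(9), repeat=4):
            if not 2 <= A + B + C + D <= 8:
                continue
            t = SpeciesTable2x2("s", A, B, C, D)
            mean, var = hypergeom_moments_by_enumeration(A, B, C, D)
            assert t.expected == mean
            assert t.variance == var


class TestUnanimityTest:
    def test_single_balanced_species(self):
        res = unanimity_test_from_flags(
            ["s"] * 4, [True, True, False, False], [1, 0, 1, 0]
        )
        assert res.X == 0
        assert res.sigma2 == pytest.approx(1 / 3)
        assert res.Z_uncorrected == 0.0
        assert res.p_one_sided_uncorrected == pytest.approx(0.5)

    def test_all_unanimous_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            unanimity_test_from_flags(
                ["s", "s", "t", "t"], [True, False, True, False], [1, 1, 1, 1]
            )

    def test_zero_margin_species_contribute_nothing(self):
        base = unanimity_test_from_flags(
            ["s"] * 4, [True, True, False, False], [1, 0, 1, 0]
        )
        padded = unanimity_test_from_flags(
            ["s"] * 4 + ["t"] * 3,
            [True, True, False, False, True, False, False],
            [1, 0, 1, 0, 1, 1, 1],  # t has C=D=0
        )
        assert padded.X == base.X and padded.sigma2 == base.sigma2
        assert len(padded.tables) == 2 and padded.n_informative == 1

    def test_label_swap_negates_statistic(self):
        rng = np.random.default_rng(5)
        species = [f"s{i}" for i in range(8) for _ in range(4)]
        flags = list(rng.random(32) < 0.5)
        unanim = list((rng.random(32) < 0.6).astype(int))
        a = unanimity_test_from_flags(species, flags, unanim)
        b = unanimity_test_from_flags(species, [not f for f in flags], unanim)
        assert a.X == pytest.approx(-b.X)
        assert a.sigma2 == pytest.approx(b.sigma2)
        assert a.Z_uncorrected == pytest.approx(-b.Z_uncorrected)

    def test_continuity_correction_moves_toward_zero(self):
        res = unanimity_test_from_flags(
            ["s"] * 6 + ["t"] * 6,
            [True] * 3 + [False] * 3 + [True] * 3 + [False] * 3,
            [1, 1, 1, 0, 0, 1, 1, 1, 0, 0, 0, 1],
        )
        assert res.continuity == pytest.approx(0.5 / math.sqrt(res.sigma2))
        assert abs(res.Z_corrected) <= abs(res.Z_uncorrected)
        assert res.Z_corrected == pytest.approx(
            res.Z_uncorrected - math.copysign(res.continuity, res.Z_uncorrected)
        )
        assert res.p_one_sided == pytest.approx(sps.norm.sf(res.Z_corrected))

    def test_end_to_end_on_tagged_fixture(self, fixture_dataset, fixture_matrix):
        from dataclasses import replace

        from barcodepci import BarcodeDataset

        tagged = BarcodeDataset(
            tuple(
                replace(s, groups=frozenset({"taxonomic"})
                        if s.sample_id in {"s1", "s2", "s5", "y1"}
                        else frozenset())
                for s in fixture_dataset.samples
            ),
            fixture_dataset.alignment_width,
        )
        m = fixture_matrix
        res = unanimity_test(tagged, m, "taxonomic")
        assert {t.species for t in res.tables} == {"S", "Y"}
        assert res.sigma2 > 0


class TestSignedRank:
    def test_identical_pipelines(self):
        pairs = [(f"s{i}", 0.5, 0.5) for i in range(5)]
        assert signed_rank_compare(pairs) == (0, 1.0)

    def test_five_uniform_improvements(self):
        pairs = [(f"s{i}", 0.5, 0.6) for i in range(5)]
        n, p = signed_rank_compare(pairs)
        assert n == 5
        assert p == pytest.approx(2 / 32)  # exact enumeration of 2^5 signs

    def test_matches_scipy_exact_on_tie_free_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(3, 15))
            # distinct magnitudes -> no ties; scipy's exact mode applies
            mags = rng.permutation(np.arange(1, n + 1)) / (n + 1.0)
            signs = rng.choice([-1.0, 1.0], size=n)
            diffs = mags * signs
            pairs = [(f"s{i}", 0.0, d) for i, d in enumerate(diffs)]
            n_nz, p = signed_rank_compare(pairs)
            ref = sps.wilcoxon(diffs, method="exact").pvalue
            assert n_nz == n
            assert p == pytest.approx(float(ref), abs=1e-12)

    def test_tied_magnitudes_enumeration(self):
        # +d, +d, -d: midranks all 2; W+ in {0,2,4,6} with weights 1,3,3,1
        pairs = [("a", 0, 0.1), ("b", 0, 0.1), ("c", 0, -0.1)]
        n, p = signed_rank_compare(pairs)
        assert n == 3
        # W+ = 4, mean 3: |W-3| >= 1 always -> p = 1
        assert p == pytest.approx(1.0)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0.2, 0.5, size=40)
        diffs = diffs[diffs != 0]
        pairs = [(f"s{i}", 0.0, d) for i, d in enumerate(diffs)]
        n, p = signed_rank_compare(pairs)
        ref = sps.wilcoxon(diffs, correction=False, method="approx").pvalue
        assert n == len(diffs)
        assert p == pytest.approx(float(ref))


class TestSignTest:
    def test_five_positive(self):
        pairs = [(f"s{i}", 0.1, 0.2) for i in range(5)]
        assert sign_test_compare(pairs) == (5, pytest.approx(2 / 32))

    def test_balanced_signs(self):
        pairs = [(f"s{i}", 0.0, d) for i, d in enumerate([1, 1, 1, -1, -1, -1])]
        n, p = sign_test_compare(pairs)
        assert n == 6 and p == pytest.approx(1.0)

    def test_zero_differences_dropped(self):
        pairs = [("a", 0.5, 0.5), ("b", 0.2, 0.4)]
        n, p = sign_test_compare(pairs)
        assert n == 1 and p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(1, 12))
            pos = int(rng.integers(0, n + 1))
            diffs = [0.1] * pos + [-0.1] * (n - pos)
            pairs = [(f"s{i}", 0.0, d) for i, d in enumerate(diffs)]
            _, p = sign_test_compare(pairs)
            # exhaustive: P(|#pos - n/2| >= |obs - n/2|) over 2^n sign vectors
            extreme = sum(
                math.comb(n, k)
                for k in range(n + 1)
                if abs(k - n / 2) >= abs(pos - n / 2) - 1e-12
            )
            assert p == pytest.approx(extreme / 2 ** n)


class TestFisherExact:
    def test_two_by_two_example(self):
        assert species_fisher_exact(SpeciesTable2x2("s", 2, 0, 0, 2)) \
            == pytest.approx(1 / 6)

    def test_empty_margin(self):
        assert species_fisher_exact(SpeciesTable2x2("s", 0, 2, 0, 2)) \
            == pytest.approx(1.0)

    def test_matches_table_enumeration(self):
        for A, B, C, D in itertools.product(range(5), repeat=4):
            if A + B + C + D < 2:
                continue
            t = SpeciesTable2x2("s", A, B, C, D)
            N, r1, c1 = t.N, A + C, A + B
            lo, hi = max(0, r1 + c1 - N), min(r1, c1)
            total = sum(math.comb(c1, a) * math.comb(N - c1, r1 - a)
                        for a in range(lo, hi + 1))
            upper = sum(math.comb(c1, a) * math.comb(N - c1, r1 - a)
                        for a in range(max(lo, A), hi + 1))
            assert species_fisher_exact(t) == pytest.approx(upper / total)


def test_bonferroni_caps_at_one():
    assert bonferroni([0.01, 0.3, 0.9]) == pytest.approx([0.03, 0.9, 1.0])
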