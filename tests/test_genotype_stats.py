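"""Hardy-Weinberg tests and pooled allele frequencies."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from snpmeta import GenotypeCounts, hwe_chisq, hwe_exact, pooled_allele_freq


def exact_hwe_brute_force(hom_effect: int, het: int, hom_other: int) -> float:
    """Independent oracle: exact conditional HWE p by full enumeration with
    rational arithmetic. Weight of a heterozygote count h is the number of
    genotype configurations realizing it: multinomial(n; he, h, ho) * 2**h."""
    n = hom_effect + het + hom_other
    n_eff = 2 * hom_effect + het
    n_minor = min(n_eff, 2 * n - n_eff)

    def weight(h: int) -> int:
        hm = (n_minor - h) // 2
        hM = n - h - hm
        return math.comb(n, hm) * math.comb(n - hm, h) * 2**h

    hets = range(n_minor % 2, n_minor + 1, 2)
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    p_obs = Fraction(weights[het], total)
    return float(sum(Fraction(w, total) for w in weights.values()
                     if Fraction(w, total) <= p_obs))


class TestHweChisq:
    # control-arm counts and the published HWE column values they reproduce
    @pytest.mark.parametrize(
        "counts, expected_p",
        [((4, 23, 23), 0.595), ((85, 115, 40), 0.917), ((554, 1330, 726), 0.228)],
    )
    def test_reproduces_published_column(self, counts, expected_p):
        res = hwe_chisq(GenotypeCounts(*counts))
        assert res.p_chisq == pytest.approx(expected_p, abs=0.005)

    def test_perfect_equilibrium(self):
        res = hwe_chisq(GenotypeCounts(25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_chisq == pytest.approx(1.0)

    def test_expected_counts_sum_to_n(self):
        res = hwe_chisq(GenotypeCounts(9, 22, 19))
        assert sum(res.expected) == pytest.approx(50.0)

    def test_monomorphic_flagged(self):
        res = hwe_chisq(GenotypeCounts(0, 0, 77))
        assert res.monomorphic and res.p_chisq == 1.0 and res.chi2 == 0.0

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            hwe_chisq(GenotypeCounts(0, 0, 0))

    @given(st.integers(0, 200), st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=100, derandomize=True)
    def test_allele_relabeling_invariance(self, a, b, c):
        if a + b + c == 0:
            return
        fwd = hwe_chisq(GenotypeCounts(a, b, c))
        rev = hwe_chisq(GenotypeCounts(c, b, a))
        assert fwd.p_chisq == pytest.approx(rev.p_chisq, rel=1e-12)


class TestHweExact:
    def test_modal_configuration(self):
        assert hwe_exact(GenotypeCounts(25, 50, 25)).p_exact == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts",
        [(4, 23, 23), (0, 2, 98), (9, 22, 19), (34, 80, 37), (2, 10, 40)],
    )
    def test_matches_brute_force_enumeration(self, counts):
        res = hwe_exact(GenotypeCounts(*counts))
        assert res.p_exact == pytest.approx(exact_hwe_brute_force(*counts), rel=1e-9)

    def test_two_point_enumeration_by_hand(self):
        # (0, 2, 98): 2 effect alleles among 200; het in {0, 2};
        # weights C(100,1)*1 (het=0: one eff-hom) vs C(100,2)... het=2: 2 het
        # carriers among 100 persons with 2^2 phase labelings over ordered
        # alleles -> conditional P(het=2) = 2*100*99 / (100 + 2*100*99) -- the
        # observed (modal) configuration, so p = 1.
        res = hwe_exact(GenotypeCounts(0, 2, 98))
        assert res.p_exact == pytest.approx(1.0)
        flipped = hwe_exact(GenotypeCounts(1, 0, 99))
        assert flipped.p_exact == pytest.approx(
            exact_hwe_brute_force(1, 0, 99), rel=1e-9)
        assert flipped.p_exact < 1.0

    def test_tracks_chisq_on_large_control_arms(self, table1_all):
        """The exact conditional p sits close to (and, near the null, slightly
        above) the chi-square p on large arms; the two never disagree about
        the 0.05 screening decision on the packaged data."""
        for record in table1_all:
            if record.controls.total() < 200:
                continue
            p_exact = hwe_exact(record.controls).p_exact
            p_chisq = hwe_chisq(record.controls).p_chisq
            assert p_exact == pytest.approx(p_chisq, abs=0.10)
            assert (p_exact < 0.05) == (p_chisq < 0.05)


class TestPooledAlleleFrequency:
    def test_single_study_hand_count(self, suleiman):
        from snpmeta import StudySet
        af = pooled_allele_freq(StudySet((suleiman,)), "cases")
        assert (af.effect_count, af.total_alleles) == (40, 100)
        assert af.freq == pytest.approx(0.400)

    @pytest.mark.parametrize(
        "variant, arm, expected",
        [
            ("rs1333049", "cases", 0.521), ("rs1333049", "controls", 0.489),
            ("rs4977574", "cases", 0.537), ("rs4977574", "controls", 0.483),
        ],
    )
    def test_reproduces_published_frequencies(self, table1_all, variant, arm, expected):
        af = pooled_allele_freq(table1_all.filter(variant=variant), arm)
        assert af.freq == pytest.approx(expected, abs=0.01)

    def test_union_equals_weighted_partition(self, rs1333049):
        whole = pooled_allele_freq(rs1333049, "controls")
        parts = [pooled_allele_freq(rs1333049.filter(ethnicity=e), "controls")
                 for e in ("West Asian", "East Asian", "Caucasian", "African")]
        assert sum(p.effect_count for p in parts) == whole.effect_count
        assert sum(p.total_alleles for p in parts) == whole.total_alleles

    def test_empty_set_rejected(self):
        from snpmeta import StudySet
        with pytest.raises(ValueError):
            pooled_allele_freq(StudySet(()), "cases")

    def test_mixed_variants_rejected(self, table1_all):
        with pytest.raises(ValueError, match="variant"):
            pooled_allele_freq(table1_all, "cases")
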