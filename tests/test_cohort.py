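"""Cohort statistics: carrier summaries, CMH, HWE, LD, Meff."""

import numpy as np
import pytest

from conftest import oracle_hwe_exact
from ptcrescue.cohort import (
    CMHResult,
    GenotypeCounts,
    StratumTable,
    UndefinedStatisticError,
    carrier_stats,
    cmh,
    crude_or,
    hwe_exact,
    ld_pair,
    meff_cutoff,
    tabulate_cohort,
)
from ptcrescue.simulate import simulate_cohort


class TestCarrierStats:
    @pytest.mark.parametrize(
        "carriers,total,pct",
        [(28, 928, 3.02), (6, 980, 0.61), (0, 100, 0.0)],
    )
    def test_printed_percentages(self, carriers, total, pct):
        got_pct, frac = carrier_stats(carriers, total)
        assert got_pct == pytest.approx(pct)
        assert frac == pytest.approx(carriers / total)

    def test_half_up_rounding(self):
        # 1/16 = 6.25% exactly; half-up keeps the 5 -> 6.25, and 0.125 -> 0.13
        assert carrier_stats(1, 16)[0] == 6.25
        assert carrier_stats(1, 800)[0] == 0.13

    def test_zero_total_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            carrier_stats(0, 0)


class TestCrudeOR:
    def test_study_scale_table(self):
        res = crude_or(StratumTable("all", 28, 900, 6, 974))
        assert res.odds_ratio == pytest.approx(28 * 974 / (900 * 6), rel=1e-12)
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert not res.corrected

    def test_unit_table(self):
        assert crude_or(StratumTable("u", 1, 1, 1, 1)).odds_ratio == 1.0

    def test_zero_cell_haldane_correction(self):
        res = crude_or(StratumTable("z", 0, 100, 5, 95))
        assert res.corrected and res.odds_ratio < 1

    def test_empty_margin_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            crude_or(StratumTable("m", 0, 0, 5, 95))


class TestCMH:
    def test_single_stratum_equals_crude_or(self):
        t = StratumTable("s", 10, 90, 5, 95)
        assert cmh([t]).or_mh == pytest.approx(crude_or(t).odds_ratio, rel=1e-12)

    def test_duplicated_stratum_leaves_or_unchanged(self):
        t = StratumTable("s", 10, 90, 5, 95)
        assert cmh([t] * 4).or_mh == pytest.approx(cmh([t]).or_mh, rel=1e-12)

    def test_matches_hand_computed_sum_formula(self):
        strata = [StratumTable("a", 10, 90, 5, 95), StratumTable("b", 4, 46, 2, 48)]
        num = sum(t.a * t.d / t.n for t in strata)
        den = sum(t.b * t.c / t.n for t in strata)
        res = cmh(strata)
        assert res.or_mh == pytest.approx(num / den, rel=1e-12)
        assert res.ci_low < res.or_mh < res.ci_high
        assert 0 < res.p < 1

    def test_stratum_permutation_invariance(self):
        strata = [
            StratumTable("a", 12, 388, 3, 397),
            StratumTable("b", 7, 143, 2, 298),
            StratumTable("c", 5, 155, 1, 294),
        ]
        forward = cmh(strata)
        backward = cmh(strata[::-1])
        assert forward.or_mh == pytest.approx(backward.or_mh, rel=1e-12)
        assert forward.p == pytest.approx(backward.p, rel=1e-12)

    def test_degenerate_strata_dropped_not_fatal(self):
        strata = [StratumTable("ok", 10, 90, 5, 95),
                  StratumTable("empty_controls", 5, 3, 0, 0)]
        res = cmh(strata)
        assert res.n_strata_used == 1 and res.n_strata_dropped == 1

    def test_ci_coverage_at_true_or_five(self):
        """100 simulated 3-stratum cohorts (n=1000/stratum) at true OR 5:
        the 95% CI covers the truth in at least 90 replicates."""
        p_ctl = 0.02
        odds_pat = 5 * p_ctl / (1 - p_ctl)
        p_pat = odds_pat / (1 + odds_pat)
        strata_spec = [{"label": s, "n_pat": 500, "n_ctl": 500} for s in "ABC"]
        covered = 0
        for seed in range(1, 101):
            df, meta = simulate_cohort(strata_spec, p_pat, p_ctl, seed)
            res = cmh(tabulate_cohort(df))
            if res.ci_low <= 5.0 <= res.ci_high:
                covered += 1
        assert covered >= 90


class TestHWE:
    def test_small_symmetric_case_is_one(self):
        assert hwe_exact(GenotypeCounts(1, 2, 1)) == pytest.approx(1.0)

    def test_monomorphic_is_one(self):
        assert hwe_exact(GenotypeCounts(100, 0, 0)) == 1.0

    def test_all_heterozygote_fails_qc_gate(self):
        # large all-het sample is wildly out of equilibrium: p < 0.001
        assert hwe_exact(GenotypeCounts(0, 100, 0)) < 0.001

    def test_matches_rational_enumeration_oracle(self):
        """120 random genotype tables (total <= 200): exact agreement with an
        independent Fraction-arithmetic enumeration."""
        rng = np.random.default_rng(3)
        for _ in range(120):
            n = int(rng.integers(2, 201))
            n_aa = int(rng.integers(0, n + 1))
            n_ab = int(rng.integers(0, n - n_aa + 1))
            n_bb = n - n_aa - n_ab
            g = GenotypeCounts(n_aa, n_ab, n_bb)
            assert hwe_exact(g) == pytest.approx(
                oracle_hwe_exact(n_aa, n_ab, n_bb), rel=1e-9, abs=1e-12
            )


class TestLD:
    def test_perfect_coupling(self):
        res = ld_pair(phased_counts=(50, 0, 0, 50))
        assert res.d_prime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_equilibrium_independence(self):
        res = ld_pair(phased_counts=(25, 25, 25, 25))
        assert res.d_prime == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            ld_pair(phased_counts=(100, 0, 100, 0))

    @staticmethod
    def _collapse(haps: np.ndarray) -> np.ndarray:
        """Pair phased haplotypes into unphased joint genotype counts."""
        table = np.zeros((3, 3))
        # hap index -> (allele at locus 1, allele at locus 2); 0 = A/B
        alleles = {0: (0, 0), 1: (0, 1), 2: (1, 0), 3: (1, 1)}
        for h1, h2 in haps.reshape(-1, 2):
            a1, b1 = alleles[h1]
            a2, b2 = alleles[h2]
            table[a1 + a2, b1 + b2] += 1
        return table

    def test_em_recovers_cis_only_phased_frequencies_exactly(self):
        """500 individuals drawn from cis-only haplotypes (AB/ab): every double
        heterozygote is truly cis, and EM recovers the phased haplotype
        frequencies to within 1e-6."""
        rng = np.random.default_rng(11)
        haps = rng.choice([0, 3], size=1000, p=[0.7, 0.3])
        table = self._collapse(haps)
        counts = np.bincount(haps, minlength=4)
        res_u = ld_pair(genotype_table=table)
        res_p = ld_pair(phased_counts=counts)
        for a, b in zip(res_u.haplotype_freqs, res_p.haplotype_freqs):
            assert a == pytest.approx(b, abs=1e-6)
        assert res_u.d_prime == pytest.approx(1.0, abs=1e-6)

    def test_em_matches_phased_estimate_under_general_mixing(self):
        """General haplotype mixture: the EM solution agrees with the phased
        estimate to sampling accuracy (the phase split is only statistically
        identifiable)."""
        rng = np.random.default_rng(13)
        true_freqs = np.array([0.5, 0.2, 0.2, 0.1])
        haps = rng.choice(4, size=1000, p=true_freqs)
        table = self._collapse(haps)
        res = ld_pair(genotype_table=table)
        phased = ld_pair(phased_counts=np.bincount(haps, minlength=4))
        assert res.d == pytest.approx(phased.d, abs=0.02)
        assert res.d_prime == pytest.approx(phased.d_prime, abs=0.05)

    def test_phased_and_unphased_agree_when_phase_unambiguous(self):
        """With no double heterozygotes the EM solution is exact: phased and
        unphased routes agree to 1e-6."""
        rng = np.random.default_rng(12)
        # restrict to cis haplotype pairs that create no AaBb genotypes
        haps = rng.choice([0, 3], size=1000, p=[0.7, 0.3])
        pairs = haps.reshape(-1, 2)
        keep = ~((pairs[:, 0] != pairs[:, 1]))  # homozygous pairs only
        haps = pairs[keep].ravel()
        table = self._collapse(haps)
        counts = np.bincount(haps, minlength=4)
        res_u = ld_pair(genotype_table=table)
        res_p = ld_pair(phased_counts=counts)
        for a, b in zip(res_u.haplotype_freqs, res_p.haplotype_freqs):
            assert a == pytest.approx(b, abs=1e-6)


class TestMeff:
    def test_identity_matrix(self):
        m_eff, thr = meff_cutoff(np.eye(22))
        assert m_eff == pytest.approx(22.0)
        assert thr == pytest.approx(0.05 / 22)

    def test_fully_correlated_pair_counts_once(self):
        m_eff, thr = meff_cutoff(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert m_eff == pytest.approx(1.0)
        assert thr == pytest.approx(0.05)

    def test_half_correlated_pair(self):
        m_eff, thr = meff_cutoff(np.array([[1.0, 0.5], [0.5, 1.0]]))
        # eigenvalues 1.5 and 0.5 -> 1 + 0.5 + 0 + 0.5 = 2.0
        assert m_eff == pytest.approx(2.0)
        assert thr == pytest.approx(0.025)

    def test_negative_correlations_use_absolute_values(self):
        m1, _ = meff_cutoff(np.array([[1.0, -0.5], [-0.5, 1.0]]))
        m2, _ = meff_cutoff(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert m1 == pytest.approx(m2)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            meff_cutoff(np.array([[1.0, 0.2], [0.4, 1.0]]))
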