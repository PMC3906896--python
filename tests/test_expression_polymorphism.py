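"""Expression summaries, polarization, SNP Ka/Ks, locations, battery."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dupasym.expression_polymorphism import (
    analysis_battery,
    build_pair_records,
    classify_location,
    expression_summary,
    polarize,
    snp_kaks,
    tissue_correlation,
)


class TestExpressionSummary:
    def test_uniform_profile(self):
        log_mean, cv, evenness = expression_summary([10.0] * 26)
        assert log_mean == pytest.approx(1.0)
        assert cv == 0.0
        assert evenness == pytest.approx(1.0)

    def test_single_expressed_tissue_minimises_evenness(self):
        profile = [0.0] * 25 + [50.0]
        _, cv, evenness = expression_summary(profile)
        assert evenness == pytest.approx(0.0)
        assert cv == pytest.approx(5.0)  # sqrt(25) for a one-hot profile

    def test_matches_brute_force_cv(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            v = rng.lognormal(1.0, 0.8, size=26)
            log_mean, cv, evenness = expression_summary(v)
            assert log_mean == pytest.approx(np.log10(v.mean()))
            assert cv == pytest.approx(v.std() / v.mean())
            assert 0.0 <= evenness <= 1.0

    def test_all_zero_profile_flagged_missing(self):
        assert all(np.isnan(x) for x in expression_summary([0.0] * 5))

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            expression_summary([1.0, -2.0])


class TestPolarize:
    def test_direct_application(self):
        # E = (2, 5), Ka = (0.3, 0.1): copy 1 is faster -> dE = 2 - 5
        assert polarize(2.0, 5.0, 0.3, 0.1) == -3.0

    def test_invariant_to_input_order(self):
        assert polarize(2.0, 5.0, 0.3, 0.1) == polarize(5.0, 2.0, 0.1, 0.3)

    def test_equal_rates_excluded(self):
        with pytest.raises(ValueError):
            polarize(2.0, 5.0, 0.2, 0.2)


class TestTissueCorrelation:
    def test_identical_profiles(self):
        v = np.arange(26, dtype=float)
        assert tissue_correlation(v, v) == pytest.approx(1.0)

    def test_negated_around_mean(self):
        v = np.arange(26, dtype=float)
        assert tissue_correlation(v, 2 * v.mean() - v) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a, b = rng.normal(size=(2, 26))
            num = ((a - a.mean()) * (b - b.mean())).sum()
            den = np.sqrt(((a - a.mean()) ** 2).sum()
                          * ((b - b.mean()) ** 2).sum())
            assert tissue_correlation(a, b) == pytest.approx(num / den)

    def test_zero_variance_flagged(self):
        assert np.isnan(tissue_correlation([1.0] * 26, np.arange(26.0)))


class TestSnpKaKs:
    def test_threshold_pair_is_eligible_with_ratio_one(self):
        ratio, eligible = snp_kaks(3, 3, 200.0, 200.0)
        assert ratio == pytest.approx(1.0)
        assert eligible

    def test_too_few_synonymous_snps_ineligible(self):
        _, eligible = snp_kaks(10, 2, 400.0, 150.0)
        assert not eligible

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ns, nn = int(rng.integers(3, 30)), int(rng.integers(3, 30))
            ss, sn = float(rng.integers(100, 400)), float(rng.integers(300, 900))
            ratio, eligible = snp_kaks(nn, ns, sn, ss)
            assert eligible
            assert ratio == pytest.approx((nn / sn) / (ns / ss))

    def test_zero_synonymous_count_gives_missing_ratio(self):
        ratio, eligible = snp_kaks(5, 0, 400.0, 150.0)
        assert np.isnan(ratio) and not eligible


class TestClassifyLocation:
    def _loc(self, arm, start, end, strand="+"):
        return {"arm": arm, "start": start, "end": end, "strand": strand}

    def test_different_arms(self):
        assert classify_location(self._loc("2L", 0, 1000),
                                 self._loc("2R", 0, 1000)) == "different_arms"

    def test_tandem_collinear_within_5kb(self):
        a = self._loc("3R", 10_000, 12_000, "+")
        b = self._loc("3R", 15_000, 17_000, "+")
        assert classify_location(a, b) == "tandem_collinear"

    def test_tandem_inverted(self):
        a = self._loc("3R", 10_000, 12_000, "+")
        b = self._loc("3R", 13_000, 15_000, "-")
        assert classify_location(a, b) == "tandem_inverted"

    def test_same_arm_distant_beyond_5kb(self):
        a = self._loc("X", 10_000, 12_000)
        b = self._loc("X", 22_001, 30_000)
        assert classify_location(a, b) == "same_arm_distant"

    def test_overlapping_spans_are_tandem_by_orientation(self):
        a = self._loc("X", 10_000, 14_000, "+")
        b = self._loc("X", 12_000, 16_000, "-")
        assert classify_location(a, b) == "tandem_inverted"

    def test_boundary_gap_is_distant(self):
        a = self._loc("X", 0, 1000)
        b = self._loc("X", 6000, 7000)
        assert classify_location(a, b, tandem_threshold=5000) == \
            "same_arm_distant"


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher probability by hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(k) <= p_obs * (1 + 1e-12))


class TestBattery:
    def _pairs(self, d_me, z2=None, seed=0):
        rng = np.random.default_rng(seed)
        n = len(d_me)
        z2 = np.full(n, 2.0) if z2 is None else np.asarray(z2, dtype=float)
        return pd.DataFrame({
            "duplication_id": [f"d{i}" for i in range(n)],
            "z2": z2,
            "log10_z2": np.where(z2 > 0, np.log10(np.where(z2 > 0, z2, 1)),
                                 np.nan),
            "d_me": d_me,
            "mean_log_me": rng.normal(1, 0.3, size=n),
            "mean_cv": rng.uniform(0.2, 1.0, size=n),
        })

    def test_fisher_exact_matches_enumeration_oracle(self):
        d_me = [1.0] * 3 + [-1.0] * 7
        out = analysis_battery(self._pairs(d_me))
        row = out["tests"].query("variable == 'd_me' and subset == 'all'")
        assert row["p_fisher"].iloc[0] == pytest.approx(
            fisher_two_sided_oracle(3, 7, 7, 3), rel=1e-9)

    def test_type_one_control_with_null_differences(self):
        rng = np.random.default_rng(77)
        hits = 0
        for rep in range(40):
            d = rng.normal(0, 1, size=30)
            out = analysis_battery(self._pairs(d, seed=rep))
            row = out["tests"].query("variable == 'd_me' and subset == 'all'")
            hits += bool(row["significant"].iloc[0])
        assert hits <= 6  # ~5% nominal rate over 40 cohorts

    def test_power_against_imposed_negative_shift(self):
        rng = np.random.default_rng(3)
        d = rng.normal(-0.6, 0.5, size=40)
        out = analysis_battery(self._pairs(d))
        row = out["tests"].query("variable == 'd_me' and subset == 'all'")
        assert row["mean"].iloc[0] < 0 and row["significant"].iloc[0]

    def test_insufficient_n_is_skipped_with_reason(self):
        out = analysis_battery(self._pairs([0.5, -0.5]))
        assert (out["skipped"]["test"].str.contains("d_me")).any()

    def test_regressions_report_coefficients(self):
        rng = np.random.default_rng(10)
        n = 50
        pairs = self._pairs(list(rng.normal(size=n)),
                            z2=rng.exponential(2.0, size=n) + 0.5, seed=2)
        out = analysis_battery(pairs)
        regs = out["regressions"].set_index("regression")
        assert "log_z2_on_mean_expression" in regs.index
        assert np.isfinite(regs["coef"]).all()


class TestBuildPairRecords:
    def _base_pairs(self):
        return pd.DataFrame({
            "duplication_id": ["d0", "d1"],
            "gene1": ["f0|a_1", "f1|b_1"],
            "gene2": ["f0|a_2", "f1|b_2"],
            "ka1": [0.3, 0.1],
            "ka2": [0.1, 0.1],
            "z2": [4.0, 0.0],
        })

    def _expression(self):
        rng = np.random.default_rng(1)
        rows = []
        for g in ("f0|a_1", "f0|a_2", "f1|b_1", "f1|b_2"):
            rows.append([g, *rng.lognormal(1, 0.4, size=4)])
        return pd.DataFrame(rows, columns=["gene_id"] + [f"tissue_{i}"
                                                         for i in range(1, 5)])

    def test_polarized_columns_and_equal_ka_exclusion(self):
        out = build_pair_records(self._base_pairs(), self._expression())
        assert np.isfinite(out.loc[0, "d_me"])
        assert np.isnan(out.loc[1, "d_me"])  # ka tie carries no direction
        assert np.isnan(out.loc[1, "log10_z2"])

    def test_duplicate_identifier_pairs_dropped(self):
        pairs = self._base_pairs()
        pairs.loc[0, "gene2"] = pairs.loc[0, "gene1"]
        out = build_pair_records(pairs, self._expression())
        assert list(out["duplication_id"]) == ["d1"]

    def test_snp_join_flags_eligibility(self):
        snp = pd.DataFrame({
            "gene_id": ["f0|a_1", "f0|a_2", "f1|b_1", "f1|b_2"],
            "n_syn": [5, 6, 2, 9],
            "n_nonsyn": [4, 7, 8, 8],
            "sites_syn": [150.0] * 4,
            "sites_nonsyn": [450.0] * 4,
        })
        out = build_pair_records(self._base_pairs(), snp=snp)
        assert bool(out.loc[0, "snp_eligible"])
        assert not bool(out.loc[1, "snp_eligible"])  # 2 synonymous SNPs
        assert np.isfinite(out.loc[0, "d_kaks"])
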