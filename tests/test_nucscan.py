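"""MNase-scanning protection profiles and amplicon tiling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromotopo import nucscan, synthgen


class TestPercentProtection:
    def test_equal_cts_full_protection(self):
        assert nucscan.percent_protection(20.0, 20.0) == pytest.approx(100.0)

    def test_one_cycle_halving(self):
        assert nucscan.percent_protection(20.0, 21.0) == pytest.approx(50.0)

    def test_large_delta(self):
        assert nucscan.percent_protection(20.0, 23.32) == pytest.approx(10.0, rel=2e-3)

    def test_depends_only_on_delta_ct(self):
        assert nucscan.percent_protection(18.0, 19.5) == pytest.approx(
            nucscan.percent_protection(25.0, 26.5)
        )

    def test_censored_ct_reports_zero(self):
        assert nucscan.percent_protection(20.0, nucscan.CENSORED_CT) == 0.0

    def test_overrange_protection_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            nucscan.percent_protection(21.0, 20.0)


class TestDesignTiling:
    def test_canonical_promoter_region(self):
        amps = nucscan.design_tiling(633)
        starts = [a.start for a in amps]
        assert starts == [1, 71, 141, 211, 281, 351, 421, 491, 534]
        assert amps[-1].end == 633

    def test_single_amplicon_region(self):
        amps = nucscan.design_tiling(100)
        assert len(amps) == 1 and (amps[0].start, amps[0].end) == (1, 100)

    def test_three_prime_region_fully_covered(self):
        amps = nucscan.design_tiling(509)
        covered = np.zeros(510, dtype=bool)
        for a in amps:
            covered[a.start : a.end + 1] = True
        assert covered[1:].all()

    def test_infeasible_tolerances_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            nucscan.design_tiling(500, amplicon_size=100, size_tol=40, overlap=30, overlap_tol=40)

    @given(region=st.integers(100, 2000))
    @settings(max_examples=100, derandomize=True)
    def test_tiling_respects_tolerances_and_coverage(self, region):
        amps = nucscan.design_tiling(region)
        covered = np.zeros(region + 1, dtype=bool)
        for a in amps:
            assert abs(a.length - 100) <= 8
            covered[a.start : a.end + 1] = True
        for prev, nxt in zip(amps, amps[1:]):
            ov = prev.end - nxt.start + 1
            assert ov >= 30 - 10  # never a gap wider than the overlap allows
            if nxt is not amps[-1]:
                assert abs(ov - 30) <= 10
        # nothing uncovered except possibly < size_tol bp at the 3' end
        assert covered[1 : region - 8].all()


class TestProtectionProfile:
    def make(self, intervals, completeness=1.0, noise=0.0, seed=0, region=633):
        truth = synthgen.OccupancyTruth(
            seed=seed,
            region_length=region,
            nucleosome_intervals=intervals,
            digestion_completeness=completeness,
            ct_noise_sd=noise,
        )
        amps = nucscan.design_tiling(region)
        return truth, amps, synthgen.gen_ct_table(truth, amps)

    def test_single_nucleosome_recovered(self):
        truth, amps, table = self.make(((201, 347),))
        prof = nucscan.protection_profile(table, amps)
        for a, mean in zip(amps, prof.data["mean_protection"]):
            frac = truth.covered_fraction(a)
            if frac == 1.0:
                assert mean == pytest.approx(100.0)
            elif frac == 0.0:
                assert mean == 0.0

    def test_identical_replicates_zero_sd(self):
        _, amps, table = self.make(((201, 347),))
        prof = nucscan.protection_profile(table, amps)
        assert (prof.data["sd_protection"] == 0.0).all()

    def test_peak_localises_to_true_nucleosome(self):
        truth, amps, table = self.make(((301, 447),), completeness=0.95, noise=0.3, seed=42)
        prof = nucscan.protection_profile(table, amps)
        best = prof.data.loc[prof.data["mean_protection"].idxmax()]
        true_center = (301 + 447) / 2
        step = amps[1].start - amps[0].start
        assert abs(best["midpoint"] - true_center) <= step + 100 / 2

    def test_unknown_amplicon_rejected(self):
        _, amps, table = self.make(((201, 347),))
        with pytest.raises(ValueError, match="unknown"):
            nucscan.protection_profile(table, amps[:-1])

    def test_mean_absolute_error_small_with_noise(self):
        truth, amps, table = self.make(
            ((101, 247), (301, 447)), completeness=1.0, noise=0.3, seed=7
        )
        prof = nucscan.protection_profile(table, amps)
        expected = np.array([100.0 * truth.surviving_fraction(a) for a in amps])
        err = np.abs(prof.data["mean_protection"].to_numpy() - expected)
        assert err.mean() < 10.0

    def test_max_normalisation(self):
        _, amps, table = self.make(((201, 347),), completeness=0.9)
        prof = nucscan.protection_profile(table, amps).max_normalized()
        assert prof.normalized
        assert prof.data["mean_protection"].max() == pytest.approx(100.0)


class TestCompareProfiles:
    def profiles(self, intervals_a, intervals_b, seed=1, noise=0.3):
        amps = nucscan.design_tiling(633)
        prof = {}
        for key, ivs, s in (("a", intervals_a, seed), ("b", intervals_b, seed + 100)):
            truth = synthgen.OccupancyTruth(
                seed=s, nucleosome_intervals=ivs, digestion_completeness=0.95,
                ct_noise_sd=noise,
            )
            prof[key] = nucscan.protection_profile(
                synthgen.gen_ct_table(truth, amps), amps, condition_label=key
            )
        return amps, prof["a"], prof["b"]

    def test_identical_profiles_no_differences(self):
        amps = nucscan.design_tiling(633)
        truth = synthgen.OccupancyTruth(seed=3, ct_noise_sd=0.0)
        p = nucscan.protection_profile(synthgen.gen_ct_table(truth, amps), amps)
        out = nucscan.compare_profiles(p, p)
        assert (out["difference"] == 0.0).all()
        assert out.attrs["trend_mean"] == 0.0

    def test_nucleosome_loss_detected_only_where_it_happened(self):
        ivs_full = ((101, 247), (301, 447))
        amps, a, b = self.profiles(ivs_full, ((101, 247),), noise=0.3)
        out = nucscan.compare_profiles(a, b)
        overlapping = [
            i for i, amp in enumerate(amps)
            if min(447, amp.end) - max(301, amp.start) >= 0
        ]
        sig = set(out.index[out["p_value"] < 0.01])
        assert sig & set(overlapping)
        assert not sig - set(overlapping)
        assert (out.loc[sorted(sig), "difference"] > 0).all()

    def test_uniform_attenuation_shows_as_negative_trend(self):
        amps = nucscan.design_tiling(633)
        ivs = ((101, 247), (301, 447))
        ta = synthgen.OccupancyTruth(
            seed=5, nucleosome_intervals=ivs, digestion_completeness=0.95, ct_noise_sd=0.3
        )
        a = nucscan.protection_profile(synthgen.gen_ct_table(ta, amps), amps)
        # condition b: everything 5% more digested (uniform sensitisation)
        tb_table = synthgen.gen_ct_table(
            synthgen.OccupancyTruth(
                seed=6, nucleosome_intervals=ivs, digestion_completeness=0.95,
                ct_noise_sd=0.3,
            ),
            amps,
        )
        dig = tb_table["digestion"] == "digested"
        tb_table.loc[dig, "ct"] = tb_table.loc[dig, "ct"] - np.log2(0.95)
        b = nucscan.protection_profile(tb_table, amps)
        out = nucscan.compare_profiles(b, a)
        assert out.attrs["trend_mean"] < 0

    def test_mismatched_amplicons_rejected(self):
        amps = nucscan.design_tiling(633)
        truth = synthgen.OccupancyTruth(seed=8)
        p = nucscan.protection_profile(synthgen.gen_ct_table(truth, amps), amps)
        q_amps = nucscan.design_tiling(509)
        q = nucscan.protection_profile(
            synthgen.gen_ct_table(
                synthgen.OccupancyTruth(seed=9, region_length=509,
                                        nucleosome_intervals=((101, 247),)),
                q_amps,
            ),
            q_amps,
        )
        with pytest.raises(ValueError, match="amplicon"):
            nucscan.compare_profiles(p, q)
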