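"""Topoisomer band detection, linking-number indexing and Morse estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromotopo import synthgen, topo
from conftest import lane_morse_fit


def make_ladder(intensities, spacing=50.0, indexed=False):
    bands = tuple(
        topo.Band(position=spacing * (i + 1), intensity=v)
        for i, v in enumerate(intensities)
    )
    ladder = topo.TopoisomerLadder(bands=bands)
    return topo.assign_linking_indices(ladder) if indexed else ladder


class TestDetectBands:
    def test_noiseless_lane_recovers_generator_bands(self):
        truth = synthgen.LadderTruth(seed=1, center=0.0, noise_sd=0.0)
        lane = synthgen.gen_topo_lane(truth)
        ladder = topo.detect_bands(lane)
        assert len(ladder.bands) == 2 * truth.n_bands_each_side + 1
        step = truth.band_spacing / truth.samples_per_spacing
        assert np.allclose(ladder.positions, truth.band_positions(), atol=step / 2 + 1e-9)

    def test_relative_intensities_recovered(self):
        truth = synthgen.LadderTruth(seed=2, center=0.0, noise_sd=0.0, background_level=0.0)
        ladder = topo.detect_bands(synthgen.gen_topo_lane(truth))
        got = ladder.intensities / ladder.intensities.max()
        want = truth.band_intensities() / truth.band_intensities().max()
        assert np.allclose(got, want, rtol=0.02)

    def test_flat_trace_is_insufficient(self):
        lane = topo.LaneProfile(np.arange(100.0), np.ones(100), "flat")
        with pytest.raises(topo.InsufficientLadderError):
            topo.detect_bands(lane)

    def test_symmetric_trace_about_brightest_band(self):
        truth = synthgen.LadderTruth(seed=3, center=0.0, noise_sd=0.0)
        lane = synthgen.gen_topo_lane(truth)
        ladder = topo.assign_linking_indices(topo.detect_bands(lane))
        inten = ladder.intensities
        mid = int(np.flatnonzero(ladder.delta_lks == 0)[0])
        assert np.allclose(inten[:mid], inten[mid + 1:][::-1], rtol=0.02)

    def test_stray_species_outside_ladder_excluded(self):
        truth = synthgen.LadderTruth(seed=4, center=0.0, noise_sd=0.0)
        lane = synthgen.gen_topo_lane(truth)
        # a nicked/linear band far beyond the ladder
        pos = np.append(lane.positions, lane.positions[-1] + np.arange(1, 300) * 2.5)
        inten = np.append(lane.intensities, np.zeros(299))
        stray_center = lane.positions[-1] + 350.0
        inten += 800.0 * np.exp(-0.5 * ((pos - stray_center) / 8.0) ** 2)
        ladder = topo.detect_bands(
            topo.LaneProfile(pos, inten, "stray"), expected_spacing=truth.band_spacing
        )
        assert len(ladder.bands) == 2 * truth.n_bands_each_side + 1


class TestAssignIndices:
    def test_central_brightest(self):
        ladder = make_ladder([1, 2, 5, 2, 1], indexed=True)
        assert list(ladder.delta_lks) == [-2, -1, 0, 1, 2]

    def test_brightest_slowest(self):
        ladder = make_ladder([5, 4, 3, 2], indexed=True)
        assert list(ladder.delta_lks) == [0, 1, 2, 3]

    def test_generator_brightest_matches_truth(self, detected_ladder):
        truth, ladder = detected_ladder
        # center 0.4: the absolute-0 band is brightest, so indices line up
        k = truth.band_delta_lks()
        np.testing.assert_array_equal(ladder.delta_lks, k)

    def test_tie_breaks_toward_mode_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            ladder = make_ladder([1.0, 4.0, 4.0, 3.0, 1.0], indexed=True)
        assert list(ladder.delta_lks) == [-2, -1, 0, 1, 2]


class TestMorseCenter:
    def test_symmetric_ladder_centers_on_brightest(self):
        truth = synthgen.LadderTruth(seed=5, center=0.0)
        fit = topo.morse_center(truth.exact_ladder())
        assert fit.center_signed == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_closed_form(self):
        truth = synthgen.LadderTruth(seed=6, center=0.4, concentration_param=0.3)
        fit = topo.morse_center(truth.exact_ladder())
        assert fit.center_signed == pytest.approx(0.4, abs=1e-12)
        assert fit.slope_m == pytest.approx(-0.3, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_off_integer_center_reanchors(self):
        truth = synthgen.LadderTruth(seed=7, center=-1.48, concentration_param=0.5)
        fit = topo.morse_center(truth.exact_ladder())
        assert fit.center_signed == pytest.approx(-0.48, abs=1e-9)
        assert truth.absolute_center(fit.center_signed) == pytest.approx(-1.48, abs=1e-9)

    def test_brute_force_regression_oracle(self):
        # independent oracle: explicit polyfit of (1/dlk)*ln(I/Imax) on dlk
        truth = synthgen.LadderTruth(seed=8, center=0.7, concentration_param=0.25)
        ladder = truth.exact_ladder()
        dlk = ladder.delta_lks
        inten = ladder.intensities
        keep = dlk != 0
        y = np.log(inten[keep] / inten[dlk == 0][0]) / dlk[keep]
        m, b = np.polyfit(dlk[keep].astype(float), y, 1)
        fit = topo.morse_center(ladder)
        assert fit.center_signed == pytest.approx(-b / (2 * m), rel=1e-9)

    @given(
        c=st.floats(-1.95, 1.95),
        a=st.floats(0.1, 1.0),
        n=st.integers(3, 6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_exact_on_noiseless_gaussian_ladders(self, c, a, n):
        truth = synthgen.LadderTruth(
            seed=0, center=c, concentration_param=a, n_bands_each_side=n
        )
        fit = topo.morse_center(truth.exact_ladder())
        assert abs(truth.absolute_center(fit.center_signed) - c) < 1e-9

    def test_invariant_to_intensity_rescaling(self):
        truth = synthgen.LadderTruth(seed=9, center=0.8)
        ladder = truth.exact_ladder()
        scaled = topo.TopoisomerLadder(
            bands=tuple(
                topo.Band(b.position, b.intensity * 37.5, b.delta_lk)
                for b in ladder.bands
            )
        )
        assert topo.morse_center(scaled).center_signed == pytest.approx(
            topo.morse_center(ladder).center_signed, rel=1e-12
        )

    def test_nonpositive_intensity_rejected(self):
        ladder = make_ladder([1, 2, 5, 0.0, 1], indexed=True)
        with pytest.raises(ValueError, match="positive"):
            topo.morse_center(ladder)

    def test_flat_distribution_has_no_center(self):
        ladder = make_ladder([2, 2, 2.0000001, 2, 2], indexed=True)
        with pytest.raises(ValueError, match="flat"):
            topo.morse_center(ladder)


class TestCentroid:
    def test_symmetric_ladder_is_zero(self):
        truth = synthgen.LadderTruth(seed=10, center=0.0)
        assert topo.centroid_center(truth.exact_ladder()) == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_morse_on_wide_ladders(self):
        truth = synthgen.LadderTruth(
            seed=11, center=0.4, concentration_param=0.3, n_bands_each_side=6
        )
        ladder = truth.exact_ladder()
        assert abs(
            topo.centroid_center(ladder) - topo.morse_center(ladder).center_signed
        ) < 0.05


class TestDeltaLk:
    def test_identical_conditions_give_zero(self):
        fits = [lane_morse_fit(100 + i, -1.0, noise_sd=0.0) for i in range(3)]
        r = topo.delta_lk(fits, fits)
        assert r.mean_difference == 0.0

    def test_sign_flips_when_swapped(self):
        a = [lane_morse_fit(200 + i, -0.5) for i in range(4)]
        b = [lane_morse_fit(300 + i, -1.5) for i in range(4)]
        r_ab, r_ba = topo.delta_lk(a, b), topo.delta_lk(b, a)
        assert r_ab.mean_difference == pytest.approx(-r_ba.mean_difference, rel=1e-12)

    @pytest.mark.parametrize("shift", [0.6, 1.0, 1.5])
    def test_injected_shift_recovered(self, shift):
        a = [lane_morse_fit(400 + i, -1.5 + shift) for i in range(5)]
        b = [lane_morse_fit(500 + i, -1.5) for i in range(5)]
        r = topo.delta_lk(a, b)
        # small detection-induced bias (<0.05) dominates the tiny replicate SEM
        assert abs(r.mean_difference - shift) < 3 * r.sem + 0.05
        assert r.p_value < 0.05

    def test_mismatched_pairing_falls_back_unpaired(self):
        a = [lane_morse_fit(600 + i, -1.0) for i in range(4)]
        b = [lane_morse_fit(700 + i, -1.0) for i in range(3)]
        with pytest.warns(UserWarning, match="unpaired"):
            r = topo.delta_lk(a, b, paired=True)
        assert not r.paired
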