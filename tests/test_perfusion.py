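"""Maximum-upslope MBF estimation and remote-flow normalization."""

import numpy as np
import pytest

from fractalperf.exceptions import InvalidInputError
from fractalperf.perfusion import (MaxUpslopeFlow, estimate_mbf, extract_aif,
                                   max_upslope, mbf_map, remote_and_relative,
                                   segment_mbf)
from fractalperf.phantom import AIFParams, make_aif_curve
from fractalperf.preprocess import ConversionParams, hu_to_concentration
from fractalperf.aha import segment_rois
from fractalperf.phantom import make_phantom

from conftest import small_config


class TestExtractAIF:
    def test_mean_of_two_single_voxel_rois(self):
        data = np.zeros((3, 3, 3, 5))
        data[0, 0, 0] = 4.0
        data[2, 2, 2] = 10.0
        roi = np.zeros((3, 3, 3), bool)
        roi[0, 0, 0] = roi[2, 2, 2] = True
        assert np.allclose(extract_aif(data, roi), 7.0)

    def test_constant_volume_flat_curve(self):
        data = np.full((3, 3, 3, 6), 5.5)
        roi = np.ones((3, 3, 3), bool)
        curve = extract_aif(data, roi)
        assert np.allclose(curve, 5.5)

    def test_empty_roi_rejected(self):
        with pytest.raises(InvalidInputError):
            extract_aif(np.zeros((3, 3, 3, 5)), np.zeros((3, 3, 3), bool))

    def test_phantom_round_trip(self, small_study):
        conc = hu_to_concentration(small_study.volume, ConversionParams(kv=80))
        curve = extract_aif(conc, small_study.aif_mask)
        truth = make_aif_curve(small_study.config.aif,
                               small_study.volume.frame_times_s)
        assert np.allclose(curve, truth, atol=0.15)  # noise + baseline detection
        assert curve.max() == pytest.approx(truth.max(), rel=0.02)


class TestMaxUpslope:
    def test_linear_ramp(self):
        t = np.arange(10.0)
        assert max_upslope(t.copy(), t) == pytest.approx(1.0)

    def test_flat_curve_zero(self):
        t = np.arange(10.0)
        assert max_upslope(np.full(10, 3.0), t) == 0.0

    def test_gamma_variate_matches_analytic_derivative(self):
        # d/dt of A x^a exp(a(1-x)), x = (t-t0)/tp: max found on a dense grid
        A, a, tp, t0 = 12.0, 3.0, 6.0, 3.0
        tau = np.linspace(1e-6, 30, 200001)
        x = tau / tp
        deriv = A * (a / tp) * (x ** (a - 1) - x**a) * np.exp(a * (1 - x))
        analytic_max = deriv.max()
        t = np.arange(30.0)
        curve = make_aif_curve(AIFParams(A, t0, a, tp / a), t)
        assert max_upslope(curve, t) == pytest.approx(analytic_max, rel=0.03)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidInputError):
            max_upslope(np.ones(3), np.arange(3.0))

    def test_window_restricts_search(self):
        t = np.arange(8.0)
        curve = np.array([0, 1, 2, 3, 3, 3, 3, 50.0])
        assert max_upslope(curve, t, window=(0, 5)) == pytest.approx(1.0)


class TestEstimateMBF:
    def test_spec_arithmetic(self):
        # tissue upslope 0.30 mg/mL/s on an AIF peaking at 12 -> 150
        t = np.arange(20.0)
        aif = make_aif_curve(AIFParams(amplitude=12.0), t)
        tissue = np.concatenate([[0.0], np.cumsum(np.minimum(0.30, aif[:-1]))])
        tissue = 0.30 * t  # constant upslope 0.30 within the first pass
        assert estimate_mbf(tissue, aif, t) == pytest.approx(150.0)

    def test_scaling_and_baseline_invariance(self):
        t = np.arange(25.0)
        aif = make_aif_curve(AIFParams(), t)
        from fractalperf.phantom import make_tissue_curve

        tissue = make_tissue_curve(aif, t, 100.0)
        assert estimate_mbf(3.0 * tissue, aif, t) == pytest.approx(
            3.0 * estimate_mbf(tissue, aif, t), rel=1e-12
        )
        assert estimate_mbf(tissue + 7.0, aif, t) == pytest.approx(
            estimate_mbf(tissue, aif, t), rel=1e-12
        )

    def test_zero_aif_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(InvalidInputError):
            estimate_mbf(np.ones(10), np.zeros(10), t)


class TestSegmentStatistics:
    def test_phantom_segment_recovery(self):
        st = make_phantom(small_config(seed=2))
        conc = hu_to_concentration(st.volume, ConversionParams(kv=80))
        aif = extract_aif(conc, st.aif_mask)
        rois = segment_rois(st.labels, st.config.spacing_mm, 1.0,
                            st.myocardium_mask)
        est = segment_mbf(conc, rois, aif, st.volume.frame_times_s)
        # compare against the mean true flow of the tissue actually sampled
        # (the eroded ROI); under voxelwise flow heterogeneity the whole-segment
        # mean differs from any sub-ROI by sampling alone
        errs = [
            abs(est[s] - st.true_mbf_field[rois[s]].mean())
            / st.true_mbf_field[rois[s]].mean()
            for s in range(1, 18)
            if rois[s].any() and np.isfinite(est.get(s, np.nan))
        ]
        assert len(errs) >= 12
        assert np.median(errs) < 0.05

    def test_voxel_map_nonnegative_and_masked(self, small_study):
        conc = hu_to_concentration(small_study.volume, ConversionParams(kv=80))
        aif = extract_aif(conc, small_study.aif_mask)
        m = mbf_map(conc, aif, small_study.volume.frame_times_s,
                    mask=small_study.myocardium_mask)
        assert m.shape == small_study.myocardium_mask.shape
        assert np.all(m >= 0)
        assert np.all(m[~small_study.myocardium_mask] == 0)

    def test_transformer_api(self, small_study):
        conc = hu_to_concentration(small_study.volume, ConversionParams(kv=80))
        est = MaxUpslopeFlow(aif_roi=small_study.aif_mask).fit(conc)
        assert est.aif_peak_ > 0
        out = est.transform(conc)
        assert out.shape == small_study.myocardium_mask.shape


class TestRemoteAndRelative:
    def test_remote_is_max_segment(self):
        table = {1: 120.0, 2: 149.0, 3: 90.0}
        remote, seg, rel = remote_and_relative(table)
        assert remote == 149.0 and seg == 2
        assert rel[2] == 1.0

    def test_all_equal_all_relative_one(self):
        remote, seg, rel = remote_and_relative({1: 100.0, 2: 100.0, 3: 100.0})
        assert all(v == 1.0 for v in rel.values())
        assert seg == 1  # tie broken to lowest index

    def test_two_segment_table(self):
        remote, _, rel = remote_and_relative({1: 100.0, 2: 50.0})
        assert remote == 100.0 and rel == {1: 1.0, 2: 0.5}

    def test_exactly_one_remote_segment(self):
        _, seg, rel = remote_and_relative({1: 80.0, 2: 95.0, 3: 95.0})
        assert sum(v == 1.0 for v in rel.values()) == 2  # ties share value...
        assert seg == 2                                   # ...but remote is unique

    def test_excluded_segments_ineligible(self):
        table = {1: 200.0, 2: 150.0}
        remote, seg, rel = remote_and_relative(
            table, included={1: False, 2: True}
        )
        assert remote == 150.0 and seg == 2
        assert 1 not in rel

    def test_all_excluded_rejected(self):
        with pytest.raises(InvalidInputError):
            remote_and_relative({1: 100.0}, included={1: False})
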