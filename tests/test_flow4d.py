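"""4D-flow centerline processing: geometry, flow integration, PI, classification."""

import numpy as np
import pytest

from bbbflow.flow4d import (
    CenterlineTree,
    FlowWaveform,
    average_waveforms,
    background_correct,
    branch_waveforms,
    classify_branches,
    cross_section_flow,
    distal_waveform,
    estimate_direction,
    interpolate_waveform,
    pulsatility_index,
    segment_vessels,
    skeletonize_tree,
    total_cbf,
    vessel_waveform,
    vesselness,
)
from bbbflow.phantom import (
    FlowPhantomTruth,
    TubeSpec,
    make_flow_phantom,
    sinusoidal_waveform,
)


class TestBackgroundCorrect:
    def _field(self, rng, shape=(12, 12, 12), n_t=4):
        return rng.normal(0, 0.0, size=(3, *shape, n_t))

    def test_planted_linear_drift_removed(self, rng):
        shape = (12, 12, 12)
        v = np.zeros((3, *shape, 4))
        grad = np.indices(shape)[0] * 0.005  # 0.5 cm/s per 100 voxels
        v[0] += grad[..., None]
        static = np.ones(shape, dtype=bool)
        out = background_correct(v, static, order=1)
        assert np.abs(out[0][static]).max() < 1e-6

    def test_zero_drift_identity(self):
        v = np.zeros((3, 8, 8, 8, 4))
        out = background_correct(v, np.ones((8, 8, 8), dtype=bool), order=2)
        np.testing.assert_allclose(out, v, atol=1e-12)

    def test_order_zero_subtracts_static_mean(self, rng):
        shape = (8, 8, 8)
        v = np.full((3, *shape, 2), 1.5)
        out = background_correct(v, np.ones(shape, dtype=bool), order=0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_time_varying_signal_preserved(self):
        """Only the static (time-averaged) polynomial field is removed."""
        shape = (8, 8, 8)
        v = np.zeros((3, *shape, 4))
        v[1, 4, 4, 4, :] = [1.0, -1.0, 1.0, -1.0]  # zero time-mean pulsation
        out = background_correct(v, np.ones(shape, dtype=bool), order=1)
        np.testing.assert_allclose(out[1, 4, 4, 4, :], [1.0, -1.0, 1.0, -1.0], atol=1e-9)

    def test_too_few_static_voxels_rejected(self):
        v = np.zeros((3, 8, 8, 8, 2))
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="static"):
            background_correct(v, mask, order=2)


class TestSkeleton:
    def _tube_mask(self, shape=(16, 16, 28), radius=3):
        ii, jj, kk = np.indices(shape)
        return ((ii - 8) ** 2 + (jj - 8) ** 2 <= radius**2) & (kk >= 3) & (kk < 25)

    def test_straight_tube_single_branch_on_axis(self):
        tree = skeletonize_tree(self._tube_mask(), spacing=1.0)
        assert tree.n_branches == 1
        path = tree.branches[0]
        assert np.all(np.abs(path[:, 0] - 8) <= 1)
        assert np.all(np.abs(path[:, 1] - 8) <= 1)

    def test_y_junction_three_branches_one_junction(self):
        shape = (40, 24, 24)
        mask = np.zeros(shape, dtype=bool)
        ii, jj, kk = np.indices(shape)
        # trunk along +x then two diagonal limbs
        mask |= ((jj - 12) ** 2 + (kk - 12) ** 2 <= 9) & (ii < 20) & (ii >= 2)
        for sign in (+1, -1):
            # limb center line: j = 12 + sign*(i-20)/2
            d2 = (jj - (12 + sign * (ii - 20) * 0.5)) ** 2 + (kk - 12) ** 2
            mask |= (d2 <= 4) & (ii >= 20) & (ii < 34)
        tree = skeletonize_tree(mask, spacing=1.0)
        assert tree.n_branches == 3
        assert len(tree.junctions) >= 1

    def test_empty_volume_empty_tree(self):
        tree = skeletonize_tree(np.zeros((8, 8, 8), dtype=bool))
        assert tree.n_branches == 0

    def test_boundary_touch_warns(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[0:10, 4:6, 4:6] = True
        with pytest.warns(UserWarning, match="boundary"):
            skeletonize_tree(mask)

    def test_segment_vessels_threshold(self):
        cd = np.zeros((5, 5, 5))
        cd[2, 2, 2] = 10.0
        assert segment_vessels(cd, 5.0).sum() == 1


class TestDirection:
    def test_straight_branch_unit_x(self):
        path = np.column_stack([np.arange(10), np.full(10, 3), np.full(10, 3)])
        tree = CenterlineTree(branches=[path], spacing=1.0)
        estimate_direction(tree, window=3)
        np.testing.assert_allclose(tree.tangents[0], [[1, 0, 0]] * 10, atol=1e-12)

    def test_circular_arc_tangent_perpendicular_to_radius(self):
        theta = np.linspace(0, np.pi / 2, 40)
        r = 20.0
        path = np.column_stack(
            [np.round(r * np.cos(theta)), np.round(r * np.sin(theta)), np.zeros_like(theta)]
        ).astype(int)
        path = path[np.any(np.diff(path, axis=0, prepend=path[:1] - 1) != 0, axis=1)]
        tree = CenterlineTree(branches=[path], spacing=1.0)
        estimate_direction(tree, window=3)
        for p, t in zip(path[3:-3], tree.tangents[0][3:-3]):
            radial = p / np.linalg.norm(p)
            angle = np.degrees(np.arcsin(abs(np.dot(radial, t))))
            assert angle < 5.0

    def test_two_voxel_branch_normalized_difference(self):
        path = np.array([[0, 0, 0], [1, 1, 0]])
        tree = CenterlineTree(branches=[path], spacing=1.0)
        estimate_direction(tree, window=2)
        np.testing.assert_allclose(
            tree.tangents[0], [[np.sqrt(0.5), np.sqrt(0.5), 0]] * 2, atol=1e-12
        )

    def test_invalid_window_rejected(self):
        tree = CenterlineTree(branches=[np.zeros((3, 3), dtype=int)], spacing=1.0)
        with pytest.raises(ValueError):
            estimate_direction(tree, window=5)


@pytest.fixture(scope="module")
def straight_tube(params_module=None):
    from bbbflow.phantom import AcquisitionParams

    params = AcquisitionParams()
    wave = sinusoidal_waveform(300.0, 0.8, params.n_cardiac_frames)
    tube = TubeSpec("t", np.array([[8.0, 8.0, 3.0], [8.0, 8.0, 25.0]]), 2.5, wave, "artery")
    ph = make_flow_phantom(FlowPhantomTruth((tube,)), (24, 24, 42), 0.6875, params)
    return ph, wave


class TestCrossSection:
    def test_phantom_waveform_recovered_within_five_percent(self, straight_tube):
        ph, wave = straight_tube
        mid = np.array([8.0, 8.0, 14.0]) / ph.spacing
        flow, diam, n = cross_section_flow(
            ph.velocity, ph.cd, np.round(mid), np.array([0.0, 0.0, 1.0]), ph.spacing
        )
        assert n > 0
        np.testing.assert_allclose(flow, wave, rtol=0.05)
        assert diam == pytest.approx(5.0, rel=0.15)

    def test_velocity_perpendicular_to_tangent_gives_zero(self, straight_tube):
        ph, _ = straight_tube
        mid = np.round(np.array([8.0, 8.0, 14.0]) / ph.spacing)
        flow, _, _ = cross_section_flow(
            ph.velocity, ph.cd, mid, np.array([1.0, 0.0, 0.0]), ph.spacing
        )
        np.testing.assert_allclose(flow, 0.0, atol=1e-9)

    def test_linearity_in_velocity(self, straight_tube):
        ph, _ = straight_tube
        mid = np.round(np.array([8.0, 8.0, 14.0]) / ph.spacing)
        t = np.array([0.0, 0.0, 1.0])
        f1, _, _ = cross_section_flow(ph.velocity, ph.cd, mid, t, ph.spacing)
        f2, _, _ = cross_section_flow(3.0 * ph.velocity, ph.cd, mid, t, ph.spacing)
        np.testing.assert_allclose(f2, 3.0 * f1, rtol=1e-12)
        pi1 = pulsatility_index(FlowWaveform(f1)).pi
        pi2 = pulsatility_index(FlowWaveform(f2)).pi
        assert pi2 == pytest.approx(pi1, rel=1e-12)


class TestVesselWaveform:
    def _tree(self, ph):
        mask = segment_vessels(ph.cd, ph.cd.max() * 0.4)
        tree = skeletonize_tree(mask, ph.spacing)
        estimate_direction(tree)
        return tree

    def test_averaging_matches_truth(self, straight_tube):
        ph, wave = straight_tube
        tree = self._tree(ph)
        seed = np.array([8.0, 8.0, 14.0]) / ph.spacing
        w, diam = vessel_waveform(tree, ph.velocity, ph.cd, seed, n_sections=15)
        np.testing.assert_allclose(w.flow, wave, rtol=0.05)

    def test_single_section_equals_cross_section_flow(self, straight_tube):
        ph, _ = straight_tube
        tree = self._tree(ph)
        seed = np.array([8.0, 8.0, 14.0]) / ph.spacing
        w1, _ = vessel_waveform(tree, ph.velocity, ph.cd, seed, n_sections=1)
        bi, i0 = 0, int(np.argmin(np.linalg.norm(tree.branches[0] - seed, axis=1)))
        direct, _, _ = cross_section_flow(
            ph.velocity, ph.cd, tree.branches[0][i0], tree.tangents[0][i0], ph.spacing
        )
        np.testing.assert_allclose(w1.flow, direct, rtol=1e-12)

    def test_branch_too_short_raises(self, straight_tube):
        ph, _ = straight_tube
        tree = self._tree(ph)
        seed = np.array([8.0, 8.0, 14.0]) / ph.spacing
        with pytest.raises(ValueError, match="n_sections"):
            vessel_waveform(tree, ph.velocity, ph.cd, seed, n_sections=10_000)


class TestClassification:
    def test_phantom_artery_vein_purity(self, flow_phantom):
        ph = flow_phantom
        mask = segment_vessels(ph.cd, 10.0)
        tree = skeletonize_tree(mask, ph.spacing)
        waveforms, diameters, _ = branch_waveforms(tree, ph.velocity, ph.cd)
        labels = classify_branches(waveforms, diameters)
        # map each branch to its generating tube class via the label volume
        correct = 0
        for path, lab in zip(tree.branches, labels):
            i, j, k = path[len(path) // 2]
            tube_id = ph.tube_labels[i, j, k]
            true_cls = ph.truth.tubes[tube_id - 1].vessel_class
            got_artery = lab in ("large-artery", "distal-artery")
            correct += got_artery == (true_cls == "artery")
        assert correct == tree.n_branches  # 100% purity

    def test_diameter_threshold_splits_large_and_distal(self):
        arterial = sinusoidal_waveform(100.0, 1.0, 20)
        venous = sinusoidal_waveform(100.0, 0.2, 20)
        waveforms = np.vstack([arterial, arterial, venous])
        diameters = np.array([1.0, 2.0, 3.0])
        labels = classify_branches(waveforms, diameters)
        assert labels == ["distal-artery", "large-artery", "vein"]

    def test_identical_waveforms_degenerate(self):
        w = sinusoidal_waveform(100.0, 0.5, 20)
        with pytest.raises(ValueError, match="manual"):
            classify_branches(np.vstack([w, 2 * w]), np.array([2.0, 2.0]))

    def test_single_branch_rejected(self):
        w = sinusoidal_waveform(100.0, 0.5, 20)
        with pytest.raises(ValueError, match=">= 2"):
            classify_branches(w[None, :], np.array([2.0]))

    def test_prune_list_honored(self):
        arterial = sinusoidal_waveform(100.0, 1.0, 20)
        venous = sinusoidal_waveform(100.0, 0.2, 20)
        waveforms = np.vstack([arterial, venous, arterial])
        labels = classify_branches(
            waveforms, np.array([2.0, 2.0, 2.0]), prune=np.array([False, False, True])
        )
        assert labels[2] == "excluded"

    def test_vesselness_enhances_tubes(self, flow_phantom):
        v = vesselness(flow_phantom.cd, scales=(1.0,))
        inside = v[flow_phantom.tube_labels > 0].mean()
        outside = v[flow_phantom.tube_labels == 0].mean()
        assert inside > outside


class TestDistalWaveform:
    def test_scale_invariance_of_shape(self):
        shape = sinusoidal_waveform(1.0, 0.9, 20)
        voxels = np.vstack([k * shape for k in (0.5, 1.0, 7.0)])
        w = distal_waveform(voxels)
        assert w.normalized
        np.testing.assert_allclose(w.flow, shape / shape.mean(), rtol=1e-12)

    def test_outlier_voxel_ignored_by_median(self):
        shape = sinusoidal_waveform(1.0, 0.9, 20)
        clean = np.vstack([shape] * 99)
        outlier = shape + np.linspace(0, 5, 20)
        w = distal_waveform(np.vstack([clean, outlier[None, :]]))
        np.testing.assert_allclose(w.flow, shape / shape.mean(), rtol=1e-12)

    def test_phantom_distal_pi_close_to_truth(self, flow_phantom):
        ph = flow_phantom
        mask = segment_vessels(ph.cd, 10.0)
        tree = skeletonize_tree(mask, ph.spacing)
        waveforms, diameters, per_voxel = branch_waveforms(tree, ph.velocity, ph.cd)
        labels = classify_branches(waveforms, diameters)
        distal = [pv for pv, lab in zip(per_voxel, labels) if lab == "distal-artery"]
        assert distal
        w = distal_waveform(distal)
        assert pulsatility_index(w).pi == pytest.approx(0.99, abs=0.05)


class TestPulsatility:
    def test_constant_waveform_zero_pi(self):
        res = pulsatility_index(FlowWaveform(np.full(20, 250.0)))
        assert res.pi == pytest.approx(0.0, abs=1e-12)

    def test_sine_closed_form(self):
        t = np.arange(20) / 20
        w = FlowWaveform(1.0 + 0.5 * np.sin(2 * np.pi * t))
        res = pulsatility_index(w)
        assert res.pi == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_scale_invariance(self, k):
        t = np.arange(20) / 20
        base = 1.0 + 0.5 * np.sin(2 * np.pi * t)
        assert pulsatility_index(FlowWaveform(k * base)).pi == pytest.approx(
            pulsatility_index(FlowWaveform(base)).pi, rel=1e-12
        )

    def test_bandlimited_interpolation_fidelity(self):
        """Spline PI within 2% of the analytic PI for <= 6 harmonics."""
        rng = np.random.default_rng(0)
        t20 = np.arange(20) / 20
        t_fine = np.arange(20000) / 20000
        for _ in range(5):
            # harmonic amplitudes decay ~1/h^2, as in arterial flow spectra
            coeff = rng.normal(0, 0.3, size=(6, 2)) / np.arange(1, 7)[:, None] ** 2
            def wave(t):
                out = np.ones_like(t)
                for h, (a, b) in enumerate(coeff, start=1):
                    out += a * np.cos(2 * np.pi * h * t) + b * np.sin(2 * np.pi * h * t)
                return out
            analytic = wave(t_fine)
            pi_true = (analytic.max() - analytic.min()) / analytic.mean()
            pi_est = pulsatility_index(FlowWaveform(wave(t20))).pi
            assert pi_est == pytest.approx(pi_true, rel=0.02)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            pulsatility_index(FlowWaveform(np.linspace(-2, 1, 20)))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="4"):
            interpolate_waveform(FlowWaveform(np.ones(3)))


class TestTotalCBF:
    def test_sum_of_means(self):
        mk = lambda m: FlowWaveform(sinusoidal_waveform(m, 0.5, 20))
        assert total_cbf(mk(300.0), mk(250.0), mk(150.0)) == pytest.approx(700.0, rel=1e-12)

    def test_normalized_waveforms_rejected(self):
        w = FlowWaveform(np.ones(20), normalized=True)
        with pytest.raises(ValueError, match="unnormalized"):
            total_cbf(w, w, w)

    def test_ica_averaging(self):
        a = FlowWaveform(sinusoidal_waveform(200.0, 1.0, 20))
        b = FlowWaveform(sinusoidal_waveform(300.0, 1.0, 20))
        avg = average_waveforms(a, b)
        np.testing.assert_allclose(avg.flow, (a.flow + b.flow) / 2, rtol=1e-14)
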