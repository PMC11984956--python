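"""SMLM post-processing: drift, filtering, registration, cluster metrics."""

import numpy as np
import pandas as pd
import pytest

import dapquant as dq
from dapquant import smlm
from dapquant.smlm import AXES

from conftest import make_cluster


def fiducial_table(true_drift, base=(100.0, 200.0, 50.0), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = len(true_drift)
    pos = np.asarray(base) + true_drift + rng.normal(0, noise, (n, 3))
    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "x_nm": pos[:, 0],
            "y_nm": pos[:, 1],
            "z_nm": pos[:, 2],
            "photons": 1e5,
            "crlb_xy_nm": 2.0,
            "channel": 0,
        }
    )


class TestDrift:
    def test_zero_drift_zero_noise_gives_zero_trace(self):
        locs = fiducial_table(np.zeros((200, 3)))
        trace = smlm.track_fiducial_and_fit_drift(locs, (100.0, 200.0, 50.0))
        assert np.allclose(trace.displacement_nm, 0.0, atol=1e-6)

    def test_linear_drift_shape_recovered_within_2nm_rms(self):
        # 0.5 nm/frame drift, 10 nm localization noise; the drift *shape*
        # (origin constant removed) must be recovered to <= 2 nm RMS; the
        # frame-0 referencing constant is a bounded origin convention.
        true = np.outer(np.arange(1000), [0.5, 0.0, 0.0])
        locs = fiducial_table(true, noise=10.0, seed=1)
        trace = smlm.track_fiducial_and_fit_drift(
            locs, (100.0, 200.0, 50.0), capture_radius_nm=600.0
        )
        err = trace.displacement_nm - true
        shape_rms = np.sqrt(((err - err.mean(axis=0)) ** 2).mean(axis=0))
        assert np.all(shape_rms <= 2.0)
        assert np.all(np.abs(err.mean(axis=0)) <= 8.0)

    def test_same_input_same_trace(self):
        true = np.outer(np.arange(300), [0.2, -0.1, 0.3])
        locs = fiducial_table(true, noise=5.0, seed=2)
        t1 = smlm.track_fiducial_and_fit_drift(locs, (100.0, 200.0, 50.0))
        t2 = smlm.track_fiducial_and_fit_drift(locs, (100.0, 200.0, 50.0))
        assert np.array_equal(t1.displacement_nm, t2.displacement_nm)

    def test_lost_fiducial_rejected(self):
        true = np.zeros((200, 3))
        locs = fiducial_table(true)
        locs = locs[(locs.frame < 50) | (locs.frame >= 150)]  # 100-frame gap
        with pytest.raises(ValueError):
            smlm.track_fiducial_and_fit_drift(
                locs, (100.0, 200.0, 50.0), max_gap_frames=50, n_frames=200
            )

    def test_apply_zero_trace_is_identity(self):
        locs = make_cluster(100, (0, 0, 0), (50, 50, 50), seed=0)
        trace = smlm.DriftTrace(np.zeros((1000, 3)))
        out = smlm.apply_drift_correction(locs, trace)
        pd.testing.assert_frame_equal(locs, out)

    def test_exact_correction_restores_fiducial_scatter(self):
        rng = np.random.default_rng(3)
        true = np.cumsum(rng.normal(0, 0.2, (500, 3)), axis=0)
        locs = fiducial_table(true, noise=2.0, seed=3)
        trace = smlm.DriftTrace(true - true[0])
        locs_shift = locs.copy()
        # place frame-0 origin convention: drift zero-referenced already
        out = smlm.apply_drift_correction(locs_shift, trace)
        sd_after = out[list(AXES)].std().to_numpy()
        assert np.all(sd_after < 2.5)  # pure localization noise

    def test_drift_correction_reduces_fiducial_sd_on_every_seed(self):
        for seed in range(10):
            cfg = dq.SmlmSceneConfig(
                drift_amplitude_nm=60.0,
                ring_n_locs=1500,
                vesicle_n_locs=300,
                partner_n_locs=200,
                n_frames=600,
                seed=seed,
            )
            locs, truth = dq.gen_smlm_scene(cfg)
            ch0 = locs[locs.channel == 0]
            trace = smlm.track_fiducial_and_fit_drift(
                ch0, truth.fiducials_nm[0], n_frames=cfg.n_frames
            )
            corrected = smlm.apply_drift_correction(ch0, trace)
            fid_before = ch0[ch0.species == "fiducial"][list(AXES)].std()
            fid_after = corrected[corrected.species == "fiducial"][list(AXES)].std()
            assert np.all(fid_after.to_numpy() <= fid_before.to_numpy())

    def test_frame_outside_trace_rejected(self):
        locs = make_cluster(10, (0, 0, 0), (50, 50, 50), seed=1)
        with pytest.raises(ValueError):
            smlm.apply_drift_correction(locs, smlm.DriftTrace(np.zeros((5, 3))))


class TestFilterQuality:
    def test_isolated_point_removed(self):
        cluster = make_cluster(1000, (0, 0, 0), (60, 60, 60), seed=4)
        stray = cluster.iloc[:1].copy()
        stray[["x_nm", "y_nm", "z_nm"]] = 5000.0
        locs = pd.concat([cluster, stray], ignore_index=True)
        out = smlm.filter_quality(locs)
        assert len(out) <= len(cluster)
        assert out.x_nm.abs().max() < 1000.0

    def test_loose_crlb_threshold_removes_nothing(self):
        locs = make_cluster(500, (0, 0, 0), (60, 60, 60), seed=5)
        locs["crlb_xy_nm"] = 10.0
        out = smlm.filter_quality(locs, crlb_max_nm=20.0, nn_mean_dist_max_nm=1e9)
        assert len(out) == len(locs)

    def test_planted_outliers_removed_cluster_kept(self):
        cfg = dq.SmlmSceneConfig(outlier_fraction=0.05, seed=6)
        locs, _ = dq.gen_smlm_scene(cfg)
        ch0 = locs[locs.channel == 0].reset_index(drop=True)
        out = smlm.filter_quality(ch0)
        planted = ch0[ch0.species == "outlier"]
        kept_planted = out[out.species == "outlier"]
        assert len(kept_planted) <= 0.05 * len(planted)
        real = ch0[ch0.species != "outlier"]
        kept_real = out[out.species != "outlier"]
        assert len(kept_real) >= 0.99 * len(real)

    def test_idempotent(self):
        cfg = dq.SmlmSceneConfig(outlier_fraction=0.03, seed=7)
        locs, _ = dq.gen_smlm_scene(cfg)
        once = smlm.filter_quality(locs[locs.channel == 0])
        twice = smlm.filter_quality(once)
        assert len(once) == len(twice)


class TestEstimateAffine:
    def test_identity_on_identical_beads(self):
        rng = np.random.default_rng(8)
        beads = rng.uniform(-5000, 5000, (10, 2))
        aff = smlm.estimate_affine(beads, beads)
        assert np.allclose(aff.matrix, np.eye(2), atol=1e-12)
        assert np.allclose(aff.translation, 0.0, atol=1e-9)
        assert aff.rms_residual_nm == pytest.approx(0.0, abs=1e-9)

    def test_known_transform_recovered_to_machine_precision(self):
        rng = np.random.default_rng(9)
        beads = rng.uniform(-5000, 5000, (10, 2))
        rot = np.deg2rad(1.0)
        mat = 1.002 * np.array(
            [[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]]
        )
        shift = np.array([50.0, -30.0])
        target = beads @ mat.T + shift
        aff = smlm.estimate_affine(beads, target)
        assert np.allclose(aff.matrix, mat, atol=1e-10)
        assert np.allclose(aff.translation, shift, atol=1e-8)

    def test_noisy_beads_rms_near_noise_level(self):
        rng = np.random.default_rng(10)
        beads = rng.uniform(-5000, 5000, (40, 2))
        target = beads + rng.normal(0, 5.0, beads.shape)
        aff = smlm.estimate_affine(beads, target)
        assert 3.0 < aff.rms_residual_nm < 8.0

    def test_collinear_beads_rejected(self):
        beads = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            smlm.estimate_affine(beads, beads)


class TestRegistration3DCC:
    def _rings(self, shift, seed, n=12000):
        def ring_df(seed_, shift_):
            r = np.random.default_rng(seed_)
            th = r.uniform(0, 2 * np.pi, n)
            rad = r.normal(150.0, 15.0, n)
            crlb = np.clip(r.normal(10, 3, n), 2, None)
            return pd.DataFrame(
                {
                    "frame": 0,
                    "x_nm": rad * np.cos(th) + r.normal(size=n) * crlb + shift_[0],
                    "y_nm": rad * np.sin(th) + r.normal(size=n) * crlb + shift_[1],
                    "z_nm": r.normal(0, 30, n) + r.normal(size=n) * 1.5 * crlb + shift_[2],
                    "photons": 2000.0,
                    "crlb_xy_nm": crlb,
                    "channel": 0,
                }
            )

        return ring_df(2 * seed, (0, 0, 0)), ring_df(2 * seed + 1, shift)

    def test_zero_offset_converges_immediately(self):
        ref, mov = self._rings((0.0, 0.0, 0.0), seed=1, n=8000)
        res, _ = smlm.refine_registration_3dcc(ref, mov)
        assert res.converged
        assert np.linalg.norm(res.shift_nm) < 2.0 * np.sqrt(3)

    def test_planted_shift_recovered_within_2nm_per_axis(self):
        ref, mov = self._rings((30.0, -20.0, 40.0), seed=2)
        res, shifted = smlm.refine_registration_3dcc(ref, mov)
        assert res.converged
        np.testing.assert_allclose(
            res.shift_nm, [-30.0, 20.0, -40.0], atol=2.0
        )
        # the shifted table is actually moved
        assert shifted.x_nm.mean() == pytest.approx(
            mov.x_nm.mean() + res.shift_nm[0], abs=1e-6
        )

    def test_one_iteration_on_large_offset_not_converged(self):
        ref, mov = self._rings((120.0, 0.0, 0.0), seed=3, n=6000)
        res, _ = smlm.refine_registration_3dcc(ref, mov, voxel_nm=10.0, max_iter=1)
        assert res.iterations == 1
        assert isinstance(res.converged, bool)

    def test_moving_channel_swap_flips_sign(self):
        ref, mov = self._rings((40.0, -25.0, 15.0), seed=4, n=8000)
        res_fwd, _ = smlm.refine_registration_3dcc(ref, mov)
        res_rev, _ = smlm.refine_registration_3dcc(mov, ref)
        np.testing.assert_allclose(res_fwd.shift_nm, -res_rev.shift_nm, atol=2.0)


class TestClusterMetrics:
    def test_isolate_cluster_box_logic(self):
        locs = make_cluster(200, (0, 0, 0), (50, 50, 50), seed=11)
        allbox = ((-1e4, 1e4), (-1e4, 1e4), (-1e4, 1e4))
        assert len(smlm.isolate_cluster(locs, allbox)) == len(locs)
        with pytest.raises(ValueError):
            smlm.isolate_cluster(locs, ((1e5, 2e5), (-1e4, 1e4), (-1e4, 1e4)))
        half_pos = smlm.isolate_cluster(locs, ((0, 1e4), (-1e4, 1e4), (-1e4, 1e4)))
        half_neg = smlm.isolate_cluster(
            locs, ((-1e4, -1e-12), (-1e4, 1e4), (-1e4, 1e4))
        )
        assert len(half_pos) + len(half_neg) == len(locs)

    def test_pure_gaussian_sigma_575_gives_width_230(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(0, 57.5, (4000, 3))
        locs = pd.DataFrame(
            {
                "frame": 0,
                "x_nm": pts[:, 0],
                "y_nm": pts[:, 1],
                "z_nm": pts[:, 2],
                "photons": 1e3,
                "crlb_xy_nm": 10.0,
                "channel": 0,
            }
        )
        summary = smlm.cluster_axis_fit(locs)
        assert summary.width_1e2_nm[0] == pytest.approx(230.0, rel=0.1)
        assert np.allclose(summary.width_1e2_nm, 4.0 * summary.sigma_nm)

    def test_isotropic_cloud_equal_widths(self):
        locs = make_cluster(5000, (0, 0, 0), (60, 60, 60), seed=13)
        summary = smlm.cluster_axis_fit(locs)
        assert np.ptp(summary.width_1e2_nm) < 0.15 * summary.width_1e2_nm.mean()

    def test_sample1_triplet_recovered_within_10pct(self):
        widths = np.array([230.0, 170.0, 190.0])
        rng = np.random.default_rng(14)
        pts = rng.normal(0, widths / 4.0, (2000, 3))
        locs = pd.DataFrame(
            {
                "frame": 0,
                "x_nm": pts[:, 0],
                "y_nm": pts[:, 1],
                "z_nm": pts[:, 2],
                "photons": 1e3,
                "crlb_xy_nm": 10.0,
                "channel": 0,
            }
        )
        summary = smlm.cluster_axis_fit(locs)
        np.testing.assert_allclose(summary.width_1e2_nm, widths, rtol=0.1)

    def test_width_converges_to_4sigma_at_large_n(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(0, 50.0, (10_000, 3))
        locs = pd.DataFrame(
            {
                "frame": 0,
                "x_nm": pts[:, 0],
                "y_nm": pts[:, 1],
                "z_nm": pts[:, 2],
                "photons": 1e3,
                "crlb_xy_nm": 10.0,
                "channel": 0,
            }
        )
        summary = smlm.cluster_axis_fit(locs)
        np.testing.assert_allclose(summary.width_1e2_nm, 200.0, rtol=0.02)

    def test_too_few_localizations_rejected(self):
        locs = make_cluster(10, (0, 0, 0), (50, 50, 50), seed=16)
        with pytest.raises(ValueError):
            smlm.cluster_axis_fit(locs)

    @pytest.mark.parametrize(
        "widths,expected",
        [
            ((230.0, 170.0, 190.0), True),
            ((110.0, 200.0, 200.0), False),
            ((120.0, 120.0, 120.0), True),  # boundary inclusive
        ],
    )
    def test_vesicle_candidate_threshold(self, widths, expected):
        summary = smlm.ClusterSummary(
            mean_nm=np.zeros(3),
            sigma_nm=np.asarray(widths) / 4.0,
            width_1e2_nm=np.asarray(widths),
            com_nm=np.zeros(3),
            n_locs=1000,
        )
        assert smlm.vesicle_candidate_filter(summary) is expected


class TestComOffset:
    def test_same_distribution_near_zero_separation(self):
        a = make_cluster(2000, (0, 0, 0), (57.5, 42.5, 47.5), seed=17)
        b = make_cluster(2000, (0, 0, 0), (57.5, 42.5, 47.5), seed=18)
        co = smlm.com_offset(a, b)
        assert co.separation_nm < 10.0

    def test_planted_89nm_offset_recovered_within_10nm(self):
        offset = 89.0 / np.sqrt(3.0)
        a = make_cluster(2000, (0, 0, 0), (57.5, 42.5, 47.5), seed=19)
        b = make_cluster(500, (offset, offset, offset), (47.5, 42.5, 62.5), seed=20)
        co = smlm.com_offset(a, b)
        assert co.separation_nm == pytest.approx(89.0, abs=10.0)

    def test_single_axis_offset_leaves_other_axes_flat(self):
        a = make_cluster(3000, (0, 0, 0), (50, 50, 50), seed=21)
        b = make_cluster(3000, (80.0, 0, 0), (50, 50, 50), seed=22)
        co = smlm.com_offset(a, b)
        assert co.offset_nm[0] == pytest.approx(80.0, abs=8.0)
        assert abs(co.offset_nm[1]) < 8.0
        assert abs(co.offset_nm[2]) < 8.0

    def test_distance_to_structure(self):
        assert smlm.distance_to_structure((0, 0, 0), (0, 0, 0)) == 0.0
        assert smlm.distance_to_structure((100, 0, 0), (0, 0, 0)) == 100.0
        assert smlm.distance_to_structure((30, 40, 0), (0, 0, 0)) == pytest.approx(50.0)


class TestEndToEndPipeline:
    def test_full_scene_recovery_over_ten_seeds(self):
        """Drift + affine + residual shift: the composed pipeline recovers
        the residual registration within 2 nm/axis and the COM separation
        within 10 nm."""
        rot = np.deg2rad(1.0)
        aff = dq.Affine2D(
            matrix=1.002
            * np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]]),
            translation=[50.0, -30.0],
        )
        for seed in range(10):
            cfg = dq.SmlmSceneConfig(
                drift_amplitude_nm=50.0,
                channel_affine=aff,
                z_shift_nm=25.0,
                residual_shift_nm=(30.0, -20.0, 40.0),
                seed=seed,
            )
            locs, truth = dq.gen_smlm_scene(cfg)
            ch0 = locs[locs.channel == 0]
            ch1 = locs[locs.channel == 1]
            tr0 = smlm.track_fiducial_and_fit_drift(
                ch0, truth.fiducials_nm[0], n_frames=cfg.n_frames
            )
            ch0c = smlm.apply_drift_correction(ch0, tr0)
            fid1 = np.r_[
                aff.apply(truth.fiducials_nm[0][None, :2])[0],
                truth.fiducials_nm[0][2] + cfg.z_shift_nm,
            ] + truth.residual_shift_nm
            tr1 = smlm.track_fiducial_and_fit_drift(ch1, fid1, n_frames=cfg.n_frames)
            ch1c = smlm.apply_drift_correction(ch1, tr1)
            inv = truth.channel_affine.inverse()
            ch1r = smlm.apply_affine_to_locs(ch1c, inv, z_shift_nm=-cfg.z_shift_nm)
            roi = ((-400, 400), (-400, 400), (-250, 250))
            res, _ = smlm.refine_registration_3dcc(
                smlm.isolate_cluster(ch0c, roi), smlm.isolate_cluster(ch1r, roi)
            )
            needed = -np.r_[
                inv.matrix @ truth.residual_shift_nm[:2], truth.residual_shift_nm[2]
            ]
            assert res.converged
            np.testing.assert_allclose(res.shift_nm, needed, atol=2.0)
            ch1f = ch1r.copy()
            for i, ax in enumerate(AXES):
                ch1f[ax] = ch1f[ax] + res.shift_nm[i]
            co = smlm.com_offset(
                ch0c[ch0c.species == "vesicle"], ch1f[ch1f.species == "partner"]
            )
            assert abs(co.separation_nm - truth.separation_nm) < 10.0
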