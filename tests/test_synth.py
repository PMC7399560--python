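"""Wormlike-chain generator, bundle decoration, fixtures, linking balance.
"""

import numpy as np
import pytest

from chiralfil import spectra, synth, twistwrithe as twr
from chiralfil.constants import TW0_TURNS_PER_NM


def straight_line(nbp, rise=0.34):
    pts = np.zeros((nbp + 1, 3))
    pts[:, 2] = np.arange(nbp + 1) * rise
    return pts


class TestSampleCenterline:
    def test_rigid_rod_limit(self):
        p = synth.ChainParameters(contour_length=100.0, segment_length=1.0,
                                  persistence_length=1e10 * 100.0)
        pts, frames = synth.sample_centerline(
            p, np.random.default_rng(0))
        t = frames[:, 0, :]
        assert np.abs(t - t[0]).max() < 1e-3
        assert np.linalg.norm(pts[-1] - pts[0]) == pytest.approx(
            100.0, rel=1e-6)

    def test_persistence_length_recovered(self):
        """Tangent correlations of 500 chains fit exp(-d/l_p) within 10%."""
        lc, lp = 420.0, 8 * 420.0
        p = synth.ChainParameters(contour_length=lc, segment_length=2.1,
                                  persistence_length=lp)
        rng = np.random.default_rng(11)
        lags = np.array([20, 50, 100])  # segments
        corr = np.zeros(lags.size)
        n = 500
        for _ in range(n):
            _, frames = synth.sample_centerline(p, rng)
            t = frames[:, 0, :]
            for i, d in enumerate(lags):
                corr[i] += np.mean(np.sum(t[:-d] * t[d:], axis=1))
        corr /= n
        lp_est = -lags * 2.1 / np.log(corr)
        assert np.all(np.abs(lp_est - lp) / lp < 0.10)

    def test_noiseless_solenoid_has_positive_writhe(self):
        """Right-handed intrinsic curvature/torsion -> polar writhe > 0."""
        kap, tau = synth.solenoid_curvature_torsion(2.0, 5.0, 420.0)
        p = synth.ChainParameters(contour_length=420.0, segment_length=0.42,
                                  persistence_length=1e6 * 420.0,
                                  intrinsic_curvature=kap,
                                  intrinsic_torsion=tau)
        pts, _ = synth.sample_centerline(p, np.random.default_rng(0))
        from chiralfil.geometry import polar_writhe_points, gyration_axes
        axis = gyration_axes(pts)[1][:, 0]
        if axis @ (pts[-1] - pts[0]) < 0:
            axis = -axis
        assert polar_writhe_points(pts, axis) > 0

    def test_coarse_discretization_rejected(self):
        p = synth.ChainParameters(contour_length=100.0, segment_length=1.0,
                                  persistence_length=0.5)
        with pytest.raises(ValueError, match="too coarse"):
            synth.sample_centerline(p, np.random.default_rng(0))


class TestDecorateBundle:
    def test_relaxed_winding_gives_zero_overtwist(self):
        geom = synth.BundleGeometry(bp_count=320)
        conf = synth.decorate_bundle(straight_line(320), geom,
                                     synth.LinkingTarget(0.0, "rigid"),
                                     0.0, 320 * 0.34, "s")
        conf.validate()
        assert abs(twr.overtwist(conf)) < 0.05  # turns/um

    def test_overwound_winding_closed_form(self):
        """10.0 bp/turn -> DeltaTw = (1/10 - 1/10.5)/0.34 nm in turns/um."""
        geom = synth.BundleGeometry(bp_count=320, bp_per_turn=10.0)
        conf = synth.decorate_bundle(straight_line(320), geom,
                                     synth.LinkingTarget(0.0, "rigid"),
                                     0.0, 320 * 0.34, "ow")
        expected = (1 / 10.0 - 1 / 10.5) / 0.34 * 1e3
        assert twr.overtwist(conf) == pytest.approx(expected, abs=0.05)

    def test_mirror_flips_chirality_measures(self):
        geom = synth.BundleGeometry(bp_count=150)
        conf = synth.decorate_bundle(straight_line(150), geom,
                                     synth.LinkingTarget(0.0, "rigid"),
                                     -10.0, 150 * 0.34, "tw")
        tw_orig = twr.duplex_twist(conf, trim_bp=5)
        tw_mirror = twr.duplex_twist(conf.mirrored(), trim_bp=5)
        np.testing.assert_allclose(tw_mirror, -tw_orig, rtol=1e-9)

    def test_geometry_invariant_violation_raises(self):
        geom = synth.BundleGeometry(bp_count=150, hex_radius=5.0)
        with pytest.raises(ValueError, match="diameter"):
            synth.decorate_bundle(straight_line(150), geom,
                                  synth.LinkingTarget(0.0, "rigid"),
                                  0.0, 150 * 0.34)


class TestGenerateEnsemble:
    def test_seeded_determinism(self):
        kw = dict(n=4, seed=99)
        p = synth.ChainParameters(contour_length=51.0,
                                  persistence_length=8 * 51.0)
        g = synth.BundleGeometry(bp_count=150)
        k = synth.LinkingTarget(3.0)
        a = synth.generate_ensemble(p, g, k, **kw)
        b = synth.generate_ensemble(p, g, k, **kw)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.positions, cb.positions)

    def test_achiral_null(self):
        """design_overtwist = 0: no helicity bias beyond noise."""
        p = synth.ChainParameters(contour_length=51.0,
                                  persistence_length=8 * 51.0)
        g = synth.BundleGeometry(bp_count=150)
        ens = synth.generate_ensemble(p, g, synth.LinkingTarget(0.0),
                                      n=60, seed=5)
        es = spectra.ensemble_helicity(ens, trim_bp=5, smooth_window=None)
        frac = np.mean(np.abs(es.H_mean[1:]) < 2.0 * es.H_se[1:])
        # ~95% expected for a null; 90% bounds the binomial fluctuation
        assert frac > 0.90

    def test_overwound_design_gives_positive_writhe(self, lh_ensemble):
        res = twr.ensemble_twist_writhe(lh_ensemble, trim_bp=5)
        assert res.writhe_mean > 3 * res.writhe_se

    def test_linking_balance(self, lh_ensemble):
        """<DeltaTw> + <Wr in turns/um> = design overtwist within 3 SE."""
        res = twr.ensemble_twist_writhe(lh_ensemble, trim_bp=5)
        balance = res.delta_tw_mean + res.writhe_mean / 1.0e3
        se = np.hypot(res.delta_tw_se, res.writhe_se / 1.0e3)
        # trimming removes a little built twist; allow 3 SE + 2% of target
        assert abs(balance - 6.0) < 3 * se + 0.12

    def test_iid_ensemble_decorrelates(self, lh_ensemble):
        ac = synth.end_to_end_autocorrelation(lh_ensemble)
        assert ac[0] == pytest.approx(1.0)
        assert np.all(np.abs(ac[1:]) < 0.5)


class TestFixtures:
    def test_ideal_helix_unit_helicity_exact_frame(self):
        pts, (u, v, w) = synth.ideal_helix_curve(420.0, 1.0, 3, 1, 1024)
        bb = spectra.BackboneCurve(pts - pts.mean(axis=0), 420.0 / 1024,
                                   420.0)
        frame = spectra.MolecularFrame(u, v, w)
        rp = spectra.transverse_displacement(bb, frame)
        spec = spectra.helicity_spectrum(rp, frame, bb.ds, 420.0)
        assert abs(spec.H[3] - 1.0) < 1e-6

    def test_rod_fixture_has_zero_helicity(self):
        spec = spectra.conformation_helicity(synth.make_straight_rod(),
                                             trim_bp=0)
        np.testing.assert_allclose(spec.H, 0.0, atol=1e-9)

    def test_handedness_flag_flips_sign_only(self):
        right = synth.make_ideal_helix(420.0, 4.0, 3, +1, 512)
        left = synth.make_ideal_helix(420.0, 4.0, 3, -1, 512)
        sr = spectra.conformation_helicity(right, trim_bp=0)
        sl = spectra.conformation_helicity(left, trim_bp=0)
        np.testing.assert_allclose(sl.H, -sr.H, atol=1e-9)
        pr = sr.c_vv + sr.c_ww
        pl = sl.c_vv + sl.c_ww
        np.testing.assert_allclose(pl, pr, rtol=1e-6,
                                   atol=1e-9 * pr.max())
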