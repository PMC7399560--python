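"""Backbone extraction, gyration frame, and the helicity spectrum H(k)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.spatial.transform import Rotation

from chiralfil import spectra, synth


def random_backbone(n=256, lc=100.0, sigma=2.0, seed=0):
    """Backbone with Gaussian transverse displacements on a straight rod."""
    rng = np.random.default_rng(seed)
    pts = np.zeros((n, 3))
    pts[:, 2] = np.arange(n) * lc / n
    pts[:, :2] = rng.normal(0.0, sigma, size=(n, 2))
    pts -= pts.mean(axis=0)
    return spectra.BackboneCurve(pts, lc / n, lc)


class TestExtractBackbone:
    def test_straight_bundle_is_collinear(self):
        geom = synth.BundleGeometry(bp_count=200)
        line = np.zeros((201, 3))
        line[:, 2] = np.arange(201) * 0.34
        conf = synth.decorate_bundle(line, geom,
                                     synth.LinkingTarget(0.0, "rigid"),
                                     0.0, 200 * 0.34)
        bb = spectra.extract_backbone(conf, trim_bp=0)
        t = bb.positions[-1] - bb.positions[0]
        t /= np.linalg.norm(t)
        transverse = bb.positions - np.outer(bb.positions @ t, t)
        assert np.abs(transverse).max() < 1e-6

    def test_helix_amplitude_recovered(self):
        conf = synth.make_ideal_helix(420.0, 4.0, 3, 1, 1024)
        bb = spectra.extract_backbone(conf, trim_bp=0)
        # measure against the fixture's own axis (z after centering)
        u = np.array([0.0, 0.0, 1.0])
        rp = bb.positions - np.outer(bb.positions @ u, u)
        amp = np.linalg.norm(rp, axis=1)
        np.testing.assert_allclose(amp, 4.0, rtol=0.01)

    def test_trim_count(self):
        geom = synth.BundleGeometry(bp_count=1235)
        line = np.zeros((1236, 3))
        line[:, 2] = np.arange(1236) * 0.34
        conf = synth.decorate_bundle(line, geom,
                                     synth.LinkingTarget(0.0, "rigid"),
                                     0.0, 1235 * 0.34)
        bb = spectra.extract_backbone(conf, trim_bp=10)
        assert bb.n == 1235 - 20


class TestGyrationFrame:
    def test_rod_axis_and_sign_rule(self):
        bb = random_backbone(sigma=0.0)
        frame = spectra.gyration_frame(bb)
        np.testing.assert_allclose(np.abs(frame.u), [0, 0, 1], atol=1e-9)
        assert frame.u @ (bb.positions[-1] - bb.positions[0]) > 0

    def test_rotation_equivariance(self):
        bb = random_backbone(sigma=2.0, seed=3)
        Q = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        rotated = spectra.BackboneCurve(bb.positions @ Q.T, bb.ds,
                                        bb.contour_length)
        f1 = spectra.gyration_frame(bb)
        f2 = spectra.gyration_frame(rotated)
        np.testing.assert_allclose(f2.u, Q @ f1.u, atol=1e-9)
        np.testing.assert_allclose(f2.v, Q @ f1.v, atol=1e-9)
        np.testing.assert_allclose(f2.w, Q @ f1.w, atol=1e-9)

    def test_planar_arc_minimum_dispersion_normal(self):
        s = np.linspace(0, np.pi / 2, 200)
        pts = np.column_stack([np.cos(s) * 50, np.zeros_like(s),
                               np.sin(s) * 50])
        pts -= pts.mean(axis=0)
        bb = spectra.BackboneCurve(pts, 1.0, 200.0)
        frame = spectra.gyration_frame(bb)
        assert abs(abs(frame.v[1]) - 1.0) < 1e-9

    def test_frame_is_right_handed_orthonormal(self):
        frame = spectra.gyration_frame(random_backbone(sigma=1.5, seed=9))
        M = frame.as_matrix()
        np.testing.assert_allclose(M.T @ M, np.eye(3), atol=1e-12)
        assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-12)


class TestTransverseDisplacement:
    def test_projection_and_pythagoras(self):
        bb = random_backbone(sigma=2.0, seed=4)
        frame = spectra.gyration_frame(bb)
        rp = spectra.transverse_displacement(bb, frame)
        assert np.abs(rp @ frame.u).max() < 1e-9
        r2 = np.sum(bb.positions ** 2, axis=1)
        ru2 = (bb.positions @ frame.u) ** 2
        np.testing.assert_allclose(r2, ru2 + np.sum(rp ** 2, axis=1),
                                   rtol=1e-9)

    def test_explicit_example(self):
        frame = spectra.MolecularFrame(np.array([0.0, 0, 1]),
                                       np.array([1.0, 0, 0]),
                                       np.array([0.0, 1, 0]))
        bb = spectra.BackboneCurve(np.array([[1.0, 2.0, 3.0]]), 1.0, 1.0)
        rp = spectra.transverse_displacement(bb, frame)
        np.testing.assert_allclose(rp[0], [1.0, 2.0, 0.0])


class TestHelicitySpectrum:
    def test_zero_mode_vanishes_for_any_conformation(self):
        for seed in range(5):
            bb = random_backbone(seed=seed)
            frame = spectra.gyration_frame(bb)
            rp = spectra.transverse_displacement(bb, frame)
            spec = spectra.helicity_spectrum(rp, frame, bb.ds,
                                             bb.contour_length)
            assert spec.H[0] == 0.0

    def test_bounded_by_one_in_magnitude(self):
        """|H| <= 1 over 200 random transverse-displacement fields."""
        rng = np.random.default_rng(12)
        frame = spectra.MolecularFrame(np.array([0.0, 0, 1]),
                                       np.array([1.0, 0, 0]),
                                       np.array([0.0, 1, 0]))
        for _ in range(200):
            n = int(rng.integers(16, 200))
            rp = np.zeros((n, 3))
            rp[:, :2] = rng.normal(0, rng.uniform(0.1, 5.0), (n, 2))
            spec = spectra.helicity_spectrum(rp, frame, 1.0, float(n))
            assert np.all(np.abs(spec.H) <= 1.0 + 1e-12)

    def test_parseval_consistency(self):
        bb = random_backbone(seed=21, n=128)
        frame = spectra.gyration_frame(bb)
        rp = spectra.transverse_displacement(bb, frame)
        spec = spectra.helicity_spectrum(rp, frame, bb.ds,
                                         bb.contour_length)
        # one-sided rfft: double the interior bins
        power = spec.c_vv + spec.c_ww
        weight = np.full(power.size, 2.0)
        weight[0] = 1.0
        if bb.n % 2 == 0:
            weight[-1] = 1.0
        lhs = np.sum(weight * power) / (bb.n * bb.ds ** 2)
        rhs = np.sum(rp ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, st.tuples(st.integers(16, 96),
                                            st.just(2)),
                      elements=st.floats(-50.0, 50.0)))
    def test_invariants_for_arbitrary_displacements(self, xy):
        """H(0) = 0, |H| <= 1, and mirror antisymmetry hold for any
        transverse displacement field."""
        frame = spectra.MolecularFrame(np.array([0.0, 0, 1]),
                                       np.array([1.0, 0, 0]),
                                       np.array([0.0, 1, 0]))
        n = xy.shape[0]
        rp = np.zeros((n, 3))
        rp[:, :2] = xy
        spec = spectra.helicity_spectrum(rp, frame, 1.0, float(n))
        assert spec.H[0] == 0.0
        assert np.all(np.abs(spec.H) <= 1.0 + 1e-12)
        rp_m = rp * np.array([1.0, -1.0, 1.0])  # reflect across (u, v)
        spec_m = spectra.helicity_spectrum(rp_m, frame, 1.0, float(n))
        np.testing.assert_allclose(spec_m.H, -spec.H, atol=1e-12)

    def test_mirror_antisymmetry(self):
        conf = synth.make_ideal_helix(100.0, 3.0, 2, 1, 256)
        s1 = spectra.conformation_helicity(conf, trim_bp=0)
        s2 = spectra.conformation_helicity(conf.mirrored(), trim_bp=0)
        np.testing.assert_allclose(s2.H, -s1.H, atol=1e-9)

    def test_rigid_motion_invariance(self):
        conf = synth.make_ideal_helix(100.0, 3.0, 2, 1, 256)
        Q = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        moved = synth.FilamentConformation(
            conf.positions @ Q.T + np.array([5.0, -3.0, 2.0]),
            conf.base_vectors @ Q.T, conf.normal_vectors @ Q.T,
            conf.strand_id, conf.duplex_id, conf.bp_index,
            conf.n_duplex, conf.contour_length, conf.diameter, "moved")
        s1 = spectra.conformation_helicity(conf, trim_bp=0)
        s2 = spectra.conformation_helicity(moved, trim_bp=0)
        np.testing.assert_allclose(s2.H, s1.H, atol=1e-8)


class TestEnsembleHelicity:
    def test_biased_ensemble_positive_at_low_k_with_kmin_peak(self):
        """Long-wavelength right-handed bias: <H> > 0 peaking at k_min."""
        lc = 105.0
        p = synth.ChainParameters(contour_length=lc, segment_length=0.34,
                                  persistence_length=25 * lc)
        g = synth.BundleGeometry(bp_count=int(lc / 0.34))
        # ~1 solenoid turn: bias at the longest accessible wavelength
        link = synth.LinkingTarget(design_overtwist=4.0,
                                   writhe_coupling=0.25,
                                   solenoid_amplitude=3.0)
        ens = synth.generate_ensemble(p, g, link, n=25, seed=8)
        es = spectra.ensemble_helicity(ens, trim_bp=5, smooth_window=None)
        assert es.H_mean[1] > 3 * es.H_se[1]
        assert np.argmax(np.abs(es.H_mean[1:])) == 0

    def test_inconsistent_grids_rejected(self, lh_ensemble):
        short = synth.make_ideal_helix(105.0, 3.0, 2, 1, 64)
        from chiralfil.io import ConformationEnsemble
        mixed = ConformationEnsemble([lh_ensemble[0], short], {})
        with pytest.raises(ValueError):
            spectra.ensemble_helicity(mixed, trim_bp=5, smooth_window=None)


class TestWlcReferenceSpectrum:
    def test_linear_in_inverse_persistence_length(self):
        k = np.array([0.01, 0.02, 0.05])
        s1 = spectra.wlc_reference_spectrum(k, 1000.0, 420.0)
        s2 = spectra.wlc_reference_spectrum(k, 2000.0, 420.0)
        np.testing.assert_allclose(s1, 2.0 * s2, rtol=1e-12)

    def test_generated_ensemble_matches_equipartition(self):
        """Bending-mode slope -4 within 0.3; exact-sum power within a
        factor 2 of the covariance-exact reference over the first decade.
        """
        from chiralfil.geometry import resample_uniform
        lc, lp = 420.0, 8 * 420.0
        p = synth.ChainParameters(contour_length=lc, segment_length=0.84,
                                  persistence_length=lp)
        rng = np.random.default_rng(17)
        power = None
        mode_power = None
        n = 300
        for _ in range(n):
            pts, _ = synth.sample_centerline(p, rng)
            uni, ds = resample_uniform(pts, 500)
            uni -= uni.mean(axis=0)
            bb = spectra.BackboneCurve(uni, ds, 500 * ds)
            frame = spectra.gyration_frame(bb)
            rp = spectra.transverse_displacement(bb, frame)
            spec = spectra.helicity_spectrum(rp, frame, bb.ds,
                                             bb.contour_length)
            p_this = spec.c_vv + spec.c_ww
            power = p_this if power is None else power + p_this
            km, pm = spectra.bending_mode_spectrum(rp, frame, bb.ds)
            mode_power = pm if mode_power is None else mode_power + pm
        power /= n
        mode_power /= n
        # the 1/(l_p k^4) bending law lives in mode space (the exact-sum
        # transform of an open filament carries boundary leakage)
        lo = slice(1, 10)  # modes 2..10
        slope = np.polyfit(np.log(km[lo]), np.log(mode_power[lo]), 1)[0]
        assert slope == pytest.approx(-4.0, abs=0.3)
        k = spec.wavenumbers
        ref = spectra.wlc_reference_spectrum(k[1:11], lp,
                                             bb.contour_length)
        ratio = power[1:11] / ref
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)
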