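"""Onsager virial stage: kernel MC, orientation distribution, elastic
constants, binodals, chiral PMF, bootstrap convergence.

The hard-spherocylinder system doubles as the conventions oracle: its
excluded volume is known in closed form and its second-virial functional
can be minimized directly on a grid, independently of the Picard /
coexistence solvers under test.
"""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize

from chiralfil import interactions as itx
from chiralfil import virial as vr


def exact_kernel_bin_averaged(edges, length, diameter, sub=8):
    """Closed-form spherocylinder kernel averaged over each cos-theta bin.
    """
    n = edges.size - 1
    out = np.zeros((n, n))
    for i in range(n):
        xs = np.linspace(edges[i], edges[i + 1], sub + 1)[:-1] \
            + (edges[i + 1] - edges[i]) / (2 * sub)
        row = vr.spherocylinder_kernel_exact(xs, length, diameter)
        # row is (sub, sub) for xs vs xs; need cross-bin averages
        for j in range(n):
            ys = np.linspace(edges[j], edges[j + 1], sub + 1)[:-1] \
                + (edges[j + 1] - edges[j]) / (2 * sub)
            grid = np.concatenate([xs, ys])
            kk = vr.spherocylinder_kernel_exact(grid, length, diameter)
            out[i, j] = kk[:sub, sub:].mean()
    return out


# ---------------------------------------------------------------------------
# Independent oracle: direct grid minimization of the Onsager functional
# ---------------------------------------------------------------------------

def free_energy_direct(kg, x, w, rho, g):
    """beta f0 on the GL grid for psi = exp(g)/Z (any g)."""
    psi = np.exp(g - g.max())
    psi /= 0.5 * np.sum(w * psi)
    entropy = 0.5 * np.sum(w * psi * np.log(np.maximum(psi, 1e-300)))
    pair = -0.125 * psi @ (kg * np.outer(w, w)) @ psi
    return rho * (np.log(rho) - 1.0) + rho * entropy + rho ** 2 * pair


def minimize_direct(kg, x, w, rho, seed_g=None):
    g0 = seed_g if seed_g is not None else 5.0 * x ** 2
    res = minimize(lambda g: free_energy_direct(kg, x, w, rho, g), g0,
                   method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return res.fun, res.x


def coexistence_direct(kg, x, w, bracket, n_grid=60):
    """Common-tangent construction on directly minimized free energies.

    Scans the aligned branch by direct minimization (keeping only
    genuinely ordered solutions, S > 0.3), then searches the common
    tangent between the isotropic closed form and the splined ordered
    branch on a fine grid before polishing with a root solve.
    """
    from scipy.interpolate import CubicSpline
    from scipy.optimize import fsolve
    rhos_all = np.linspace(bracket[0], bracket[1], n_grid)
    rhos, f_nem = [], []
    g = None
    p2 = 0.5 * (3 * x ** 2 - 1)
    for r in rhos_all:
        f, g = minimize_direct(kg, x, w, r, g)
        psi = np.exp(g - g.max())
        psi /= 0.5 * np.sum(w * psi)
        if 0.5 * np.sum(w * psi * p2) > 0.3:
            rhos.append(r)
            f_nem.append(f)
    rhos = np.array(rhos)
    f_n = CubicSpline(rhos, np.array(f_nem))
    a2_iso = -0.125 * np.sum(np.outer(w, w) * kg)

    def f_i(r):
        return r * (np.log(r) - 1.0) + r ** 2 * a2_iso

    def mu_i(r):
        return np.log(r) + 2.0 * r * a2_iso

    def eqs(v):
        r1, r2 = v
        mu_n = f_n(r2, 1)
        return [mu_i(r1) - mu_n,
                (f_n(r2) - f_i(r1)) - mu_n * (r2 - r1)]

    # coarse common-tangent search for the initial guess
    r1_grid = np.linspace(bracket[0], rhos[-1], 80)
    r2_grid = np.linspace(rhos[0], rhos[-1], 80)
    best, guess = np.inf, None
    for r1 in r1_grid:
        res = np.abs(eqs([r1, r2_grid])[0]) + np.abs(
            np.array([eqs([r1, r2])[1] for r2 in r2_grid]))
        j = int(np.argmin(res))
        if res[j] < best and r2_grid[j] > r1 * 1.001:
            best, guess = res[j], (r1, r2_grid[j])
    sol = fsolve(eqs, guess)
    return float(sol[0]), float(sol[1])


class TestVirialKernel:
    def test_spherocylinder_diagonal_matches_excluded_volume(
            self, sc_bodies, hard_model):
        """MC kernel diagonal vs closed-form 2 L^2 D sin(gamma) + caps."""
        k = vr.virial_kernel(sc_bodies, hard_model, n_bins=20,
                             mc_budget=20_000_000, seed=3)
        exact = exact_kernel_bin_averaged(k.bin_edges, 10.0, 2.0)
        diag_mc = np.diag(k.kappa)
        diag_ex = np.diag(exact)
        rel = np.abs(diag_mc - diag_ex) / np.abs(diag_ex)
        assert rel.mean() < 0.02
        # pointwise agreement within MC error
        assert np.all(np.abs(diag_mc - diag_ex)
                      < np.maximum(4.0 * np.diag(k.se),
                                   0.02 * np.abs(diag_ex)))

    def test_symmetry_and_sign(self, sc_bodies, hard_model):
        k = vr.virial_kernel(sc_bodies, hard_model, n_bins=10,
                             mc_budget=500_000, seed=5)
        np.testing.assert_array_equal(k.kappa, k.kappa.T)
        assert np.all(k.kappa < 0)  # pure repulsion: -excluded volume

    def test_se_shrinks_with_budget(self, sc_bodies, hard_model):
        k1 = vr.virial_kernel(sc_bodies, hard_model, n_bins=8,
                              mc_budget=400_000, seed=9)
        k2 = vr.virial_kernel(sc_bodies, hard_model, n_bins=8,
                              mc_budget=1_600_000, seed=9)
        ratio = np.mean(k2.se) / np.mean(k1.se)
        assert 0.35 < ratio < 0.7  # ~1/2 expected for 4x budget

    def test_insufficient_budget_raises(self, sc_bodies, hard_model):
        with pytest.raises(ValueError, match="budget"):
            vr.virial_kernel(sc_bodies, hard_model, n_bins=20,
                             mc_budget=1000, seed=0)


class TestSolveOdf:
    def setup_method(self):
        self.x, self.w = leggauss(48)
        self.kg = vr.spherocylinder_kernel_exact(self.x, 10.0, 2.0)
        self.b = np.pi / 4 * 10.0 ** 2 * 2.0

    def test_low_density_is_isotropic(self):
        """Ideal-gas limit: psi -> uniform (deviation is O(rho))."""
        odf = vr.solve_odf(self.kg, 1e-6 / self.b, n_nodes=48)
        np.testing.assert_allclose(odf.psi, 1.0, atol=1e-8)

    def test_high_density_nematic_branch(self):
        odf = vr.solve_odf(self.kg, 5.0 / self.b, n_nodes=48)
        assert odf.order_parameter > 0.7
        # peaked at the poles
        assert odf.psi[0] > odf.psi[24] and odf.psi[-1] > odf.psi[24]

    def test_head_tail_symmetry(self):
        odf = vr.solve_odf(self.kg, 5.0 / self.b, n_nodes=48)
        np.testing.assert_allclose(odf.psi, odf.psi[::-1], rtol=1e-8)

    def test_normalization_and_self_consistency(self):
        odf = vr.solve_odf(self.kg, 4.8 / self.b, n_nodes=48)
        assert 0.5 * np.sum(odf.weights * odf.psi) == pytest.approx(
            1.0, abs=1e-10)
        # substituting psi into the fixed-point map reproduces psi
        kw = self.kg * odf.weights[None, :]
        fld = 0.5 * odf.rho * (kw @ odf.psi)
        trial = np.exp(fld - fld.max())
        trial /= 0.5 * np.sum(odf.weights * trial)
        np.testing.assert_allclose(trial, odf.psi, atol=1e-7)

    def test_agrees_with_direct_minimization(self):
        """Picard fixed point vs direct L-BFGS minimization of f0."""
        rho = 4.8 / self.b
        odf = vr.solve_odf(self.kg, rho, n_nodes=48)
        _, g = minimize_direct(self.kg, self.x, self.w, rho)
        psi = np.exp(g - g.max())
        psi /= 0.5 * np.sum(self.w * psi)
        s_direct = 0.5 * np.sum(self.w * psi * 0.5
                                * (3 * self.x ** 2 - 1))
        assert odf.order_parameter == pytest.approx(s_direct, abs=2e-3)


class TestElasticConstantsAndPitch:
    def test_achiral_rod_has_no_chiral_strength(self, sc_bodies,
                                                hard_model):
        x, w = leggauss(48)
        kg = vr.spherocylinder_kernel_exact(x, 10.0, 2.0)
        b = np.pi / 4 * 200.0
        odf = vr.solve_odf(kg, 4.8 / b, n_nodes=48)
        K2, kt, s2, st = vr.elastic_constants(sc_bodies, hard_model, odf,
                                              mc_budget=3_000_000, seed=5)
        assert K2 > 3 * s2          # twist modulus resolved and positive
        assert abs(kt) < 2 * st     # parity forces kt = 0

    def test_k2_increases_with_density(self, sc_bodies, hard_model):
        x, w = leggauss(48)
        kg = vr.spherocylinder_kernel_exact(x, 10.0, 2.0)
        b = np.pi / 4 * 200.0
        vals = []
        for c in (4.6, 6.0):
            odf = vr.solve_odf(kg, c / b, n_nodes=48)
            K2, kt, s2, st = vr.elastic_constants(
                sc_bodies, hard_model, odf, mc_budget=3_000_000, seed=7)
            vals.append((K2, s2))
        assert vals[1][0] > vals[0][0]

    def test_solenoid_parity(self, solenoid_body, hard_model):
        """Mirror image: kt -> -kt within error, K2 unchanged."""
        k = vr.virial_kernel(solenoid_body, hard_model, n_bins=16,
                             mc_budget=2_000_000, seed=7)
        rho = 1.2 * 4.0 / (-0.25 * np.mean(k.kappa))
        odf = vr.solve_odf(k, rho, n_nodes=48)
        K2, kt, s2, st = vr.elastic_constants(
            solenoid_body, hard_model, odf, mc_budget=8_000_000, seed=11)
        mirror = solenoid_body.mirrored()
        km = vr.virial_kernel(mirror, hard_model, n_bins=16,
                              mc_budget=2_000_000, seed=7)
        odfm = vr.solve_odf(km, rho, n_nodes=48)
        K2m, ktm, s2m, stm = vr.elastic_constants(
            mirror, hard_model, odfm, mc_budget=8_000_000, seed=11)
        assert kt < -2 * st          # right-handed solenoid: kt < 0
        assert ktm > 0               # mirror prefers the other handedness
        assert abs(kt + ktm) < 3 * np.hypot(st, stm)
        assert abs(K2 - K2m) < 3 * np.hypot(s2, s2m)

    def test_pitch_arithmetic_and_flags(self):
        p, se, flag = vr.pitch(1.0, 2.0 * np.pi * 1e-6)
        assert p == pytest.approx(1000.0)  # 1 mm in um
        assert not flag
        p2, _, _ = vr.pitch(1.0, -2.0 * np.pi * 1e-6)
        assert p2 == pytest.approx(-1000.0)
        _, _, flag0 = vr.pitch(1.0, 0.0)
        assert flag0
        _, _, flag1 = vr.pitch(1.0, 1e-6, kt_se=2e-6)
        assert flag1  # achiral within error


class TestBinodal:
    def test_onsager_limit_regression(self):
        """Pure sin(gamma) kernel: classical coexistence 3.290 / 4.191,
        S = 0.792 (dimensionless densities b rho)."""
        n = 48
        x, w = leggauss(n)
        phi = (np.arange(512) + 0.5) * 2 * np.pi / 512
        s = np.sqrt(1 - x ** 2)
        cg = (x[:, None, None] * x[None, :, None]
              + s[:, None, None] * s[None, :, None]
              * np.cos(phi)[None, None, :])
        sing = np.sqrt(np.maximum(0, 1 - cg ** 2))
        kg = -(2.0 * (4 / np.pi) * sing).mean(axis=2)  # b = 1 units
        pb = vr.binodal(kg, (3.2, 6.0), n_nodes=n)
        assert pb.rho_iso == pytest.approx(3.290, rel=0.01)
        assert pb.rho_chol == pytest.approx(4.191, rel=0.01)
        assert pb.order_parameter == pytest.approx(0.792, abs=0.01)
        assert pb.rho_chol > pb.rho_iso
        assert pb.mu_residual < 1e-8 and pb.pressure_residual < 1e-8

    def test_agrees_with_direct_common_tangent(self):
        """L/D = 5 spherocylinders: solver vs independent grid
        minimization + common-tangent construction, within 1%."""
        n = 48
        x, w = leggauss(n)
        kg = vr.spherocylinder_kernel_exact(x, 10.0, 2.0)
        b = np.pi / 4 * 200.0
        pb = vr.binodal(kg, (3.0 / b, 7.0 / b), n_nodes=n)
        r1, r2 = coexistence_direct(kg, x, w,
                                    (pb.rho_iso * 0.8, pb.rho_chol * 1.3))
        assert pb.rho_iso == pytest.approx(r1, rel=0.01)
        assert pb.rho_chol == pytest.approx(r2, rel=0.01)

    def test_mass_conversion(self):
        n = 32
        x, w = leggauss(n)
        kg = vr.spherocylinder_kernel_exact(x, 10.0, 2.0)
        pb = vr.binodal(kg, (3.0 / (np.pi / 4 * 200), 7.0 / (np.pi / 4
                                                             * 200)),
                        n_nodes=n, bp_count=100)
        # c = rho * 100 bp * 650 Da -> g/L
        assert pb.c_iso_gL == pytest.approx(
            pb.rho_iso * 100 * 650 * 1.66054, rel=1e-6)
        assert pb.c_chol_gL > pb.c_iso_gL


class TestChiralPmf:
    def test_achiral_rod_even_pmf(self, sc_bodies, hard_model):
        gam = np.linspace(-60, 60, 9)
        pmf = vr.chiral_pmf(sc_bodies, hard_model, gam,
                            mc_budget=400_000, seed=3)
        assert pmf.W[np.searchsorted(gam, 0.0)] == 0.0
        assert np.abs(pmf.W_odd).max() < 0.05
        assert pmf.gamma_star_deg == 0.0

    def test_right_handed_solenoid_prefers_left_crossings(
            self, hard_model):
        """Strongly curled right-handed helix: gamma* < 0."""
        from chiralfil import synth
        pts, axis = synth.make_solenoid_curve(84.0, 2.5, 35.0, 25)
        sites = (pts - pts.mean(axis=0)) @ np.column_stack(
            [axis, [1.0, 0, 0], [0, 1.0, 0]])
        bodies = itx.BodyEnsemble.from_bodies(
            [itx.RigidBody(sites, np.zeros(25), 6.0, kind=0)])
        gam = np.linspace(-80, 80, 17)
        pmf = vr.chiral_pmf(bodies, hard_model, gam,
                            mc_budget=1_000_000, seed=5, box_xy=12.0)
        assert pmf.gamma_star_deg < 0
        # odd part: right-handed shape penalizes right-handed crossings
        mid = np.abs(pmf.W_odd[10:15])
        assert pmf.W_odd[10:15].mean() > 0.02


class TestBootstrapPitch:
    def test_dispersion_report_contract(self, solenoid_body, hard_model):
        k = vr.virial_kernel(solenoid_body, hard_model, n_bins=12,
                             mc_budget=800_000, seed=2)
        rho = 1.2 * 4.0 / (-0.25 * np.mean(k.kappa))
        rep = vr.bootstrap_pitch(solenoid_body, hard_model, rho,
                                 n_runs=4, kernel_budget=400_000,
                                 elastic_budget=2_000_000, seed=6,
                                 n_nodes=32)
        assert rep.pitches_um.size == 4
        assert rep.passed == (rep.dispersion < rep.threshold)
        assert rep.dispersion >= 0
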