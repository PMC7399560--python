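"""Extended Onsager theory of cholesteric order.

Conventions.  Orientations are integrated with the normalized Haar
measure dR (total mass 1); the one-particle orientation distribution
psi(cos theta) of the long axes u about the nematic director n = e_x is
normalized so that the isotropic state is psi = 1, i.e.
(1/2) int_-1^1 dcos(theta) psi = 1.  The second-virial free energy per
unit volume (in kT) is

    beta f0 = rho (ln rho - 1) + rho <ln psi>
              + (rho^2 / 8) int dx1 dx2 psi(x1) psi(x2) [-kappa(x1, x2)],

with kappa(x, x') the conformationally and azimuthally averaged Mayer
integral (negative of an excluded volume for repulsive interactions).
Functional minimization gives the self-consistency equation

    psi(x) = Z^-1 exp[ (rho/2) int dx' psi(x') kappa(x, x') ],

solved by damped Picard iteration.  The Oseen-Frank twist modulus K2 and
chiral strength kt follow from the standard second-virial perturbation of
a weakly twisted director field (helical axis e_z),

    beta K2 = (rho^2/2) int dr12 E[ fbar psidot(x1) psidot(x2)
                                     rz^2 u1y u2y ],
    beta kt = (rho^2/2) int dr12 E[ fbar psi(x1) psidot(x2) rz u2y ],

and the equilibrium pitch is P = 2 pi K2 / kt (positive = right-handed).
Isotropic/cholesteric binodals equate chemical potential and osmotic
pressure between the isotropic branch and the aligned branch (the chiral
contribution to coexistence, kt * 2 pi / P, is negligible at the pitches
of interest and is ignored).  These conventions are validated end to end
against classical hard-rod theory via an independent grid-minimization
oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import CubicSpline, RectBivariateSpline
from scipy.optimize import brentq

from . import _mc
from .constants import BP_MASS_DA, DA_PER_NM3_TO_G_PER_L
from .interactions import BodyEnsemble, InteractionModel, \
    CELL_LIST_PAIR_THRESHOLD


def _use_cells(bodies: BodyEnsemble) -> bool:
    return bodies.positions.shape[1] ** 2 > CELL_LIST_PAIR_THRESHOLD


def _cutoff(bodies: BodyEnsemble, model: InteractionModel) -> float:
    if not np.any(bodies.charges):
        return 0.0  # pure hard core: no tail, exact support
    return model.cutoff_for(bodies.diameter)


def _box_half(bodies: BodyEnsemble, model: InteractionModel) -> np.ndarray:
    # must contain the full Mayer support: near-collinear pairs interact
    # out to center separations of twice the capsule reach plus the tail
    w = 2.0 * (bodies.axis_half + bodies.lat_radius) + _cutoff(bodies, model)
    return np.array([w, w, w])


@dataclass
class VirialKernel:
    """Angular virial kernel on a theta-uniform bin grid (nm^3).

    Bins are uniform in the polar angle theta, not cos(theta): the
    excluded volume has a |sin gamma| cusp at parallel alignment, and
    cos-uniform bins (which are coarse in angle at the poles) round it
    enough to visibly weaken the first-order character of the
    isotropic/nematic transition.
    """

    bin_centers: np.ndarray   # cos(theta) bin centroids, ascending
    kappa: np.ndarray
    se: np.ndarray
    bin_edges: np.ndarray = None

    def interpolator(self):
        x = self.bin_centers
        if x.size >= 4:
            return RectBivariateSpline(x, x, self.kappa, kx=3, ky=3)
        return RectBivariateSpline(x, x, self.kappa, kx=1, ky=1)

    def on_grid(self, x: np.ndarray) -> np.ndarray:
        interp = self.interpolator()
        k = interp(x, x)
        return 0.5 * (k + k.T)


def virial_kernel(bodies: BodyEnsemble, model: InteractionModel,
                  n_bins: int = 20, mc_budget: int = 400_000,
                  seed: int = 0, n_batches: int = 16) -> VirialKernel:
    """Monte Carlo estimate of kappa(theta, theta').

    mc_budget is the total sample count, split evenly over the stratified
    upper-triangle (cos theta1, cos theta2) bin pairs; deterministic per
    seed.  Raises if the per-bin-pair budget is too small to say anything.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    n_pairs = n_bins * (n_bins + 1) // 2
    per_pair = mc_budget // n_pairs
    if per_pair < n_batches:
        raise ValueError(
            f"mc_budget {mc_budget} gives {per_pair} samples per bin pair "
            f"({n_pairs} pairs); increase the budget")
    edges = np.cos(np.linspace(np.pi, 0.0, n_bins + 1))
    edges[0], edges[-1] = -1.0, 1.0
    kappa, se = _mc.kernel_mc(
        bodies.positions, bodies.charges, bodies.kind, bodies.diameter,
        bodies.axis_half, bodies.lat_radius, model.bjerrum_nm,
        model.debye_nm, _cutoff(bodies, model), edges, per_pair,
        n_batches,
        _box_half(bodies, model), seed % 2 ** 31, _use_cells(bodies))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return VirialKernel(centers, kappa, se, edges)


# ---------------------------------------------------------------------------
# Orientation distribution
# ---------------------------------------------------------------------------

@dataclass
class OrientationDistribution:
    nodes: np.ndarray       # cos theta Gauss-Legendre nodes
    weights: np.ndarray
    psi: np.ndarray
    rho: float              # 1/nm^3
    Z: float
    n_iter: int
    residual: float

    @property
    def order_parameter(self) -> float:
        """Nematic order parameter S = <P2(cos theta)>."""
        p2 = 0.5 * (3.0 * self.nodes ** 2 - 1.0)
        return float(0.5 * np.sum(self.weights * self.psi * p2))

    def entropy_term(self) -> float:
        """<ln psi> under the normalized orientation measure."""
        return float(0.5 * np.sum(self.weights * self.psi
                                  * np.log(np.maximum(self.psi, 1e-300))))

    def pair_term(self, kappa_grid: np.ndarray) -> float:
        """a2 = -(1/8) int dx1 dx2 psi psi kappa  (nm^3)."""
        return float(-0.125 * self.psi @ (kappa_grid * np.outer(
            self.weights, self.weights)) @ self.psi)

    def psi_splines(self):
        """Cubic-spline psi(x) and its derivative on [-1, 1]."""
        x = np.concatenate([[-1.0], self.nodes, [1.0]])
        # natural extension to the endpoints via quadratic extrapolation
        cs = CubicSpline(self.nodes, self.psi, bc_type="not-a-knot",
                         extrapolate=True)
        y = cs(x)
        cs_full = CubicSpline(x, y)
        return cs_full, cs_full.derivative()


def solve_odf(kernel: VirialKernel | np.ndarray, rho: float,
              n_nodes: int = 48, tol: float = 1e-10, mixing: float = 0.4,
              init="nematic", max_iter: int = 4000
              ) -> OrientationDistribution:
    """Damped Picard solution of the self-consistency equation.

    init "isotropic" converges to the isotropic branch at low density;
    "nematic" seeds an aligned trial and returns the nematic branch when
    one exists (falling back to isotropic where it does not); an array
    init continues from a previously converged distribution (used by the
    coexistence solver to track the weakly ordered branch).
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    x, w = leggauss(n_nodes)
    if isinstance(kernel, VirialKernel):
        kg = kernel.on_grid(x)
    else:
        kg = np.asarray(kernel)
        if kg.shape != (n_nodes, n_nodes):
            raise ValueError("kernel grid does not match n_nodes")
    if isinstance(init, str) and init == "isotropic":
        psi = np.ones(n_nodes)
    elif isinstance(init, str) and init == "nematic":
        psi = np.exp(5.0 * x ** 2)
        psi /= 0.5 * np.sum(w * psi)
    elif isinstance(init, np.ndarray):
        psi = np.maximum(init.copy(), 1e-12)
        psi /= 0.5 * np.sum(w * psi)
    else:
        raise ValueError(f"unknown init {init!r}")
    kw = kg * w[None, :]
    residual = np.inf
    for it in range(1, max_iter + 1):
        fld = 0.5 * rho * (kw @ psi)
        fld -= fld.max()
        trial = np.exp(fld)
        Z = 0.5 * np.sum(w * trial)
        trial /= Z
        residual = float(np.max(np.abs(trial - psi)))
        if residual < tol:
            psi = trial  # return the fixed-point image itself
            break
        psi = (1.0 - mixing) * psi + mixing * trial
    else:
        raise RuntimeError(
            f"orientation distribution not converged after {max_iter} "
            f"iterations (residual {residual:.2e})")
    fld = 0.5 * rho * (kw @ psi)
    Z_final = float(0.5 * np.sum(w * np.exp(fld - fld.max()))
                    * np.exp(fld.max()))
    return OrientationDistribution(x, w, psi, rho, Z_final, it, residual)


# ---------------------------------------------------------------------------
# Elastic constants, pitch
# ---------------------------------------------------------------------------

@dataclass
class CholestericSolution:
    rho: float
    odf: OrientationDistribution
    K2: float               # kT/nm
    K2_se: float
    kt: float               # kT/nm^2
    kt_se: float
    pitch_um: float | None  # signed; None if achiral within error
    pitch_se_um: float | None
    achiral_within_error: bool
    concentration_gL: float | None = None


def elastic_constants(bodies: BodyEnsemble, model: InteractionModel,
                      odf: OrientationDistribution,
                      mc_budget: int = 2_000_000, seed: int = 1,
                      n_batches: int = 16, psi_table_size: int = 2001):
    """MC estimates of (K2, kt) with batch-mean standard errors (kT units).
    """
    cs, dcs = odf.psi_splines()
    xt = np.linspace(-1.0, 1.0, psi_table_size)
    psi_tab = np.maximum(cs(xt), 0.0)
    psidot_tab = dcs(xt)
    # importance proposal for cos(theta): follow psi + |psidot|, floored
    q_tab = psi_tab + np.abs(psidot_tab)
    q_tab = q_tab / np.trapezoid(q_tab, xt) + 0.05
    q_tab /= np.trapezoid(q_tab, xt)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (q_tab[1:] + q_tab[:-1]) * np.diff(xt))])
    cdf /= cdf[-1]
    u_grid = np.linspace(0.0, 1.0, 4096)
    inv_cdf = np.interp(u_grid, cdf, xt)
    i2, it, s2, st = _mc.elastic_mc(
        bodies.positions, bodies.charges, bodies.kind, bodies.diameter,
        bodies.axis_half, bodies.lat_radius, model.bjerrum_nm,
        model.debye_nm, _cutoff(bodies, model), psi_tab, psidot_tab,
        q_tab, inv_cdf,
        mc_budget, n_batches, _box_half(bodies, model), seed % 2 ** 31,
        _use_cells(bodies))
    pref = 0.5 * odf.rho ** 2
    return pref * i2, pref * it, pref * s2, pref * st


def pitch(K2: float, kt: float, K2_se: float = 0.0, kt_se: float = 0.0):
    """Equilibrium cholesteric pitch P = 2 pi K2 / kt in um.

    Returns (P_um, P_se_um, achiral_flag); achiral_flag is set (and P is
    None) when kt is within one standard error of zero.
    """
    if abs(kt) <= kt_se or kt == 0.0:
        return None, None, True
    p_nm = 2.0 * math.pi * K2 / kt
    rel = math.sqrt((K2_se / K2) ** 2 + (kt_se / kt) ** 2) \
        if K2 != 0 else 0.0
    return p_nm * 1e-3, abs(p_nm) * rel * 1e-3, False


def solve_cholesteric(bodies: BodyEnsemble, model: InteractionModel,
                      rho: float, kernel: VirialKernel | None = None,
                      kernel_budget: int = 400_000,
                      elastic_budget: int = 2_000_000, seed: int = 0,
                      n_nodes: int = 48, bp_count: int | None = None
                      ) -> CholestericSolution:
    """Kernel -> ODF -> (K2, kt) -> pitch at one state point."""
    if kernel is None:
        kernel = virial_kernel(bodies, model, mc_budget=kernel_budget,
                               seed=seed)
    odf = solve_odf(kernel, rho, n_nodes=n_nodes)
    K2, kt, K2_se, kt_se = elastic_constants(bodies, model, odf,
                                             elastic_budget, seed + 1)
    p, p_se, achiral = pitch(K2, kt, K2_se, kt_se)
    conc = None
    if bp_count is not None:
        conc = rho * bp_count * BP_MASS_DA * DA_PER_NM3_TO_G_PER_L
    return CholestericSolution(rho, odf, K2, K2_se, kt, kt_se, p, p_se,
                               achiral, conc)


# ---------------------------------------------------------------------------
# Thermodynamics and binodals
# ---------------------------------------------------------------------------

def _thermo(kernel_grid: np.ndarray, rho: float, n_nodes: int,
            branch: str, init="nematic"):
    """(beta mu, beta Pi, odf) of one branch at density rho."""
    x, w = leggauss(n_nodes)
    if branch == "isotropic":
        psi = np.ones(n_nodes)
        odf = OrientationDistribution(x, w, psi, rho, 1.0, 0, 0.0)
    else:
        odf = solve_odf(kernel_grid, rho, n_nodes=n_nodes, init=init)
    a2 = odf.pair_term(kernel_grid)
    mu = math.log(rho) + odf.entropy_term() + 2.0 * rho * a2
    pi = rho + rho ** 2 * a2
    return mu, pi, odf


@dataclass
class PhaseBoundary:
    rho_iso: float
    rho_chol: float
    c_iso_gL: float | None
    c_chol_gL: float | None
    mu: float
    pressure: float
    mu_residual: float
    pressure_residual: float
    order_parameter: float


def binodal(kernel: VirialKernel | np.ndarray, rho_bracket: tuple,
            n_nodes: int = 48, bp_count: int | None = None,
            n_scan: int = 40, tol: float = 1e-10) -> PhaseBoundary:
    """Isotropic/cholesteric coexistence by equating mu and Pi.

    Scans the aligned branch over rho_bracket, pairs each point with the
    isotropic density of equal chemical potential, and locates the
    pressure crossing by bisection.  Concentrations use bp_count x 650 Da.
    """
    x, w = leggauss(n_nodes)
    if isinstance(kernel, VirialKernel):
        kg = kernel.on_grid(x)
    else:
        kg = np.asarray(kernel)

    def mu_iso(rho):
        a2 = -0.125 * np.sum(np.outer(w, w) * kg)
        return math.log(rho) + 2.0 * rho * a2, rho + rho ** 2 * a2

    def pressure_mismatch(rho_n, init):
        mu_n, pi_n, odf = _thermo(kg, rho_n, n_nodes, "nematic", init)
        if odf.order_parameter < 0.2:
            return None  # aligned branch does not exist here
        lo, hi = 1e-12, rho_n * 2.0
        f = lambda r: mu_iso(r)[0] - mu_n
        while f(hi) < 0:
            hi *= 2.0
            if hi > 1e6:
                raise RuntimeError("isotropic mu never matches")
        rho_i = brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
        return mu_iso(rho_i)[1] - pi_n, rho_i, mu_n, pi_n, odf

    # walk the aligned branch downward by continuation: seeding each
    # solve with the previous psi tracks the weakly ordered (metastable)
    # part of the branch that a fixed aligned seed can miss
    rhos = np.linspace(rho_bracket[1], rho_bracket[0], n_scan)
    psi_prev = "nematic"
    prev = None
    sol = None
    for rho_n in rhos:
        res = pressure_mismatch(rho_n, psi_prev)
        if res is None:
            # branch terminated between scan points: refine toward its
            # end — the coexistence window can be narrower than a step
            if prev is None:
                break
            alive, dead = prev[0], rho_n
            res = None
            for _ in range(14):
                mid = 0.5 * (alive + dead)
                rmid = pressure_mismatch(mid, psi_prev)
                if rmid is None:
                    dead = mid
                    continue
                psi_prev = rmid[4].psi
                alive = mid
                if rmid[0] * prev[1][0] <= 0.0:
                    res = rmid
                    rho_n = mid
                    break
            if res is None:
                break
        psi_prev = res[4].psi
        if prev is not None and res[0] * prev[1][0] <= 0.0:
            lo_r, hi_r = rho_n, prev[0]
            f_lo = res[0]
            psi_bis = res[4].psi
            for _ in range(200):
                mid = 0.5 * (lo_r + hi_r)
                rmid = pressure_mismatch(mid, psi_bis)
                if rmid is None:
                    lo_r = mid
                    continue
                psi_bis = rmid[4].psi
                if rmid[0] * f_lo <= 0.0:
                    hi_r = mid
                else:
                    lo_r, f_lo = mid, rmid[0]
                if hi_r - lo_r < tol * max(1.0, mid):
                    break
            sol = pressure_mismatch(0.5 * (lo_r + hi_r), psi_bis)
            break
        prev = (rho_n, res)
    if sol is None:
        raise RuntimeError(
            "no isotropic/cholesteric pressure crossing found in "
            f"rho bracket {rho_bracket}; scan the free-energy branches")
    mismatch, rho_i, mu_n, pi_n, odf = sol
    rho_n = odf.rho
    if rho_n <= rho_i:
        raise RuntimeError("aligned branch density not above isotropic; "
                           "bracket likely below the transition")
    c_i = c_n = None
    if bp_count is not None:
        f = bp_count * BP_MASS_DA * DA_PER_NM3_TO_G_PER_L
        c_i, c_n = rho_i * f, rho_n * f
    mu_i, pi_i = mu_iso(rho_i)
    return PhaseBoundary(rho_i, rho_n, c_i, c_n, mu_n, pi_n,
                         abs(mu_i - mu_n), abs(pi_i - pi_n),
                         odf.order_parameter)


# ---------------------------------------------------------------------------
# Chiral pair potential of mean force
# ---------------------------------------------------------------------------

@dataclass
class ChiralPmf:
    gamma_deg: np.ndarray
    W: np.ndarray           # kT, relative to gamma = 0
    W_odd: np.ndarray       # antisymmetric (chiral) part, kT
    gamma_star_deg: float


def chiral_pmf(bodies: BodyEnsemble, model: InteractionModel,
               gamma_deg: np.ndarray | None = None,
               mc_budget: int = 2_000_000, seed: int = 0,
               box_xy: float | None = None) -> ChiralPmf:
    """Angular scan of the chiral two-body potential of mean force.

    For each interaxial angle gamma, W(gamma) = -ln <exp(-beta U)>
    averaged over conformations, axial spins, and separations in the
    crossing region (one-sided normal offsets within reach of the
    surfaces, lateral offsets around the filament midpoints), referenced
    to W(0) = 0.  The minimizing gamma* gives the preferred pair
    handedness (negative = left-handed crossing); W_odd isolates the
    chiral component, which vanishes identically for achiral particles.

    The scan requires a symmetric gamma grid (so W_odd is well defined);
    the default spans -90..90 degrees.
    """
    if gamma_deg is None:
        gamma_deg = np.linspace(-90.0, 90.0, 19)
    gamma_deg = np.asarray(gamma_deg, dtype=float)
    if not np.allclose(gamma_deg + gamma_deg[::-1], 0.0):
        raise ValueError("gamma grid must be symmetric about 0")
    n_per = max(1, mc_budget // gamma_deg.size)
    cut = _cutoff(bodies, model)
    # normal offsets must reach past contact even for pure hard cores
    box_z = 2.0 * bodies.lat_radius + cut + 0.5 * bodies.diameter
    if box_xy is None:
        box_xy = 0.25 * bodies.axis_half + cut
    means = _mc.pmf_mc(
        bodies.positions, bodies.charges, bodies.kind, bodies.diameter,
        bodies.axis_half, bodies.lat_radius, model.bjerrum_nm,
        model.debye_nm, cut, np.radians(gamma_deg), n_per,
        box_xy, box_z, seed % 2 ** 31, _use_cells(bodies))
    i0 = int(np.argmin(np.abs(gamma_deg)))
    W = -np.log(np.maximum(means, 1e-300)) \
        + math.log(max(means[i0], 1e-300))
    W_odd = 0.5 * (W - W[::-1])
    return ChiralPmf(gamma_deg, W, W_odd,
                     float(gamma_deg[int(np.argmin(W))]))


# ---------------------------------------------------------------------------
# Bootstrap convergence check
# ---------------------------------------------------------------------------

@dataclass
class BootstrapReport:
    pitches_um: np.ndarray
    dispersion: float       # relative std of the pitch
    threshold: float
    passed: bool


def bootstrap_pitch(bodies: BodyEnsemble, model: InteractionModel,
                    rho: float, n_runs: int = 16,
                    kernel_budget: int = 200_000,
                    elastic_budget: int = 500_000, seed: int = 0,
                    threshold: float = 0.10,
                    n_nodes: int = 32) -> BootstrapReport:
    """Pitch dispersion across bootstrap resamples of the ensemble.

    Mirrors the convergence criterion used for production runs: the
    relative dispersion of P across independent resamples must stay
    below the threshold (default 10%).
    """
    rng = np.random.default_rng(seed)
    pitches = []
    for run in range(n_runs):
        idx = rng.integers(0, bodies.count, size=bodies.count)
        sub = bodies.subset(idx)
        sol = solve_cholesteric(sub, model, rho,
                                kernel_budget=kernel_budget,
                                elastic_budget=elastic_budget,
                                seed=int(rng.integers(0, 2 ** 31)),
                                n_nodes=n_nodes)
        p = sol.pitch_um
        if p is None:
            p = math.copysign(1e9, sol.kt if sol.kt != 0 else 1.0) * 1e-3
        pitches.append(p)
    pitches = np.array(pitches)
    mean = pitches.mean()
    disp = float(pitches.std(ddof=1) / abs(mean)) if mean != 0 else np.inf
    return BootstrapReport(pitches, disp, threshold, disp < threshold)


# ---------------------------------------------------------------------------
# Hard-rod reference (closed-form kernel for validation)
# ---------------------------------------------------------------------------

def spherocylinder_kernel_exact(x: np.ndarray, length: float,
                                diameter: float,
                                n_phi: int = 256) -> np.ndarray:
    """Azimuth-averaged -excluded-volume kernel of hard spherocylinders.

    V_excl(gamma) = 2 L^2 D sin(gamma) + 2 pi L D^2 + (4/3) pi D^3 with
    cos(gamma) = x x' + sqrt(1-x^2) sqrt(1-x'^2) cos(phi), averaged over
    the relative azimuth phi.  Returns kappa = -<V_excl> on the x grid.
    """
    x = np.asarray(x, dtype=float)
    phi = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
    s = np.sqrt(np.maximum(0.0, 1.0 - x ** 2))
    cg = (x[:, None, None] * x[None, :, None]
          + s[:, None, None] * s[None, :, None]
          * np.cos(phi)[None, None, :])
    sing = np.sqrt(np.maximum(0.0, 1.0 - cg ** 2))
    vex = (2.0 * length ** 2 * diameter * sing
           + 2.0 * np.pi * length * diameter ** 2
           + (4.0 / 3.0) * np.pi * diameter ** 3)
    return -vex.mean(axis=2)
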