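"""Backbone fluctuation spectra and the helicity order parameter H(k).

The filament backbone is the per-bp-plane average of the six duplex
midpoints.  In the principal frame (u, v, w) of its gyration tensor the
transverse displacement r_perp(s) = r(s) - (r.u) u is Fourier analysed on
the one-sided grid k_n = n / l_c, and the helicity order parameter

    H(k) = 2 Im{c_vw(k)} / (c_vv(k) + c_ww(k)),

the normalized imaginary part of the transverse cross-spectrum, measures
how close a deformation mode is to an ideal circular helix: H = +1 (-1)
iff the two transverse components have equal amplitudes in exact phase
quadrature, i.e. a right- (left-) handed helical mode about +u.

The transform is the exact discrete sum sum_s ds r_perp(s) e^{-2 i pi k s}
with N samples at s_j = j ds and the convention l_c = N ds (under which
the ideal-helix identity |H| = 1 is exact on the grid); it is evaluated
with an FFT, which is identical to that sum on this grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .geometry import gyration_axes, resample_uniform
from .io import ConformationEnsemble, FilamentConformation

log = logging.getLogger(__name__)


@dataclass
class BackboneCurve:
    """Uniformly sampled backbone with center of mass at the origin."""

    positions: np.ndarray   # (N, 3), nm
    ds: float               # nm
    contour_length: float   # N * ds, nm

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def s(self) -> np.ndarray:
        return np.arange(self.n) * self.ds


@dataclass
class MolecularFrame:
    """Right-handed orthonormal frame (u, v, w); u = max-dispersion axis,
    v = min-dispersion axis, w = u x v."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray

    def as_matrix(self) -> np.ndarray:
        """Columns (u, v, w)."""
        return np.column_stack([self.u, self.v, self.w])


@dataclass
class HelicitySpectrum:
    wavenumbers: np.ndarray   # 1/nm, k_n = n / l_c
    rv: np.ndarray            # complex Fourier components along v
    rw: np.ndarray            # along w
    c_vv: np.ndarray
    c_ww: np.ndarray
    c_vw: np.ndarray          # complex cross-spectrum
    H: np.ndarray


@dataclass
class EnsembleSpectrum:
    wavenumbers: np.ndarray
    power: np.ndarray         # <|r_perp_hat|^2>(k) = <c_vv + c_ww>
    power_se: np.ndarray
    H_mean: np.ndarray
    H_se: np.ndarray
    H_smooth: np.ndarray | None = None
    smoothing: str = "none"
    count: int = 0


def extract_backbone(conformation: FilamentConformation,
                     trim_bp: int = 10) -> BackboneCurve:
    """Backbone curve: mean of the six duplex midpoints per bp plane.

    trim_bp planes are dropped at each extremity (end-effect control),
    the curve is re-parameterized to uniform ds by arc length, and the
    center of mass is moved to the origin.
    """
    if trim_bp < 0:
        raise ValueError("trim_bp must be >= 0")
    planes = [conformation.bp_planes(d) for d in range(conformation.n_duplex)]
    n_bp = {p.shape[0] for p in planes}
    if len(n_bp) != 1:
        raise ValueError("duplexes have differing bp plane counts")
    n_bp = n_bp.pop()
    if n_bp - 2 * trim_bp < 4:
        raise ValueError("too few bp planes after trimming")
    pts = np.mean(planes, axis=0)
    if trim_bp:
        pts = pts[trim_bp:n_bp - trim_bp]
    n = pts.shape[0]
    uniform, ds = resample_uniform(pts, n)
    uniform = uniform - uniform.mean(axis=0)
    return BackboneCurve(uniform, ds, n * ds)


def gyration_frame(backbone: BackboneCurve) -> MolecularFrame:
    """Principal frame of the backbone gyration tensor with fixed signs.

    u (max dispersion) points from the first to the last backbone point;
    the sign of v (min dispersion) follows the first non-negligible
    transverse displacement; w = u x v completes the right-handed frame.
    Near-degenerate transverse eigenvalues are resolved by this same rule
    and logged.
    """
    pts = backbone.positions
    if pts.shape[0] < 3:
        raise ValueError("need at least three backbone points")
    w_eig, vecs = gyration_axes(pts)
    u = vecs[:, 0]
    v = vecs[:, 2]
    if abs(w_eig[1] - w_eig[2]) < 1e-12 * max(w_eig[0], 1.0):
        log.info("degenerate transverse gyration eigenvalues; sign rule "
                 "fixes the frame")
    if np.dot(u, pts[-1] - pts[0]) < 0:
        u = -u
    r_perp = pts - np.outer(pts @ u, u)
    norms = np.linalg.norm(r_perp, axis=1)
    imax = int(np.argmax(norms))
    if norms[imax] > 1e-9 and np.dot(v, r_perp[imax]) < 0:
        v = -v
    return MolecularFrame(u, v, np.cross(u, v))


def transverse_displacement(backbone: BackboneCurve,
                            frame: MolecularFrame) -> np.ndarray:
    """r_perp(s_j) = r(s_j) - (r . u) u; orthogonal to u by construction."""
    pts = backbone.positions
    return pts - np.outer(pts @ frame.u, frame.u)


def helicity_spectrum(r_perp: np.ndarray, frame: MolecularFrame,
                      ds: float, contour_length: float) -> HelicitySpectrum:
    """One-sided transverse spectra and H(k) at k_n = n / l_c, n <= N/2."""
    n = r_perp.shape[0]
    if abs(contour_length - n * ds) > 1e-6 * contour_length:
        raise ValueError("contour_length must equal N * ds")
    pv = r_perp @ frame.v
    pw = r_perp @ frame.w
    # exact sum ds * sum_j x_j e^{-2 pi i n j / N} == ds * FFT
    rv = ds * np.fft.rfft(pv)
    rw = ds * np.fft.rfft(pw)
    c_vv = (rv * np.conj(rv)).real
    c_ww = (rw * np.conj(rw)).real
    c_vw = rv * np.conj(rw)
    denom = c_vv + c_ww
    H = np.zeros_like(denom)
    ok = denom > 1e-300
    H[ok] = 2.0 * c_vw.imag[ok] / denom[ok]
    k = np.arange(rv.size) / contour_length
    return HelicitySpectrum(k, rv, rw, c_vv, c_ww, c_vw, H)


def conformation_helicity(conformation: FilamentConformation,
                          trim_bp: int = 10) -> HelicitySpectrum:
    """Backbone -> frame -> transverse displacement -> H(k) in one call."""
    backbone = extract_backbone(conformation, trim_bp)
    frame = gyration_frame(backbone)
    r_perp = transverse_displacement(backbone, frame)
    return helicity_spectrum(r_perp, frame, backbone.ds,
                             backbone.contour_length)


def ensemble_helicity(ensemble: ConformationEnsemble, trim_bp: int = 10,
                      smooth_window: int | None = 15,
                      smooth_order: int = 9) -> EnsembleSpectrum:
    """Pointwise ensemble averages of the per-conformation spectra.

    Savitzky-Golay smoothing (default order 9) is applied to the mean
    helicity curve only, as a presentation aid; all statistics are formed
    from the raw per-conformation spectra.
    """
    if ensemble.count < 2:
        raise ValueError("need at least two conformations")
    H_rows, P_rows, k_ref = [], [], None
    for conf in ensemble:
        spec = conformation_helicity(conf, trim_bp)
        if k_ref is None:
            k_ref = spec.wavenumbers
        elif spec.wavenumbers.size != k_ref.size or not np.allclose(
                spec.wavenumbers, k_ref):
            raise ValueError("inconsistent wave-number grids in ensemble")
        H_rows.append(spec.H)
        P_rows.append(spec.c_vv + spec.c_ww)
    H_arr = np.array(H_rows)
    P_arr = np.array(P_rows)
    m = H_arr.shape[0]
    H_mean = H_arr.mean(axis=0)
    H_se = H_arr.std(axis=0, ddof=1) / np.sqrt(m)
    P_mean = P_arr.mean(axis=0)
    P_se = P_arr.std(axis=0, ddof=1) / np.sqrt(m)
    H_smooth, smoothing = None, "none"
    if smooth_window is not None and smooth_window > smooth_order:
        window = min(smooth_window, H_mean.size - (H_mean.size + 1) % 2)
        if window > smooth_order:
            H_smooth = savgol_filter(H_mean, window, smooth_order)
            smoothing = f"savgol(window={window}, order={smooth_order})"
    return EnsembleSpectrum(k_ref, P_mean, P_se, H_mean, H_se, H_smooth,
                            smoothing, m)


def wlc_reference_spectrum(k: np.ndarray, persistence_length: float,
                           contour_length: float,
                           n_points: int = 400) -> np.ndarray:
    """Expected transverse power of a free semiflexible filament, exactly.

    The discrete wormlike chain is Gaussian in the weak-bending regime:
    per transverse component, successive tangents perform a random walk
    with step variance ds / l_p, so the transverse displacement has a
    known covariance.  This routine builds that covariance on an
    n_points grid, applies the same observation operators as the
    measurement pipeline — center-of-mass removal and long-axis (linear)
    detrending, the linear-response equivalent of the gyration frame —
    and evaluates the expected one-sided power
    <|r_hat_perp(k)|^2> = <c_vv + c_ww> of the exact discrete transform.

    The result is proportional to 1 / l_p and scales as 1 / (l_p k^4) in
    mode space (see :func:`bending_mode_spectrum`); the transform power
    itself carries the boundary leakage of a non-periodic filament, which
    this prediction includes.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    lc, lp = contour_length, persistence_length
    n = int(n_points)
    ds = lc / n
    s = np.arange(n) * ds
    # tangent-component covariance: random walk, C_u[i, j] = ds/lp *
    # (min(i, j) + 1); displacement x = ds * cumsum(u)
    idx = np.arange(n)
    c_u = (np.minimum.outer(idx, idx) + 1.0) * (ds / lp)
    c_x = ds ** 2 * np.cumsum(np.cumsum(c_u, axis=0), axis=1)
    # observation: remove mean and the least-squares linear trend in s
    sc = s - s.mean()
    P = np.eye(n) - np.ones((n, n)) / n - np.outer(sc, sc) / (sc @ sc)
    c_obs = P @ c_x @ P.T
    phases = np.exp(-2j * np.pi * np.outer(k, s))
    out = np.einsum("ki,ij,kj->k", phases, c_obs, np.conj(phases)).real
    return 2.0 * ds ** 2 * out  # two transverse components


def bending_mode_spectrum(r_perp: np.ndarray, frame: MolecularFrame,
                          ds: float):
    """Cosine-mode amplitude power of the transverse displacement.

    Expands each transverse component on cos(pi n (j + 1/2) / N) (an
    orthogonal basis on the open filament) and returns (k_n, A_n^2
    summed over both components) for n = 1..N-1, with k_n = n / (2 l_c)
    the mode wave number.  For an equipartitioned persistent chain
    <A_n^2> follows the 1 / (l_p k^4) bending law; this mode-space
    spectrum is free of the boundary leakage that the exponential
    transform of an open chain carries.
    """
    from scipy.fft import dct
    n = r_perp.shape[0]
    av = dct(r_perp @ frame.v, type=2) / n
    aw = dct(r_perp @ frame.w, type=2) / n
    power = (av ** 2 + aw ** 2)[1:]
    k = np.arange(1, n) / (2.0 * n * ds)
    return k, power
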