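"""Synthetic six-helix-bundle conformations.

This module stands in for nucleotide-level molecular dynamics: it draws
filament centerlines from a discrete wormlike chain (with optional
intrinsic curvature/torsion, i.e. a solenoidal bias), decorates them as
six-duplex hexagonal bundles with prescribed axial twist and duplex
winding, and assembles i.i.d. ensembles with full provenance.

The linking bookkeeping is explicit: a design overtwist (turns/um, the
duplex overtwist the filament would carry if held straight and untwisted)
is partitioned between built duplex overtwist and centerline solenoidal
writhe, so that over the ensemble

    <DeltaTw> + <Wr expressed in turns/um>  ~=  design_overtwist.

Under the default "thermal" partition rule the solenoidal bias has the
same handedness as the overtwist (overwound duplexes -> right-handed
writhe), emulating the twist->writhe conversion seen in thermalized
origami filaments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .constants import RISE_NM, BP_PER_TURN, TW0_TURNS_PER_NM
from .geometry import (arclength_spline, rotation_minimizing_frame,
                       polar_writhe_points, gyration_axes)
from .io import FilamentConformation, ConformationEnsemble


@dataclass
class ChainParameters:
    """Discrete wormlike-chain parameters for the filament centerline.

    contour_length, segment_length, persistence_length in nm; curvature
    and torsion in 1/nm; axial_twist_rate in turns/um (signed, positive =
    right-handed rotation of the bundle cross-section along the contour).
    """

    contour_length: float = 420.0
    segment_length: float = 0.34
    persistence_length: float = 8.0 * 420.0
    intrinsic_curvature: float = 0.0
    intrinsic_torsion: float = 0.0
    axial_twist_rate: float = 0.0
    seed: int = 0

    @property
    def n_segments(self) -> int:
        return int(round(self.contour_length / self.segment_length))

    def validate(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")
        if not (0 < self.segment_length < self.contour_length):
            raise ValueError("need 0 < segment_length < contour_length")
        if self.n_segments < 10:
            raise ValueError("fewer than 10 segments; refine segment_length")
        if self.persistence_length / self.segment_length < 1.0:
            raise ValueError(
                "persistence_length / segment_length < 1: discretization "
                "too coarse for the wormlike-chain step distribution")


@dataclass
class BundleGeometry:
    """Cross-section and winding geometry of the six-helix bundle."""

    n_duplex: int = 6
    hex_radius: float = 2.6       # duplex-axis distance from centerline, nm
    duplex_radius: float = 1.0    # strand distance from the duplex axis, nm
    rise: float = RISE_NM         # nm per bp
    bp_per_turn: float = BP_PER_TURN
    bp_count: int = 1235
    diameter: float = 6.0         # nominal bundle diameter sigma, nm

    @property
    def duplex_twist_density(self) -> float:
        """Relaxed winding of the duplex strands, turns/nm."""
        return 1.0 / (self.bp_per_turn * self.rise)

    def validate(self, contour_length: float) -> None:
        # the duplex-axis circle must fit the nominal diameter within 10%;
        # the strand orbit may circumscribe it by up to a duplex radius
        if 2.0 * self.hex_radius > 1.1 * self.diameter:
            raise ValueError("duplex-axis circle exceeds bundle diameter "
                             "by >10%")
        if 2.0 * (self.hex_radius + self.duplex_radius) > 1.3 * self.diameter:
            raise ValueError("strand orbit incompatible with bundle diameter")
        built = self.rise * self.bp_count
        if abs(built - contour_length) > 0.02 * contour_length:
            raise ValueError(
                f"rise * bp_count = {built:.1f} nm differs from contour "
                f"length {contour_length:.1f} nm by more than 2%")


@dataclass
class LinkingTarget:
    """How designed duplex overtwist is expressed in the ensemble.

    design_overtwist: turns/um carried by the duplexes if the filament is
    held straight and untwisted.  partition_rule:

    - "thermal" (default): a solenoidal centerline bias of the same
      handedness as the overtwist is applied (writhe_coupling solenoid
      turns per turn/um of overtwist, amplitude solenoid_amplitude nm),
      and the built duplex winding is reduced by each conformation's
      actual centerline polar writhe, keeping the linking balance exact.
    - "rigid": no centerline bias, full overtwist built into the duplexes.
    """

    design_overtwist: float = 0.0
    partition_rule: str = "thermal"
    writhe_coupling: float = 0.25   # solenoid turns per (turn/um)
    solenoid_amplitude: float = 5.0  # nm
    amplitude_sd: float = 0.0        # nm, optional dispersion of the bias

    def validate(self) -> None:
        if self.partition_rule not in ("thermal", "rigid"):
            raise ValueError(f"unknown partition_rule {self.partition_rule!r}")


def solenoid_curvature_torsion(n_turns: float, radius: float,
                               contour_length: float):
    """Intrinsic (curvature, torsion) of a helix with the given number of
    turns and radius over the given contour length.

    Positive n_turns gives a right-handed solenoid (positive torsion).
    """
    if radius <= 0 or abs(n_turns) < 1e-12:
        return 0.0, 0.0
    sin_a = 2.0 * math.pi * radius * abs(n_turns) / contour_length
    if sin_a >= 1.0:
        raise ValueError("solenoid turns incompatible with contour length")
    cos_a = math.sqrt(1.0 - sin_a ** 2)
    kappa = sin_a ** 2 / radius
    tau = math.copysign(sin_a * cos_a / radius, n_turns)
    return kappa, tau


@njit(cache=True)
def _propagate_chain(n_seg, ds, stiffness, kappa0, tau0, u_draw, phi_draw):
    """Discrete WLC propagation with intrinsic curvature/torsion.

    Material frame (t, e1, e2) with e1 x e2 = t; intrinsic strain applied
    as a single Rodrigues rotation about (tau0 t + kappa0 e2) per step,
    thermal kinks as minimal rotations of t with wormlike-chain polar
    angles.  Returns node positions and per-node frames.
    """
    pos = np.zeros((n_seg + 1, 3))
    frames = np.zeros((n_seg + 1, 3, 3))
    t = np.array([0.0, 0.0, 1.0])
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, 1.0, 0.0])
    frames[0, 0], frames[0, 1], frames[0, 2] = t, e1, e2
    exp2k = math.exp(-2.0 * stiffness) if stiffness < 350.0 else 0.0
    for i in range(n_seg):
        pos[i + 1] = pos[i] + ds * t
        # intrinsic rotation
        wx = tau0 * t[0] + kappa0 * e2[0]
        wy = tau0 * t[1] + kappa0 * e2[1]
        wz = tau0 * t[2] + kappa0 * e2[2]
        wnorm = math.sqrt(wx * wx + wy * wy + wz * wz)
        if wnorm > 1e-14:
            ax = np.array([wx / wnorm, wy / wnorm, wz / wnorm])
            ang = wnorm * ds
            c, s = math.cos(ang), math.sin(ang)
            for vec in (t, e1, e2):
                av = ax[0] * vec[0] + ax[1] * vec[1] + ax[2] * vec[2]
                cx = ax[1] * vec[2] - ax[2] * vec[1]
                cy = ax[2] * vec[0] - ax[0] * vec[2]
                cz = ax[0] * vec[1] - ax[1] * vec[0]
                vec[0] = vec[0] * c + cx * s + ax[0] * av * (1 - c)
                vec[1] = vec[1] * c + cy * s + ax[1] * av * (1 - c)
                vec[2] = vec[2] * c + cz * s + ax[2] * av * (1 - c)
        # thermal kink: cos(theta) from p ~ exp(stiffness * cos theta)
        u = u_draw[i]
        arg = 1.0 - u * (1.0 - exp2k)
        if arg < 1e-300:
            arg = 1e-300
        ct = 1.0 + math.log(arg) / stiffness
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        st = math.sqrt(1.0 - ct * ct)
        phi = phi_draw[i]
        # bend direction in the normal plane and rotation axis = t x d
        dx = math.cos(phi) * e1[0] + math.sin(phi) * e2[0]
        dy = math.cos(phi) * e1[1] + math.sin(phi) * e2[1]
        dz = math.cos(phi) * e1[2] + math.sin(phi) * e2[2]
        ax0 = t[1] * dz - t[2] * dy
        ax1 = t[2] * dx - t[0] * dz
        ax2 = t[0] * dy - t[1] * dx
        anorm = math.sqrt(ax0 * ax0 + ax1 * ax1 + ax2 * ax2)
        if anorm > 1e-14 and st > 0.0:
            ax = np.array([ax0 / anorm, ax1 / anorm, ax2 / anorm])
            for vec in (t, e1, e2):
                av = ax[0] * vec[0] + ax[1] * vec[1] + ax[2] * vec[2]
                cx = ax[1] * vec[2] - ax[2] * vec[1]
                cy = ax[2] * vec[0] - ax[0] * vec[2]
                cz = ax[0] * vec[1] - ax[1] * vec[0]
                vec[0] = vec[0] * ct + cx * st + ax[0] * av * (1 - ct)
                vec[1] = vec[1] * ct + cy * st + ax[1] * av * (1 - ct)
                vec[2] = vec[2] * ct + cz * st + ax[2] * av * (1 - ct)
        frames[i + 1, 0], frames[i + 1, 1], frames[i + 1, 2] = t, e1, e2
    return pos, frames


def sample_centerline(params: ChainParameters, rng: np.random.Generator):
    """Draw one centerline from the discrete wormlike chain.

    Returns (positions (n+1, 3) nm, frames (n+1, 3, 3) with rows t, e1,
    e2).  Reproducible given the generator state.
    """
    params.validate()
    n = params.n_segments
    stiffness = params.persistence_length / params.segment_length
    u_draw = rng.random(n)
    phi_draw = rng.random(n) * 2.0 * np.pi
    return _propagate_chain(n, params.segment_length, stiffness,
                            params.intrinsic_curvature,
                            params.intrinsic_torsion, u_draw, phi_draw)


def decorate_bundle(centerline: np.ndarray, geometry: BundleGeometry,
                    linking: LinkingTarget, axial_twist_rate: float = 0.0,
                    contour_length: float | None = None,
                    design_label: str = "synthetic") -> FilamentConformation:
    """Decorate a centerline as a six-helix bundle.

    The six duplex axes sit at hexagon vertices in a twist-free frame of
    the centerline, rotated along the contour at axial_twist_rate
    (turns/um).  Each duplex's two strands are wound about its own axis in
    that axis's rotation-minimizing frame, so the built winding rate is
    exactly the twist measured by the stacking-angle integral.  Under the
    "thermal" partition rule the built overtwist is the design overtwist
    minus this conformation's centerline polar writhe (in turns/um).
    """
    geometry.validate(contour_length if contour_length is not None
                      else geometry.rise * geometry.bp_count)
    linking.validate()
    nbp = geometry.bp_count
    cs, s_nodes = arclength_spline(centerline)
    s_k = np.arange(nbp) * geometry.rise
    if s_k[-1] > s_nodes[-1] * 1.02:
        raise ValueError("centerline too short for bp_count * rise")
    pts = cs(np.clip(s_k, 0.0, s_nodes[-1]))
    t, f1, f2 = rotation_minimizing_frame(pts)

    writhe_turns_per_um = 0.0
    if linking.partition_rule == "thermal":
        axis = gyration_axes(pts)[1][:, 0]
        if np.dot(axis, pts[-1] - pts[0]) < 0:
            axis = -axis
        try:
            wr_per_nm = polar_writhe_points(pts, axis)  # turns/nm
            writhe_turns_per_um = wr_per_nm * 1.0e3
        except ValueError:
            writhe_turns_per_um = 0.0  # turning point: no correction
    built_overtwist = linking.design_overtwist - writhe_turns_per_um
    tw_built = geometry.duplex_twist_density + built_overtwist * 1.0e-3

    s_axis = np.arange(nbp) * geometry.rise
    phi_bundle = (2.0 * np.pi * axial_twist_rate * 1.0e-3) * s_axis

    n_sites = geometry.n_duplex * nbp * 2
    positions = np.zeros((n_sites, 3))
    base_vectors = np.zeros((n_sites, 3))
    normal_vectors = np.zeros((n_sites, 3))
    strand_id = np.zeros(n_sites, dtype=np.int64)
    duplex_id = np.zeros(n_sites, dtype=np.int64)
    bp_idx = np.zeros(n_sites, dtype=np.int64)

    k = 0
    for d in range(geometry.n_duplex):
        phi_d = 2.0 * np.pi * d / geometry.n_duplex
        ang = phi_d + phi_bundle
        axis_pts = (pts + geometry.hex_radius
                    * (np.cos(ang)[:, None] * f1 + np.sin(ang)[:, None] * f2))
        td, g1, g2 = rotation_minimizing_frame(
            axis_pts, normal0=np.cos(ang[0]) * f1[0] + np.sin(ang[0]) * f2[0])
        seg = np.linalg.norm(np.diff(axis_pts, axis=0), axis=1)
        s_d = np.concatenate([[0.0], np.cumsum(seg)])
        theta = phi_d + 2.0 * np.pi * tw_built * s_d
        nhat = np.cos(theta)[:, None] * g1 + np.sin(theta)[:, None] * g2
        for s in (0, 1):
            sgn = 1.0 if s == 0 else -1.0
            sl = slice(k, k + nbp)
            positions[sl] = axis_pts + sgn * geometry.duplex_radius * nhat
            base_vectors[sl] = -sgn * nhat
            normal_vectors[sl] = sgn * td
            strand_id[sl] = s
            duplex_id[sl] = d
            bp_idx[sl] = np.arange(nbp)
            k += nbp
    lc = contour_length if contour_length is not None else geometry.rise * nbp
    return FilamentConformation(positions, base_vectors, normal_vectors,
                                strand_id, duplex_id, bp_idx,
                                geometry.n_duplex, lc, geometry.diameter,
                                design_label)


def generate_ensemble(params: ChainParameters, geometry: BundleGeometry,
                      linking: LinkingTarget, n: int,
                      seed: int | None = None,
                      design_label: str = "synthetic"
                      ) -> ConformationEnsemble:
    """Generate n i.i.d. decorated bundle conformations.

    Deterministic under a fixed seed (defaults to params.seed); provenance
    records all parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    linking.validate()
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    base_turns = linking.writhe_coupling * linking.design_overtwist
    conformations = []
    for i in range(n):
        rng = np.random.Generator(np.random.PCG64(children[i]))
        amp = linking.solenoid_amplitude
        if linking.amplitude_sd > 0:
            amp = abs(rng.normal(amp, linking.amplitude_sd))
        kap, tau = (0.0, 0.0)
        if linking.partition_rule == "thermal" and abs(base_turns) > 1e-12:
            kap, tau = solenoid_curvature_torsion(
                base_turns, amp, params.contour_length)
        p = ChainParameters(params.contour_length, params.segment_length,
                            params.persistence_length,
                            params.intrinsic_curvature + kap,
                            params.intrinsic_torsion + tau,
                            params.axial_twist_rate, seed)
        pts, _ = sample_centerline(p, rng)
        conformations.append(decorate_bundle(
            pts, geometry, linking, params.axial_twist_rate,
            params.contour_length, design_label))
    provenance = {"generator": "chiralfil.synth", "seed": int(seed),
                  "n": int(n), "design_label": design_label,
                  "chain": asdict(params), "geometry": asdict(geometry),
                  "linking": asdict(linking)}
    return ConformationEnsemble(conformations, provenance)


# ---------------------------------------------------------------------------
# Ideal fixtures
# ---------------------------------------------------------------------------

def ideal_helix_curve(contour_length: float, amplitude: float,
                      mode_number: int, handedness: int = 1,
                      n_points: int = 1024):
    """Ideal circular-helix transverse mode on the package's s-grid.

    r(s_j) = s_j u + a (cos(2 pi m s_j / l_c) v + h sin(...) w) with
    s_j = j l_c / N, u = z, v = x, w = y.  handedness +1 gives a
    right-handed displacement about +u.  Returns (points, (u, v, w)).
    """
    if mode_number < 1:
        raise ValueError("mode_number must be >= 1")
    if amplitude > 0.2 * contour_length:
        raise ValueError("amplitude must be << contour length")
    s = np.arange(n_points) * contour_length / n_points
    phase = 2.0 * np.pi * mode_number * s / contour_length
    u = np.array([0.0, 0.0, 1.0])
    v = np.array([1.0, 0.0, 0.0])
    w = np.array([0.0, 1.0, 0.0])
    pts = (s[:, None] * u + amplitude * np.cos(phase)[:, None] * v
           + handedness * amplitude * np.sin(phase)[:, None] * w)
    return pts, (u, v, w)


def _curve_to_conformation(pts: np.ndarray, contour_length: float,
                           label: str) -> FilamentConformation:
    """Wrap a backbone curve as a degenerate 6-duplex conformation whose
    per-plane duplex midpoints all lie exactly on the curve."""
    nbp = pts.shape[0]
    t, f1, f2 = rotation_minimizing_frame(pts)
    n_sites = 6 * nbp * 2
    positions = np.zeros((n_sites, 3))
    base = np.zeros((n_sites, 3))
    norm = np.zeros((n_sites, 3))
    strand = np.zeros(n_sites, dtype=np.int64)
    duplex = np.zeros(n_sites, dtype=np.int64)
    bp = np.zeros(n_sites, dtype=np.int64)
    k = 0
    for d in range(6):
        phi = 2.0 * np.pi * d / 6.0
        nhat = np.cos(phi) * f1 + np.sin(phi) * f2
        for s in (0, 1):
            sgn = 1.0 if s == 0 else -1.0
            sl = slice(k, k + nbp)
            positions[sl] = pts + sgn * 0.5 * nhat
            base[sl] = -sgn * nhat
            norm[sl] = sgn * t
            strand[sl] = s
            duplex[sl] = d
            bp[sl] = np.arange(nbp)
            k += nbp
    return FilamentConformation(positions, base, norm, strand, duplex, bp,
                                6, contour_length, 6.0, label)


def make_ideal_helix(contour_length: float = 420.0, amplitude: float = 4.0,
                     mode_number: int = 3, handedness: int = 1,
                     n_points: int = 1024) -> FilamentConformation:
    """Ideal circular-helix fixture as a FilamentConformation."""
    pts, _ = ideal_helix_curve(contour_length, amplitude, mode_number,
                               handedness, n_points)
    return _curve_to_conformation(
        pts, contour_length, f"helix_m{mode_number}_h{handedness:+d}")


def make_straight_rod(contour_length: float = 420.0,
                      n_points: int = 1024) -> FilamentConformation:
    """Straight-rod fixture (zero transverse displacement everywhere)."""
    s = np.arange(n_points) * contour_length / n_points
    pts = np.zeros((n_points, 3))
    pts[:, 2] = s
    return _curve_to_conformation(pts, contour_length, "rod")


def make_solenoid_curve(contour_length: float = 420.0, n_turns: float = 2.0,
                        pitch_angle_deg: float = 10.0, n_points: int = 1000):
    """Arclength-sampled circular helix with a prescribed pitch angle.

    The pitch angle alpha is the angle between the tangent and the long
    axis; the radius follows from the turn count.  Positive n_turns gives
    a right-handed solenoid.  Returns (points, axis u).
    """
    alpha = math.radians(pitch_angle_deg)
    h = 1.0 if n_turns >= 0 else -1.0
    m = abs(n_turns)
    radius = contour_length * math.sin(alpha) / (2.0 * math.pi * m)
    s = np.linspace(0.0, contour_length, n_points)
    phi = h * 2.0 * np.pi * m * s / contour_length
    pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                           s * math.cos(alpha)])
    return pts, np.array([0.0, 0.0, 1.0])


def end_to_end_autocorrelation(ensemble, max_lag: int | None = None
                               ) -> np.ndarray:
    """Autocorrelation of the end-to-end distance along the ensemble order.

    Diagnostic for imported trajectories, whose frames may be time
    correlated; synthetic ensembles are i.i.d. by construction and should
    decorrelate at lag 1.  Returns the normalized autocorrelation for
    lags 0..max_lag (default count // 4).
    """
    from .spectra import extract_backbone
    dists = []
    for conf in ensemble:
        bb = extract_backbone(conf, 0)
        dists.append(np.linalg.norm(bb.positions[-1] - bb.positions[0]))
    x = np.asarray(dists) - np.mean(dists)
    n = x.size
    if max_lag is None:
        max_lag = max(1, n // 4)
    var = float(x @ x) / n
    if var == 0:
        return np.concatenate([[1.0], np.zeros(max_lag)])
    out = [1.0]
    for lag in range(1, max_lag + 1):
        out.append(float(x[:-lag] @ x[lag:]) / ((n - lag) * var))
    return np.array(out)
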