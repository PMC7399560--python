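"""Pair interactions: screened electrostatics + hard cores, and the
rigid-body packing used by the virial Monte Carlo stage.

The intermolecular potential is a sum over inter-filament site pairs of a
hard core (infinite on overlap) and a Debye-Hueckel tail,

    U(r) = q_i q_j l_B exp(-r / lambda_D) / r   [kT, r in nm],

truncated at a cutoff of a few screening lengths.  Site charges are
effective (counterion condensation is not modeled); the per-nucleotide
default of 0.5 e is the main fidelity knob of the electrostatic stage.

Filaments enter the Monte Carlo integrals as :class:`RigidBody` packs:
site coordinates in the molecular (gyration) frame so that the body x
axis is the long axis u, plus capsule bounds for cheap rejection.  A
bead-level coarse-graining of the six-helix bundle (per-duplex or
centerline beads) keeps pair sums tractable; an analytic hard
spherocylinder body is provided for validation against classical hard-rod
theory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _mc
from .constants import (EPSILON_0, E_CHARGE, K_BOLTZMANN, N_AVOGADRO,
                        WATER_EPS_R, bjerrum_length_nm)
from .io import ConformationEnsemble, FilamentConformation
from .spectra import extract_backbone, gyration_frame


def debye_length(c_salt: float, temperature: float = 293.0,
                 eps_r: float = WATER_EPS_R) -> float:
    """Debye screening length (nm) of a 1:1 electrolyte.

    c_salt in mol/L; ionic strength I = c_salt for monovalent salt.
    """
    if c_salt <= 0:
        raise ValueError("c_salt must be positive")
    ionic_m3 = c_salt * 1000.0 * N_AVOGADRO  # ions of each sign per m^3
    lam2 = (EPSILON_0 * eps_r * K_BOLTZMANN * temperature
            / (2.0 * ionic_m3 * E_CHARGE ** 2))
    return math.sqrt(lam2) * 1e9


@dataclass
class InteractionModel:
    """Site-site hard-core + Debye-Hueckel interaction parameters."""

    site_diameter: float = 0.7      # nm, hard-core diameter per site
    site_charge: float = 0.5        # effective charge per nucleotide, e
    c_salt: float = 0.26            # mol/L
    temperature: float = 293.0      # K
    eps_r: float = WATER_EPS_R
    debye_nm: float = field(init=False)
    bjerrum_nm: float = field(init=False)
    cutoff: float = field(init=False)

    def __post_init__(self) -> None:
        self.debye_nm = debye_length(self.c_salt, self.temperature,
                                     self.eps_r)
        self.bjerrum_nm = bjerrum_length_nm(self.temperature, self.eps_r)
        self.cutoff = self.cutoff_for(self.site_diameter)

    def cutoff_for(self, diameter: float) -> float:
        """Tail cutoff for sites of the given hard-core diameter.

        The screened tail must extend beyond contact, so the cutoff is
        measured from the hard-core distance: diameter + 3 lambda_D.
        """
        return diameter + 3.0 * self.debye_nm


@dataclass
class RigidBody:
    """One conformation packed for the MC stage, in its molecular frame."""

    sites: np.ndarray       # (n, 3), nm; x axis = long axis u
    charges: np.ndarray     # (n,), e
    diameter: float         # hard-core site diameter, nm
    kind: int = 0           # 0 = beads, 1 = analytic spherocylinder
    axis_half: float = 0.0
    lat_radius: float = 0.0

    def __post_init__(self) -> None:
        self.sites = np.ascontiguousarray(self.sites, dtype=float)
        self.charges = np.ascontiguousarray(self.charges, dtype=float)
        if self.axis_half == 0.0:
            self.axis_half = float(np.abs(self.sites[:, 0]).max())
        if self.lat_radius == 0.0 and self.kind == 0:
            lat = float(np.sqrt(self.sites[:, 1] ** 2
                                + self.sites[:, 2] ** 2).max())
            self.lat_radius = lat + self.diameter / 2.0

    def mirrored(self) -> "RigidBody":
        s = self.sites.copy()
        s[:, 2] *= -1.0  # reflect across the (u, v) plane
        return RigidBody(s, self.charges.copy(), self.diameter, self.kind,
                         self.axis_half, self.lat_radius)


@dataclass
class BodyEnsemble:
    """Homogeneous stack of RigidBody conformations for the MC kernels."""

    positions: np.ndarray   # (n_conf, n_sites, 3)
    charges: np.ndarray     # (n_sites,)
    diameter: float
    kind: int
    axis_half: float        # max over conformations
    lat_radius: float

    @classmethod
    def from_bodies(cls, bodies: list[RigidBody]) -> "BodyEnsemble":
        n_sites = {b.sites.shape[0] for b in bodies}
        if len(n_sites) != 1:
            raise ValueError("bodies have differing site counts")
        pos = np.stack([b.sites for b in bodies])
        return cls(np.ascontiguousarray(pos),
                   bodies[0].charges.copy(), bodies[0].diameter,
                   bodies[0].kind,
                   max(b.axis_half for b in bodies),
                   max(b.lat_radius for b in bodies))

    @property
    def count(self) -> int:
        return self.positions.shape[0]

    def mirrored(self) -> "BodyEnsemble":
        pos = self.positions.copy()
        pos[:, :, 2] *= -1.0
        return BodyEnsemble(pos, self.charges.copy(), self.diameter,
                            self.kind, self.axis_half, self.lat_radius)

    def subset(self, indices) -> "BodyEnsemble":
        return BodyEnsemble(
            np.ascontiguousarray(self.positions[np.asarray(indices)]),
            self.charges, self.diameter, self.kind, self.axis_half,
            self.lat_radius)


def make_spherocylinder(length: float, diameter: float) -> RigidBody:
    """Analytic hard spherocylinder (axis along x), for validation."""
    half = length / 2.0
    sites = np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]])
    return RigidBody(sites, np.zeros(2), diameter, kind=1,
                     axis_half=half, lat_radius=diameter / 2.0)


def coarse_grain(conformation: FilamentConformation,
                 model: InteractionModel, mode: str = "duplex",
                 target_spacing: float = 2.5,
                 bead_diameter: float | None = None,
                 trim_bp: int = 0) -> RigidBody:
    """Bead-level rigid body of one conformation in its molecular frame.

    mode "duplex": beads along each of the six duplex axes (retains the
    chiral bundle surface); mode "centerline": beads on the filament
    backbone only (retains solenoidal shape chirality, cheapest).  Bead
    charges aggregate the effective charge of the nucleotides each bead
    replaces.
    """
    backbone = extract_backbone(conformation, trim_bp)
    frame = gyration_frame(backbone)
    M = frame.as_matrix()

    def to_body(points):
        return (points - points.mean(axis=0)) @ M

    if mode == "centerline":
        curves = [np.mean([conformation.bp_planes(d)
                           for d in range(conformation.n_duplex)], axis=0)]
        nt_per_plane = 2 * conformation.n_duplex
        if bead_diameter is None:
            bead_diameter = conformation.diameter
    elif mode == "duplex":
        curves = [conformation.bp_planes(d)
                  for d in range(conformation.n_duplex)]
        nt_per_plane = 2
        if bead_diameter is None:
            bead_diameter = 2.4
    else:
        raise ValueError(f"unknown coarse-grain mode {mode!r}")

    # common center: the conformation's overall bp-plane centroid
    allpts = np.concatenate(curves)
    center = allpts.mean(axis=0)
    sites, charges = [], []
    for curve in curves:
        n = curve.shape[0]
        stride = max(1, int(round(target_spacing / 0.34)))
        idx = np.arange(0, n, stride)
        sites.append((curve[idx] - center) @ M)
        q = np.full(idx.size, model.site_charge * nt_per_plane * stride)
        charges.append(q)
    return RigidBody(np.concatenate(sites), np.concatenate(charges),
                     bead_diameter, kind=0)


def coarse_grain_ensemble(ensemble: ConformationEnsemble,
                          model: InteractionModel, mode: str = "duplex",
                          target_spacing: float = 2.5,
                          bead_diameter: float | None = None,
                          trim_bp: int = 0) -> BodyEnsemble:
    bodies = [coarse_grain(c, model, mode, target_spacing, bead_diameter,
                           trim_bp) for c in ensemble]
    return BodyEnsemble.from_bodies(bodies)


def nucleotide_body(conformation: FilamentConformation,
                    model: InteractionModel) -> RigidBody:
    """Full nucleotide-resolution rigid body (cell-list territory)."""
    backbone = extract_backbone(conformation, 0)
    frame = gyration_frame(backbone)
    pts = conformation.positions
    sites = (pts - pts.mean(axis=0)) @ frame.as_matrix()
    charges = np.full(pts.shape[0], model.site_charge)
    return RigidBody(sites, charges, model.site_diameter, kind=0)


#: above this many site pairs, pair_energy switches to the cell list
CELL_LIST_PAIR_THRESHOLD = 250_000


def pair_energy(body_a: RigidBody, body_b: RigidBody,
                model: InteractionModel, r12: np.ndarray,
                R1: np.ndarray | None = None,
                R2: np.ndarray | None = None) -> float:
    """Interaction energy (kT) of two oriented bodies at separation r12.

    Returns math.inf on hard-core overlap.  Uses the direct double loop
    for small bodies and a cell list for large ones.
    """
    R1 = np.eye(3) if R1 is None else np.asarray(R1, dtype=float)
    R2 = np.eye(3) if R2 is None else np.asarray(R2, dtype=float)
    r12 = np.asarray(r12, dtype=float)
    pa = body_a.sites @ R1.T
    pb = body_b.sites @ R2.T + r12
    if body_a.kind == 1 and body_b.kind == 1:
        d2 = _mc._seg_seg_dist2(pa[0], pa[1], pb[0], pb[1])
        d = 0.5 * (body_a.diameter + body_b.diameter)
        return math.inf if d2 < d * d else 0.0
    d = 0.5 * (body_a.diameter + body_b.diameter)
    big = pa.shape[0] * pb.shape[0] > CELL_LIST_PAIR_THRESHOLD
    fn = _mc._energy_sites_cells if big else _mc._energy_sites
    e = fn(pa, body_a.charges, pb, body_b.charges, d * d,
           model.bjerrum_nm, model.debye_nm,
           model.cutoff_for(d) ** 2)
    return math.inf if e >= _mc.BIG else float(e)


def mayer_average(bodies: BodyEnsemble, model: InteractionModel,
                  r12: np.ndarray, R1: np.ndarray, R2: np.ndarray,
                  n_samples: int = 1000, seed: int = 0) -> float:
    """Conformationally averaged Mayer function at fixed (r12, R1, R2).

    Estimated by uniform random draws of conformation pairs; bounded in
    [-1, 0] for purely repulsive interactions.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    use_cells = bodies.positions.shape[1] ** 2 > CELL_LIST_PAIR_THRESHOLD
    return float(_mc.mayer_fixed_pair(
        bodies.positions, bodies.charges, bodies.kind, bodies.diameter,
        bodies.axis_half, bodies.lat_radius,
        np.ascontiguousarray(R1, dtype=float),
        np.ascontiguousarray(R2, dtype=float),
        np.ascontiguousarray(r12, dtype=float),
        model.bjerrum_nm, model.debye_nm,
        model.cutoff_for(bodies.diameter), n_samples,
        seed % 2 ** 31, use_cells))
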