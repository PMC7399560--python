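"""Duplex twist densities and backbone polar writhe.

Per-duplex twist is the stacking-angle integral

    Tw_i = (1 / 2 pi l_i) int ds  t_i . (n_i x dn_i/ds),

with t_i the duplex centerline tangent and n_i the unit vector joining
the two strands, evaluated on cubic-spline interpolants with composite
Simpson quadrature (turns per unit length; reported in turns/um).  The
overtwist is DeltaTw = mean_i Tw_i - Tw0 with 1/Tw0 = 10.5 bp by default.

The filament-scale solenoidal deformation is measured by the local polar
writhe of the backbone about its long axis u,

    Wr = (1 / 2 pi l_c) int ds  u . (t x dt/ds) / (1 + u . t),

valid when the backbone has no turning point along u; Wr > 0 for
right-handed winding of t about u (reported in 1/mm).  The backbone is
pre-smoothed with a Savitzky-Golay filter (order 9) to remove the
short-wavelength jitter inherent to the geometric centerline definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .constants import (TW0_TURNS_PER_NM, TURNS_PER_NM_TO_TURNS_PER_UM,
                        PER_NM_TO_PER_MM)
from .io import ConformationEnsemble, FilamentConformation
from .spectra import BackboneCurve, MolecularFrame, extract_backbone, \
    gyration_frame


@dataclass
class TwistWritheRecord:
    """Twist/writhe measurements of one conformation (reporting units)."""

    tw_per_duplex: np.ndarray   # turns/um
    delta_tw: float             # turns/um, mean over duplexes minus Tw0
    writhe: float | None        # 1/mm; None if the precondition failed


@dataclass
class EnsembleTwistWrithe:
    records: list[TwistWritheRecord]
    delta_tw_mean: float
    delta_tw_se: float
    writhe_mean: float
    writhe_se: float
    twist_writhe_correlation: float
    n_writhe_failures: int


def duplex_twist(conformation: FilamentConformation, trim_bp: int = 10,
                 oversample: int = 8) -> np.ndarray:
    """Twist density of each duplex, turns/um.

    Splines the two strand curves against the duplex centerline arc
    length, forms n(s) = (r1 - r2)/|r1 - r2|, and integrates
    t . (n x dn/ds) by Simpson quadrature on an oversampled grid.
    """
    out = np.zeros(conformation.n_duplex)
    for d in range(conformation.n_duplex):
        r1 = conformation.strand_positions(d, 0)
        r2 = conformation.strand_positions(d, 1)
        nbp = r1.shape[0]
        if trim_bp:
            if nbp - 2 * trim_bp < 4:
                raise ValueError("fewer than 4 bp planes after trimming")
            r1 = r1[trim_bp:nbp - trim_bp]
            r2 = r2[trim_bp:nbp - trim_bp]
        center = 0.5 * (r1 + r2)
        seg = np.linalg.norm(np.diff(center, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        li = s[-1]
        cs_c = CubicSpline(s, center, axis=0)
        cs_d = CubicSpline(s, r1 - r2, axis=0)
        m = oversample * (r1.shape[0] - 1)
        if m % 2:
            m += 1
        sg = np.linspace(0.0, li, m + 1)
        tang = cs_c(sg, 1)
        tang /= np.linalg.norm(tang, axis=1)[:, None]
        dvec = cs_d(sg)
        dnorm = np.linalg.norm(dvec, axis=1)
        if np.any(dnorm < 1e-9):
            raise ValueError(f"duplex {d}: strands touch; normal undefined")
        nvec = dvec / dnorm[:, None]
        ddvec = cs_d(sg, 1)
        # dn/ds = (I - n n^T) d'(s) / |d|
        dn = (ddvec - np.sum(ddvec * nvec, axis=1)[:, None] * nvec) \
            / dnorm[:, None]
        integrand = np.sum(tang * np.cross(nvec, dn), axis=1)
        total_turns = simpson(integrand, x=sg) / (2.0 * np.pi)
        out[d] = total_turns / li * TURNS_PER_NM_TO_TURNS_PER_UM
    return out


def overtwist(conformation: FilamentConformation, trim_bp: int = 10,
              tw0_turns_per_nm: float = TW0_TURNS_PER_NM) -> float:
    """DeltaTw = mean duplex twist minus Tw0, turns/um."""
    tw = duplex_twist(conformation, trim_bp)
    return float(tw.mean() - tw0_turns_per_nm * TURNS_PER_NM_TO_TURNS_PER_UM)


def polar_writhe(backbone: BackboneCurve, frame: MolecularFrame,
                 presmooth_window: int = 21, presmooth_order: int = 9,
                 oversample: int = 4) -> float:
    """Local polar writhe of the backbone about frame.u, in 1/mm.

    The backbone positions are pre-smoothed along the contour with a
    Savitzky-Golay filter before splining.  Raises ValueError (naming the
    abscissa) if dr_u/ds <= 0 anywhere, in which case the local polar
    writhe decomposition does not apply.
    """
    pts = backbone.positions
    n = pts.shape[0]
    if presmooth_window and presmooth_window > presmooth_order \
            and n > presmooth_window:
        window = presmooth_window + (1 - presmooth_window % 2)
        pts = savgol_filter(pts, window, presmooth_order, axis=0)
    u = frame.u
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    lc = s[-1]
    cs = CubicSpline(s, pts, axis=0)
    m = oversample * (n - 1)
    if m % 2:
        m += 1
    sg = np.linspace(0.0, lc, m + 1)
    d1 = cs(sg, 1)
    d2 = cs(sg, 2)
    speed = np.linalg.norm(d1, axis=1)
    t = d1 / speed[:, None]
    ru_rate = t @ u
    if np.any(ru_rate <= 0.0):
        bad = sg[int(np.argmin(ru_rate))]
        raise ValueError(
            f"turning point along u near s = {bad:.2f} nm: local polar "
            "writhe undefined for this conformation")
    dt = (d2 - np.sum(d2 * t, axis=1)[:, None] * t) / speed[:, None]
    integrand = (np.cross(t, dt) @ u) / (1.0 + ru_rate)
    wr_per_nm = simpson(integrand, x=sg) / (2.0 * np.pi * lc)
    return float(wr_per_nm * PER_NM_TO_PER_MM)


def conformation_twist_writhe(conformation: FilamentConformation,
                              trim_bp: int = 10,
                              tw0_turns_per_nm: float = TW0_TURNS_PER_NM,
                              presmooth_window: int = 21
                              ) -> TwistWritheRecord:
    tw = duplex_twist(conformation, trim_bp)
    dtw = float(tw.mean()
                - tw0_turns_per_nm * TURNS_PER_NM_TO_TURNS_PER_UM)
    backbone = extract_backbone(conformation, trim_bp)
    frame = gyration_frame(backbone)
    try:
        wr = polar_writhe(backbone, frame, presmooth_window)
    except ValueError:
        wr = None
    return TwistWritheRecord(tw, dtw, wr)


def ensemble_twist_writhe(ensemble: ConformationEnsemble, trim_bp: int = 10,
                          tw0_turns_per_nm: float = TW0_TURNS_PER_NM,
                          presmooth_window: int = 21,
                          max_failure_fraction: float = 0.05
                          ) -> EnsembleTwistWrithe:
    """Per-conformation records plus ensemble means, SEs and the
    twist-writhe correlation.

    Conformations violating the writhe turning-point precondition are
    excluded from the writhe statistics and counted; if their fraction
    exceeds max_failure_fraction a ValueError is raised rather than
    silently reporting a biased mean.
    """
    if ensemble.count < 2:
        raise ValueError("need at least two conformations")
    records = [conformation_twist_writhe(c, trim_bp, tw0_turns_per_nm,
                                         presmooth_window)
               for c in ensemble]
    dtw = np.array([r.delta_tw for r in records])
    wr = np.array([r.writhe for r in records if r.writhe is not None])
    n_fail = sum(1 for r in records if r.writhe is None)
    if n_fail > max_failure_fraction * len(records):
        raise ValueError(
            f"{n_fail}/{len(records)} conformations fail the polar-writhe "
            "precondition; ensemble writhe would be biased")
    if wr.size < 2:
        raise ValueError("too few conformations with defined writhe")
    both = np.array([(r.delta_tw, r.writhe) for r in records
                     if r.writhe is not None])
    if np.std(both[:, 0]) > 0 and np.std(both[:, 1]) > 0:
        corr = float(np.corrcoef(both[:, 0], both[:, 1])[0, 1])
    else:
        corr = 0.0
    return EnsembleTwistWrithe(
        records,
        float(dtw.mean()), float(dtw.std(ddof=1) / np.sqrt(dtw.size)),
        float(wr.mean()), float(wr.std(ddof=1) / np.sqrt(wr.size)),
        corr, n_fail)
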