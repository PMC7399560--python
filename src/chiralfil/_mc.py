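"""Numba inner loops for the second-virial Monte Carlo integrations.

All kernels are single-threaded and seeded explicitly (np.random.seed
inside the jitted code), so every estimate is bit-reproducible.  Particle
"bodies" arrive as packed arrays: site positions in the molecular frame
(conformation index, site index, xyz), one charge per site, a hard-core
site diameter, and capsule bounds (half-length along the body x axis,
lateral radius) used for O(1) distance prechecks.  kind = 0 means a bead
model, kind = 1 an analytic hard spherocylinder (sites = axis endpoints).

Orientations use the x-convention Euler factorization
R = Rx(phi) Rz(theta) Rx(chi): the body long axis u = R e_x then has
polar cosine cos(theta) with respect to the laboratory director e_x, and
(cos theta, phi, chi) drawn uniformly give Haar-distributed rotations.
"""

import math

import numpy as np
from numba import njit

BIG = 1.0e30


@njit(cache=True, inline="always")
def _rot_from_euler(ct, phi, chi, R):
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp, sp = math.cos(phi), math.sin(phi)
    cc, sc = math.cos(chi), math.sin(chi)
    # R = Rx(phi) @ Rz(theta) @ Rx(chi)
    # Rz(theta) @ Rx(chi):
    m00, m01, m02 = ct, -st * cc, st * sc
    m10, m11, m12 = st, ct * cc, -ct * sc
    m20, m21, m22 = 0.0, sc, cc
    R[0, 0], R[0, 1], R[0, 2] = m00, m01, m02
    R[1, 0] = cp * m10 - sp * m20
    R[1, 1] = cp * m11 - sp * m21
    R[1, 2] = cp * m12 - sp * m22
    R[2, 0] = sp * m10 + cp * m20
    R[2, 1] = sp * m11 + cp * m21
    R[2, 2] = sp * m12 + cp * m22


@njit(cache=True, inline="always")
def _seg_seg_dist2(a0, a1, b0, b1):
    """Squared minimum distance between segments [a0,a1] and [b0,b1]."""
    dax = a1[0] - a0[0]; day = a1[1] - a0[1]; daz = a1[2] - a0[2]
    dbx = b1[0] - b0[0]; dby = b1[1] - b0[1]; dbz = b1[2] - b0[2]
    rx = a0[0] - b0[0]; ry = a0[1] - b0[1]; rz = a0[2] - b0[2]
    A = dax * dax + day * day + daz * daz
    B = dax * dbx + day * dby + daz * dbz
    C = dbx * dbx + dby * dby + dbz * dbz
    D = dax * rx + day * ry + daz * rz
    E = dbx * rx + dby * ry + dbz * rz
    den = A * C - B * B
    if den > 1e-12 * max(A * C, 1e-30):
        s = (B * E - C * D) / den
    else:
        s = 0.0
    if s < 0.0:
        s = 0.0
    elif s > 1.0:
        s = 1.0
    if C > 1e-30:
        t = (E + s * B) / C
    else:
        t = 0.0
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    if A > 1e-30:
        s = (B * t - D) / A
        if s < 0.0:
            s = 0.0
        elif s > 1.0:
            s = 1.0
    px = rx + s * dax - t * dbx
    py = ry + s * day - t * dby
    pz = rz + s * daz - t * dbz
    return px * px + py * py + pz * pz


@njit(cache=True)
def _transform(body, R, shift, out):
    n = body.shape[0]
    for i in range(n):
        x, y, z = body[i, 0], body[i, 1], body[i, 2]
        out[i, 0] = R[0, 0] * x + R[0, 1] * y + R[0, 2] * z + shift[0]
        out[i, 1] = R[1, 0] * x + R[1, 1] * y + R[1, 2] * z + shift[1]
        out[i, 2] = R[2, 0] * x + R[2, 1] * y + R[2, 2] * z + shift[2]


@njit(cache=True)
def _energy_sites(pa, qa, pb, qb, d2, lb, lam, cutoff2):
    """Site-site energy in kT; BIG on hard-core overlap."""
    na, nb = pa.shape[0], pb.shape[0]
    e = 0.0
    for i in range(na):
        ax, ay, az = pa[i, 0], pa[i, 1], pa[i, 2]
        qi = qa[i]
        for j in range(nb):
            dx = ax - pb[j, 0]
            dy = ay - pb[j, 1]
            dz = az - pb[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < d2:
                return BIG
            if r2 < cutoff2:
                r = math.sqrt(r2)
                e += lb * qi * qb[j] * math.exp(-r / lam) / r
    return e


@njit(cache=True)
def _energy_sites_cells(pa, qa, pb, qb, d2, lb, lam, cutoff2):
    """Cell-list variant of _energy_sites (linear in site count).

    Builds a uniform grid of cell edge = cutoff over body b's sites and
    visits only the 27 neighboring cells for each site of a.
    """
    na, nb = pa.shape[0], pb.shape[0]
    cut = math.sqrt(cutoff2)
    xmin, ymin, zmin = BIG, BIG, BIG
    xmax, ymax, zmax = -BIG, -BIG, -BIG
    for j in range(nb):
        if pb[j, 0] < xmin:
            xmin = pb[j, 0]
        if pb[j, 0] > xmax:
            xmax = pb[j, 0]
        if pb[j, 1] < ymin:
            ymin = pb[j, 1]
        if pb[j, 1] > ymax:
            ymax = pb[j, 1]
        if pb[j, 2] < zmin:
            zmin = pb[j, 2]
        if pb[j, 2] > zmax:
            zmax = pb[j, 2]
    ncx = max(1, int((xmax - xmin) / cut) + 1)
    ncy = max(1, int((ymax - ymin) / cut) + 1)
    ncz = max(1, int((zmax - zmin) / cut) + 1)
    ncell = ncx * ncy * ncz
    count = np.zeros(ncell + 1, dtype=np.int64)
    cell_of = np.empty(nb, dtype=np.int64)
    for j in range(nb):
        cx = int((pb[j, 0] - xmin) / cut)
        cy = int((pb[j, 1] - ymin) / cut)
        cz = int((pb[j, 2] - zmin) / cut)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell_of[j] = c
        count[c + 1] += 1
    for c in range(ncell):
        count[c + 1] += count[c]
    order = np.empty(nb, dtype=np.int64)
    fill = count[:-1].copy()
    for j in range(nb):
        c = cell_of[j]
        order[fill[c]] = j
        fill[c] += 1
    e = 0.0
    for i in range(na):
        ax, ay, az = pa[i, 0], pa[i, 1], pa[i, 2]
        qi = qa[i]
        cx = int((ax - xmin) / cut)
        cy = int((ay - ymin) / cut)
        cz = int((az - zmin) / cut)
        for ox in range(cx - 1, cx + 2):
            if ox < 0 or ox >= ncx:
                continue
            for oy in range(cy - 1, cy + 2):
                if oy < 0 or oy >= ncy:
                    continue
                for oz in range(cz - 1, cz + 2):
                    if oz < 0 or oz >= ncz:
                        continue
                    c = (ox * ncy + oy) * ncz + oz
                    for jj in range(count[c], count[c + 1]):
                        j = order[jj]
                        dx = ax - pb[j, 0]
                        dy = ay - pb[j, 1]
                        dz = az - pb[j, 2]
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < d2:
                            return BIG
                        if r2 < cutoff2:
                            r = math.sqrt(r2)
                            e += lb * qi * qb[j] * math.exp(-r / lam) / r
    return e


@njit(cache=True)
def _boltzmann_pair(bodies, charges, kind, diam, axis_half, lat_rad,
                    ia, ib, R1, R2, r12, lb, lam, cutoff, use_cells,
                    buf_a, buf_b):
    """exp(-beta U) for one sampled pair configuration."""
    # capsule precheck on the body long axes
    a0 = np.empty(3)
    a1 = np.empty(3)
    b0 = np.empty(3)
    b1 = np.empty(3)
    for k in range(3):
        a0[k] = -axis_half * R1[k, 0]
        a1[k] = axis_half * R1[k, 0]
        b0[k] = r12[k] - axis_half * R2[k, 0]
        b1[k] = r12[k] + axis_half * R2[k, 0]
    dmin2 = _seg_seg_dist2(a0, a1, b0, b1)
    reach = 2.0 * lat_rad + cutoff
    if dmin2 > reach * reach:
        return 1.0
    if kind == 1:
        # analytic hard spherocylinder
        if dmin2 < diam * diam:
            return 0.0
        return 1.0
    na = bodies.shape[1]
    zero = np.zeros(3)
    _transform(bodies[ia], R1, zero, buf_a)
    _transform(bodies[ib], R2, r12, buf_b)
    if use_cells:
        e = _energy_sites_cells(buf_a[:na], charges, buf_b[:na], charges,
                                diam * diam, lb, lam, cutoff * cutoff)
    else:
        e = _energy_sites(buf_a[:na], charges, buf_b[:na], charges,
                          diam * diam, lb, lam, cutoff * cutoff)
    if e >= BIG:
        return 0.0
    return math.exp(-e)


@njit(cache=True)
def kernel_mc(bodies, charges, kind, diam, axis_half, lat_rad, lb, lam,
              cutoff, bin_edges, n_per_pair, n_batches, box_half, seed,
              use_cells):
    """Stratified MC estimate of the angular virial kernel.

    Returns (kappa, se) on the (n_bins, n_bins) grid of cos-theta bins:
    kappa[i, j] = V_box * E[ f(r12, R1, R2) | cos t1 in bin i, cos t2 in
    bin j ], the Mayer function averaged over conformation pairs, azimuth
    and spin angles, and separations in the sampling box.
    """
    np.random.seed(seed)
    n_bins = bin_edges.shape[0] - 1
    n_conf = bodies.shape[0]
    n_sites = bodies.shape[1]
    vbox = 8.0 * box_half[0] * box_half[1] * box_half[2]
    kappa = np.zeros((n_bins, n_bins))
    se = np.zeros((n_bins, n_bins))
    R1 = np.empty((3, 3))
    R2 = np.empty((3, 3))
    r12 = np.empty(3)
    buf_a = np.empty((n_sites, 3))
    buf_b = np.empty((n_sites, 3))
    per_batch = max(1, n_per_pair // n_batches)
    for i in range(n_bins):
        for j in range(i, n_bins):
            bsum = np.zeros(n_batches)
            for b in range(n_batches):
                acc = 0.0
                for _ in range(per_batch):
                    ia = np.random.randint(0, n_conf)
                    ib = np.random.randint(0, n_conf)
                    ct1 = bin_edges[i] + np.random.random() * (
                        bin_edges[i + 1] - bin_edges[i])
                    ct2 = bin_edges[j] + np.random.random() * (
                        bin_edges[j + 1] - bin_edges[j])
                    _rot_from_euler(ct1, np.random.random() * 2 * math.pi,
                                    np.random.random() * 2 * math.pi, R1)
                    _rot_from_euler(ct2, np.random.random() * 2 * math.pi,
                                    np.random.random() * 2 * math.pi, R2)
                    for k in range(3):
                        r12[k] = (2.0 * np.random.random() - 1.0) \
                            * box_half[k]
                    w = _boltzmann_pair(bodies, charges, kind, diam,
                                        axis_half, lat_rad, ia, ib, R1, R2,
                                        r12, lb, lam, cutoff, use_cells,
                                        buf_a, buf_b)
                    acc += w - 1.0
                bsum[b] = acc / per_batch
            mean = bsum.mean()
            kappa[i, j] = vbox * mean
            kappa[j, i] = kappa[i, j]
            if n_batches > 1:
                sd = bsum.std() * math.sqrt(
                    n_batches / (n_batches - 1.0))
                se[i, j] = vbox * sd / math.sqrt(n_batches)
                se[j, i] = se[i, j]
    return kappa, se


@njit(cache=True, inline="always")
def _tab_lin(tab, x):
    """Linear interpolation of a table on the uniform grid over [-1, 1]."""
    ntab = tab.shape[0]
    p = (x + 1.0) * 0.5 * (ntab - 1)
    i = int(p)
    if i > ntab - 2:
        i = ntab - 2
    w = p - i
    return tab[i] * (1.0 - w) + tab[i + 1] * w


@njit(cache=True)
def elastic_mc(bodies, charges, kind, diam, axis_half, lat_rad, lb, lam,
               cutoff, psi_tab, psidot_tab, q_tab, inv_cdf, n_samples,
               n_batches, box_half, seed, use_cells):
    """MC estimates of the twist-modulus and chiral-strength integrals.

    cos(theta) is importance-sampled from the proposal density q (q_tab
    on the uniform [-1, 1] grid, inv_cdf its inverse CDF), which should
    roughly follow psi + |psidot|; each draw carries the weight
    (1/2) / q(x) so the estimator still targets the uniform-measure
    expectation.  Returns (I_K2, I_kt, se_K2, se_kt) with
    I_K2 = V E[f psidot1 psidot2 rz^2 u1y u2y] and
    I_kt = V E[f psi1 psidot2 rz u2y];
    beta K2 = (rho^2/2) I_K2, beta kt = (rho^2/2) I_kt.
    """
    np.random.seed(seed)
    n_conf = bodies.shape[0]
    n_sites = bodies.shape[1]
    ninv = inv_cdf.shape[0]
    vbox = 8.0 * box_half[0] * box_half[1] * box_half[2]
    R1 = np.empty((3, 3))
    R2 = np.empty((3, 3))
    r12 = np.empty(3)
    buf_a = np.empty((n_sites, 3))
    buf_b = np.empty((n_sites, 3))
    per_batch = max(1, n_samples // n_batches)
    bk2 = np.zeros(n_batches)
    bkt = np.zeros(n_batches)
    for b in range(n_batches):
        acc2 = 0.0
        acct = 0.0
        for _ in range(per_batch):
            ia = np.random.randint(0, n_conf)
            ib = np.random.randint(0, n_conf)
            u1 = np.random.random() * (ninv - 1)
            j1 = int(u1)
            ct1 = inv_cdf[j1] + (u1 - j1) * (
                inv_cdf[min(j1 + 1, ninv - 1)] - inv_cdf[j1])
            u2 = np.random.random() * (ninv - 1)
            j2 = int(u2)
            ct2 = inv_cdf[j2] + (u2 - j2) * (
                inv_cdf[min(j2 + 1, ninv - 1)] - inv_cdf[j2])
            phi1 = np.random.random() * 2 * math.pi
            phi2 = np.random.random() * 2 * math.pi
            _rot_from_euler(ct1, phi1, np.random.random() * 2 * math.pi, R1)
            _rot_from_euler(ct2, phi2, np.random.random() * 2 * math.pi, R2)
            for k in range(3):
                r12[k] = (2.0 * np.random.random() - 1.0) * box_half[k]
            w = _boltzmann_pair(bodies, charges, kind, diam, axis_half,
                                lat_rad, ia, ib, R1, R2, r12, lb, lam,
                                cutoff, use_cells, buf_a, buf_b)
            f = w - 1.0
            if f != 0.0:
                wi1 = 0.5 / _tab_lin(q_tab, ct1)
                wi2 = 0.5 / _tab_lin(q_tab, ct2)
                psi1 = _tab_lin(psi_tab, ct1)
                pd1 = _tab_lin(psidot_tab, ct1)
                pd2 = _tab_lin(psidot_tab, ct2)
                u1y = R1[1, 0]
                u2y = R2[1, 0]
                rz = r12[2]
                fw = f * wi1 * wi2
                acc2 += fw * pd1 * pd2 * rz * rz * u1y * u2y
                acct += fw * psi1 * pd2 * rz * u2y
        bk2[b] = vbox * acc2 / per_batch
        bkt[b] = vbox * acct / per_batch
    m2 = bk2.mean()
    mt = bkt.mean()
    if n_batches > 1:
        corr = math.sqrt(n_batches / (n_batches - 1.0))
        s2 = bk2.std() * corr / math.sqrt(n_batches)
        st = bkt.std() * corr / math.sqrt(n_batches)
    else:
        s2 = 0.0
        st = 0.0
    return m2, mt, s2, st


@njit(cache=True)
def pmf_mc(bodies, charges, kind, diam, axis_half, lat_rad, lb, lam,
           cutoff, gammas, n_samples, box_xy, box_z, seed, use_cells):
    """Boltzmann-averaged pair weight at fixed interaxial angle gamma.

    Particle 1's long axis is e_x; particle 2's axis is rotated by gamma
    about e_z (the near-contact normal); spins, conformations and
    separations in the crossing region are averaged over.  The normal
    offset is one-sided (rz in [0, box_z]): symmetric z sampling would
    relate (gamma, rz) to (-gamma, -rz) by a proper rotation and cancel
    the chiral asymmetry exactly.  Returns mean weights
    <exp(-beta U)>(gamma).
    """
    np.random.seed(seed)
    n_conf = bodies.shape[0]
    n_sites = bodies.shape[1]
    ng = gammas.shape[0]
    out = np.zeros(ng)
    R1 = np.empty((3, 3))
    R2 = np.empty((3, 3))
    r12 = np.empty(3)
    buf_a = np.empty((n_sites, 3))
    buf_b = np.empty((n_sites, 3))
    for g in range(ng):
        cg, sg = math.cos(gammas[g]), math.sin(gammas[g])
        acc = 0.0
        for _ in range(n_samples):
            ia = np.random.randint(0, n_conf)
            ib = np.random.randint(0, n_conf)
            chi1 = np.random.random() * 2 * math.pi
            chi2 = np.random.random() * 2 * math.pi
            # R1 = Rx(chi1); axis e_x
            _rot_from_euler(1.0, 0.0, chi1, R1)
            # R2 = Rz(gamma) Rx(chi2)
            _rot_from_euler(1.0, 0.0, chi2, R2)
            for r in range(3):
                x = R2[0, r]
                y = R2[1, r]
                R2[0, r] = cg * x - sg * y
                R2[1, r] = sg * x + cg * y
            r12[0] = (2.0 * np.random.random() - 1.0) * box_xy
            r12[1] = (2.0 * np.random.random() - 1.0) * box_xy
            r12[2] = np.random.random() * box_z
            acc += _boltzmann_pair(bodies, charges, kind, diam, axis_half,
                                   lat_rad, ia, ib, R1, R2, r12, lb, lam,
                                   cutoff, use_cells, buf_a, buf_b)
        out[g] = acc / n_samples
    return out


@njit(cache=True)
def mayer_fixed_pair(bodies, charges, kind, diam, axis_half, lat_rad,
                     R1, R2, r12, lb, lam, cutoff, n_samples, seed,
                     use_cells):
    """Conformationally averaged Mayer function at fixed (r12, R1, R2)."""
    np.random.seed(seed)
    n_conf = bodies.shape[0]
    n_sites = bodies.shape[1]
    buf_a = np.empty((n_sites, 3))
    buf_b = np.empty((n_sites, 3))
    acc = 0.0
    for _ in range(n_samples):
        ia = np.random.randint(0, n_conf)
        ib = np.random.randint(0, n_conf)
        acc += _boltzmann_pair(bodies, charges, kind, diam, axis_half,
                               lat_rad, ia, ib, R1, R2, r12, lb, lam,
                               cutoff, use_cells, buf_a, buf_b) - 1.0
    return acc / n_samples
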