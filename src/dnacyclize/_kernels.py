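"""Numba kernels: lattice Metropolis MCMC and rigid base-pair chain generation.

These are internal; the public entry points live in :mod:`dnacyclize.epbd`,
:mod:`dnacyclize.chain_mc` and :mod:`dnacyclize.jfactor`.  All kernels take a
``numpy.random.Generator`` and consume randomness in a documented, fixed
order so results are reproducible bit-for-bit for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Lattice (breathing) Monte Carlo


@njit(cache=True)
def _site_energy(u, v, j, D, a, Ku, Kv, rho, beta_anh):
    """Morse energy of site j plus its two adjacent stacking bonds.

    Bond ``k`` couples sites ``k-1`` and ``k`` (periodic), with force
    constants ``Ku[k]``/``Kv[k]``.
    """
    n = u.shape[0]
    y = u[j] - v[j]
    e = np.expm1(-a[j] * y)
    total = D[j] * e * e
    for bond in (j, (j + 1) % n):
        jm = (bond - 1) % n
        du = u[bond] - u[jm]
        dv = v[bond] - v[jm]
        ys = (u[bond] - v[bond]) + (u[jm] - v[jm])
        cross = np.sqrt(Ku[bond]) * du - np.sqrt(Kv[bond]) * dv
        total += (
            0.5 * Ku[bond] * du * du
            + 0.5 * Kv[bond] * dv * dv
            + 0.25 * rho * np.exp(-beta_anh * ys) * cross * cross
        )
    return total


@njit(cache=True)
def epbd_mcmc(
    rng,
    u,
    v,
    D,
    a,
    Ku,
    Kv,
    rho,
    beta_anh,
    inv_kt,
    width,
    y_max,
    n_equil,
    n_sample,
    thin,
    threshold,
):
    """Metropolis sampling of the breathing lattice.

    One sweep makes N single-site proposals on the u strand, then N on the v
    strand (uniform displacements of half-width ``width``), in site order; the
    per-proposal random numbers are one uniform for the displacement and one
    for the acceptance test.  After each sweep the zero mode (a rigid common
    shift of both strands, to which the potential is blind) is re-centred.

    Returns ``(open_counts, n_samples, n_accepted, n_proposed)`` where
    ``open_counts[n]`` counts sampled states with ``u_n - v_n > threshold``.
    """
    n = u.shape[0]
    open_counts = np.zeros(n, dtype=np.int64)
    n_samples = 0
    n_acc = 0
    n_prop = 0
    total_sweeps = n_equil + n_sample
    for sweep in range(total_sweeps):
        for strand in range(2):
            x = u if strand == 0 else v
            for j in range(n):
                old = x[j]
                delta = width * (2.0 * rng.random() - 1.0)
                acc_u = rng.random()
                new = old + delta
                # y = u - v is softly walled below by the Morse term and
                # capped above at y_max (the dissociated plateau is flat and
                # non-normalizable); out-of-bounds proposals are rejected.
                if strand == 0:
                    y_new = new - v[j]
                else:
                    y_new = u[j] - new
                n_prop += 1
                if y_new > y_max:
                    continue
                e_old = _site_energy(u, v, j, D, a, Ku, Kv, rho, beta_anh)
                x[j] = new
                e_new = _site_energy(u, v, j, D, a, Ku, Kv, rho, beta_anh)
                dv = e_new - e_old
                if dv <= 0.0 or acc_u < np.exp(-dv * inv_kt):
                    n_acc += 1
                else:
                    x[j] = old
        # remove the free translation mode
        shift = 0.0
        for j in range(n):
            shift += 0.5 * (u[j] + v[j])
        shift /= n
        for j in range(n):
            u[j] -= shift
            v[j] -= shift
        if sweep >= n_equil and (sweep - n_equil) % thin == 0:
            n_samples += 1
            for j in range(n):
                if u[j] - v[j] > threshold:
                    open_counts[j] += 1
    return open_counts, n_samples, n_acc, n_prop


# ---------------------------------------------------------------------------
# Rigid base-pair chain generation
#
# Frame composition uses the symmetric (mid-step) construction: with bend
# magnitude G = hypot(tilt, roll) and bend phase phi = atan2(tilt, roll), the
# step rotation is Rz(tw/2 - phi) . Ry(G) . Rz(tw/2 + phi) and the
# displacement (shift, slide, rise) is applied in the mid-step frame
# Rz(tw/2 - phi) . Ry(G/2) . Rz(phi).  Pure twist then rotates about the
# base-pair normal, and tilt/roll act about the mid-frame x/y axes.


@njit(cache=True, inline="always")
def _step_update(T, o, tilt, roll, twist, shift, slide, rise):
    G = np.sqrt(tilt * tilt + roll * roll)
    if G > 1e-14:
        cphi = roll / G
        sphi = tilt / G
    else:
        cphi = 1.0
        sphi = 0.0
    ch = np.cos(0.5 * G)
    sh = np.sin(0.5 * G)
    cg = 1.0 - 2.0 * sh * sh
    sg = 2.0 * sh * ch
    ct = np.cos(0.5 * twist)
    st = np.sin(0.5 * twist)
    # angle sums: a = tw/2 - phi, b = tw/2 + phi
    ca = ct * cphi + st * sphi
    sa = st * cphi - ct * sphi
    cb = ct * cphi - st * sphi
    sb = st * cphi + ct * sphi

    # step rotation R = Rz(a) Ry(G) Rz(b)
    r00 = ca * cg * cb - sa * sb
    r01 = -ca * cg * sb - sa * cb
    r02 = ca * sg
    r10 = sa * cg * cb + ca * sb
    r11 = -sa * cg * sb + ca * cb
    r12 = sa * sg
    r20 = -sg * cb
    r21 = sg * sb
    r22 = cg

    # mid-step rotation M = Rz(a) Ry(G/2) Rz(phi)
    m00 = ca * ch * cphi - sa * sphi
    m01 = -ca * ch * sphi - sa * cphi
    m02 = ca * sh
    m10 = sa * ch * cphi + ca * sphi
    m11 = -sa * ch * sphi + ca * cphi
    m12 = sa * sh
    m20 = -sh * cphi
    m21 = sh * sphi
    m22 = ch

    # displacement in the mid-step frame, then into the lab frame
    dx = m00 * shift + m01 * slide + m02 * rise
    dy = m10 * shift + m11 * slide + m12 * rise
    dz = m20 * shift + m21 * slide + m22 * rise
    o[0] += T[0, 0] * dx + T[0, 1] * dy + T[0, 2] * dz
    o[1] += T[1, 0] * dx + T[1, 1] * dy + T[1, 2] * dz
    o[2] += T[2, 0] * dx + T[2, 1] * dy + T[2, 2] * dz

    # T <- T . R
    for i in range(3):
        t0 = T[i, 0]
        t1 = T[i, 1]
        t2 = T[i, 2]
        T[i, 0] = t0 * r00 + t1 * r10 + t2 * r20
        T[i, 1] = t0 * r01 + t1 * r11 + t2 * r21
        T[i, 2] = t0 * r02 + t1 * r12 + t2 * r22


@njit(cache=True, inline="always")
def _reorthogonalize(T):
    """Modified Gram-Schmidt on the triad columns (x, y), z = x cross y."""
    nx = np.sqrt(T[0, 0] ** 2 + T[1, 0] ** 2 + T[2, 0] ** 2)
    for i in range(3):
        T[i, 0] /= nx
    d = T[0, 0] * T[0, 1] + T[1, 0] * T[1, 1] + T[2, 0] * T[2, 1]
    for i in range(3):
        T[i, 1] -= d * T[i, 0]
    ny = np.sqrt(T[0, 1] ** 2 + T[1, 1] ** 2 + T[2, 1] ** 2)
    for i in range(3):
        T[i, 1] /= ny
    T[0, 2] = T[1, 0] * T[2, 1] - T[2, 0] * T[1, 1]
    T[1, 2] = T[2, 0] * T[0, 1] - T[0, 0] * T[2, 1]
    T[2, 2] = T[0, 0] * T[1, 1] - T[1, 0] * T[0, 1]


@njit(cache=True)
def simulate_closure(
    rng,
    n_chains,
    theta0,
    p_open,
    sd_ds,
    sd_ss,
    reorth_every,
    out_r,
    out_cosg,
    out_cosp,
):
    """Generate chains and record closure observables.

    Per chain the random stream is consumed in a fixed order: first one
    uniform per step for the hinge (single-stranded state) draw, then three
    standard normals per step for tilt/roll/twist.  ``theta0`` is the (S, 6)
    equilibrium step matrix with angles already in radians; ``p_open[s]`` is
    the opening probability of the base pair the step enters; ``sd_ds`` /
    ``sd_ss`` are the duplex / single-strand angular RMS values in radians.
    """
    S = theta0.shape[0]
    for c in range(n_chains):
        hinge_u = rng.random(S)
        z = rng.standard_normal(3 * S)
        T = np.eye(3)
        o = np.zeros(3)
        for s in range(S):
            if hinge_u[s] <= p_open[s]:
                sd = sd_ss
            else:
                sd = sd_ds
            tilt = theta0[s, 0] + sd[0] * z[3 * s]
            roll = theta0[s, 1] + sd[1] * z[3 * s + 1]
            twist = theta0[s, 2] + sd[2] * z[3 * s + 2]
            _step_update(T, o, tilt, roll, twist, theta0[s, 3], theta0[s, 4], theta0[s, 5])
            if (s + 1) % reorth_every == 0:
                _reorthogonalize(T)
        out_r[c] = np.sqrt(o[0] ** 2 + o[1] ** 2 + o[2] ** 2)
        out_cosg[c] = T[2, 2]
        # torsional register: last frame's x axis projected on the first
        # base-pair plane, compared with the first frame's x axis
        px = T[0, 0]
        py = T[1, 0]
        pn = np.sqrt(px * px + py * py)
        if pn > 1e-12:
            out_cosp[c] = px / pn
        else:
            out_cosp[c] = -1.0


@njit(cache=True)
def simulate_normals(rng, n_chains, theta0, sd, reorth_every, out_normals):
    """Generate uniform-state chains, recording the base-pair normal at every
    frame.  ``out_normals`` has shape (n_chains, S + 1, 3).  The random stream
    matches :func:`simulate_closure` with all hinge draws skipped."""
    S = theta0.shape[0]
    for c in range(n_chains):
        z = rng.standard_normal(3 * S)
        T = np.eye(3)
        o = np.zeros(3)
        out_normals[c, 0, 0] = 0.0
        out_normals[c, 0, 1] = 0.0
        out_normals[c, 0, 2] = 1.0
        for s in range(S):
            tilt = theta0[s, 0] + sd[0] * z[3 * s]
            roll = theta0[s, 1] + sd[1] * z[3 * s + 1]
            twist = theta0[s, 2] + sd[2] * z[3 * s + 2]
            _step_update(T, o, tilt, roll, twist, theta0[s, 3], theta0[s, 4], theta0[s, 5])
            if (s + 1) % reorth_every == 0:
                _reorthogonalize(T)
            out_normals[c, s + 1, 0] = T[0, 2]
            out_normals[c, s + 1, 1] = T[1, 2]
            out_normals[c, s + 1, 2] = T[2, 2]
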