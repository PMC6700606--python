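"""Numba-compiled force kernels and the Langevin integration inner loop.

Everything here operates on plain arrays; the object layer in :mod:`efm`,
:mod:`gomodel` and :mod:`dynamics` packs model parameters into tuples that
these kernels unpack.  Energies and forces are exact negative gradients of
each other by construction; the test suite checks this against central
finite differences.

Status codes returned by the integrator chunk: 0 = ok, 1 = non-finite
coordinates, 2 = overstretched FENE bond.
"""

import numpy as np
from numba import njit

TWO_1_6 = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# shared bonded / angular building blocks
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fene_bonds(pos, k_fene, R0, forces):
    """FENE bond energy/forces; returns (energy, ok)."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        x = r2 / (R0 * R0)
        if x >= 1.0:
            return 0.0, False
        e += -0.5 * k_fene * R0 * R0 * np.log(1.0 - x)
        # dU/dr = k r / (1 - (r/R0)^2); force on i+1 along -d
        fac = -k_fene / (1.0 - x)
        forces[i + 1, 0] += fac * dx
        forces[i + 1, 1] += fac * dy
        forces[i + 1, 2] += fac * dz
        forces[i, 0] -= fac * dx
        forces[i, 1] -= fac * dy
        forces[i, 2] -= fac * dz
    return e, True


@njit(cache=True)
def _wca_pair(r2, eps, sig):
    """WCA energy and dU/dr / r for one pair (0 beyond cutoff)."""
    rc2 = TWO_1_6 * TWO_1_6 * sig * sig
    if r2 >= rc2:
        return 0.0, 0.0
    s2 = sig * sig / r2
    s6 = s2 * s2 * s2
    s12 = s6 * s6
    e = 4.0 * eps * (s12 - s6) + eps
    # dU/dr = -24 eps (2 s12 - s6)/r  -> per-distance factor dU/dr / r
    dudr_over_r = -24.0 * eps * (2.0 * s12 - s6) / r2
    return e, dudr_over_r


@njit(cache=True)
def _angular(pos, theta0, kbend, phi0, k1, k3, out, ang_cap):
    """Bending k(theta-theta0)^2 plus torsion k1[1-cos d] + k3[1-cos 3d].

    Angular forces accumulate into a scratch buffer and the per-bead
    magnitude is capped at ``ang_cap`` before being added to ``out``: the
    1/sin(theta) geometry factors diverge at collinear transients and the
    cap (together with the sin floors) bounds those spikes without touching
    the bonded/steric restoring walls.
    """
    n = pos.shape[0]
    e = 0.0
    forces = np.zeros((n, 3))
    # bending
    for i in range(n - 2):
        ux = pos[i, 0] - pos[i + 1, 0]
        uy = pos[i, 1] - pos[i + 1, 1]
        uz = pos[i, 2] - pos[i + 1, 2]
        vx = pos[i + 2, 0] - pos[i + 1, 0]
        vy = pos[i + 2, 1] - pos[i + 1, 1]
        vz = pos[i + 2, 2] - pos[i + 1, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        d = theta - theta0[i]
        e += kbend[i] * d * d
        dude = 2.0 * kbend[i] * d
        s = np.sqrt(1.0 - c * c)
        # floor the 1/sin(theta) factor: regularizes the collinear
        # singularity met in stretched starting states (theta ~ pi) without
        # affecting forces beyond ~3 degrees of collinearity
        if s < 0.05:
            s = 0.05
        # grad_theta at outer beads
        gax = -((vx / nv) - c * (ux / nu)) / (nu * s)
        gay = -((vy / nv) - c * (uy / nu)) / (nu * s)
        gaz = -((vz / nv) - c * (uz / nu)) / (nu * s)
        gcx = -((ux / nu) - c * (vx / nv)) / (nv * s)
        gcy = -((uy / nu) - c * (vy / nv)) / (nv * s)
        gcz = -((uz / nu) - c * (vz / nv)) / (nv * s)
        forces[i, 0] -= dude * gax
        forces[i, 1] -= dude * gay
        forces[i, 2] -= dude * gaz
        forces[i + 2, 0] -= dude * gcx
        forces[i + 2, 1] -= dude * gcy
        forces[i + 2, 2] -= dude * gcz
        forces[i + 1, 0] += dude * (gax + gcx)
        forces[i + 1, 1] += dude * (gay + gcy)
        forces[i + 1, 2] += dude * (gaz + gcz)
    # torsion
    for i in range(n - 3):
        b1x = pos[i + 1, 0] - pos[i, 0]
        b1y = pos[i + 1, 1] - pos[i, 1]
        b1z = pos[i + 1, 2] - pos[i, 2]
        b2x = pos[i + 2, 0] - pos[i + 1, 0]
        b2y = pos[i + 2, 1] - pos[i + 1, 1]
        b2z = pos[i + 2, 2] - pos[i + 1, 2]
        b3x = pos[i + 3, 0] - pos[i + 2, 0]
        b3y = pos[i + 3, 1] - pos[i + 2, 1]
        b3z = pos[i + 3, 2] - pos[i + 2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        xv = n1x * n2x + n1y * n2y + n1z * n2z
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        yv = (cxx * b2x + cxy * b2y + cxz * b2z) / nb2
        phi = np.arctan2(yv, xv)
        d = phi - phi0[i]
        e += k1[i] * (1.0 - np.cos(d)) + k3[i] * (1.0 - np.cos(3.0 * d))
        dudphi = k1[i] * np.sin(d) + 3.0 * k3[i] * np.sin(3.0 * d)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        # floor |b x b|^2 at (0.05 |b||b|)^2: same collinearity
        # regularization as for bending (near-unit bonds assumed)
        b1sq = b1x * b1x + b1y * b1y + b1z * b1z
        b3sq = b3x * b3x + b3y * b3y + b3z * b3z
        floor1 = 2.5e-3 * b1sq * nb2 * nb2
        floor3 = 2.5e-3 * b3sq * nb2 * nb2
        if n1sq < floor1:
            n1sq = floor1
        if n2sq < floor3:
            n2sq = floor3
        # grad phi: ends -|b2|/|n1|^2 n1 and +|b2|/|n2|^2 n2 for the atan2
        # convention above; middle beads follow from the b2-partial
        # dphi/db2 = (b1.b2) n1/(|b2||n1|^2) - (b3.b2) n2/(|b2||n2|^2)
        g0x = -nb2 / n1sq * n1x
        g0y = -nb2 / n1sq * n1y
        g0z = -nb2 / n1sq * n1z
        g3x = nb2 / n2sq * n2x
        g3y = nb2 / n2sq * n2y
        g3z = nb2 / n2sq * n2z
        t = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
        s = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
        g1x = -(1.0 + t) * g0x + s * g3x
        g1y = -(1.0 + t) * g0y + s * g3y
        g1z = -(1.0 + t) * g0z + s * g3z
        g2x = t * g0x - (1.0 + s) * g3x
        g2y = t * g0y - (1.0 + s) * g3y
        g2z = t * g0z - (1.0 + s) * g3z
        forces[i, 0] -= dudphi * g0x
        forces[i, 1] -= dudphi * g0y
        forces[i, 2] -= dudphi * g0z
        forces[i + 1, 0] -= dudphi * g1x
        forces[i + 1, 1] -= dudphi * g1y
        forces[i + 1, 2] -= dudphi * g1z
        forces[i + 2, 0] -= dudphi * g2x
        forces[i + 2, 1] -= dudphi * g2y
        forces[i + 2, 2] -= dudphi * g2z
        forces[i + 3, 0] -= dudphi * g3x
        forces[i + 3, 1] -= dudphi * g3y
        forces[i + 3, 2] -= dudphi * g3z
    for i in range(n):
        fsq = forces[i, 0] ** 2 + forces[i, 1] ** 2 + forces[i, 2] ** 2
        if fsq > ang_cap * ang_cap:
            scale = ang_cap / np.sqrt(fsq)
            forces[i, 0] *= scale
            forces[i, 1] *= scale
            forces[i, 2] *= scale
        out[i, 0] += forces[i, 0]
        out[i, 1] += forces[i, 1]
        out[i, 2] += forces[i, 2]
    return e


# ---------------------------------------------------------------------------
# EFM total energy/forces
# ---------------------------------------------------------------------------

@njit(cache=True)
def efm_energy_forces(pos, args):
    """Total EFM energy and forces.

    args = (theta0, phi0, kbend, k1tor, k3tor, k_fene, R0, eps, sigma,
            min_sep, bp_i, bp_j, b_eps, b_sig, b_rc, bridges_on, ang_cap)

    ``min_sep`` is the smallest |i-j| included in the WCA sum (1 = include
    bonded pairs).  Returns (energy, forces, status).
    """
    (theta0, phi0, kbend, k1tor, k3tor, k_fene, R0, eps, sigma,
     min_sep, bp_i, bp_j, b_eps, b_sig, b_rc, bridges_on, ang_cap) = args
    n = pos.shape[0]
    forces = np.zeros((n, 3))

    e_bond, ok = _fene_bonds(pos, k_fene, R0, forces)
    if not ok:
        return 0.0, forces, 2

    e = e_bond
    rc2 = TWO_1_6 * TWO_1_6 * sigma * sigma
    for i in range(n):
        for j in range(i + min_sep, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            ew, fr = _wca_pair(r2, eps, sigma)
            e += ew
            forces[i, 0] -= fr * dx
            forces[i, 1] -= fr * dy
            forces[i, 2] -= fr * dz
            forces[j, 0] += fr * dx
            forces[j, 1] += fr * dy
            forces[j, 2] += fr * dz

    e += _angular(pos, theta0, kbend, phi0, k1tor, k3tor, forces, ang_cap)

    if bridges_on == 1:
        for b in range(bp_i.shape[0]):
            i = bp_i[b]
            j = bp_j[b]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            rc = b_rc[b]
            if r >= rc:
                continue
            sig = b_sig[b]
            epb = b_eps[b]
            s6 = (sig / r) ** 6
            s12 = s6 * s6
            u = 4.0 * epb * (s12 - s6)
            du = -24.0 * epb * (2.0 * s12 - s6) / r
            s6c = (sig / rc) ** 6
            s12c = s6c * s6c
            uc = 4.0 * epb * (s12c - s6c)
            duc = -24.0 * epb * (2.0 * s12c - s6c) / rc
            e += u - uc - (r - rc) * duc
            fr = (du - duc) / r
            forces[i, 0] -= fr * dx
            forces[i, 1] -= fr * dy
            forces[i, 2] -= fr * dz
            forces[j, 0] += fr * dx
            forces[j, 1] += fr * dy
            forces[j, 2] += fr * dz

    return e, forces, 0


# ---------------------------------------------------------------------------
# Go-model total energy/forces
# ---------------------------------------------------------------------------

@njit(cache=True)
def go_energy_forces(pos, args):
    """Total Go-model energy and forces.

    args = (theta0, phi0, kbend, k1tor, k3tor, k_fene, R0, eps, sigma,
            ci, cj, cr0, cE, eps_ev, sigma_ev, is_contact, ang_cap)

    Bonds are FENE; local sterics (|i-j| <= 2) are WCA at the chain diameter;
    native contacts (|i-j| >= 3) get the 12-10 potential minimal at the
    native distance; remaining |i-j| >= 3 pairs get a 12-power excluded
    volume of diameter sigma_ev.  ``is_contact`` is a flattened boolean
    lookup of size n*n.
    """
    (theta0, phi0, kbend, k1tor, k3tor, k_fene, R0, eps, sigma,
     ci, cj, cr0, cE, eps_ev, sigma_ev, is_contact, ang_cap) = args
    n = pos.shape[0]
    forces = np.zeros((n, 3))

    e_bond, ok = _fene_bonds(pos, k_fene, R0, forces)
    if not ok:
        return 0.0, forces, 2
    e = e_bond

    # local sterics for |i-j| in {1, 2}
    for i in range(n):
        for j in range(i + 1, min(i + 3, n)):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            ew, fr = _wca_pair(r2, eps, sigma)
            if ew != 0.0:
                e += ew
                forces[i, 0] -= fr * dx
                forces[i, 1] -= fr * dy
                forces[i, 2] -= fr * dz
                forces[j, 0] += fr * dx
                forces[j, 1] += fr * dy
                forces[j, 2] += fr * dz

    # non-contact excluded volume, |i-j| >= 3
    ev_rc2 = 9.0 * sigma_ev * sigma_ev  # (sigma_ev/r)^12 < 2e-6 beyond 3 sigma_ev
    for i in range(n):
        for j in range(i + 3, n):
            if is_contact[i * n + j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= ev_rc2:
                continue
            s2 = sigma_ev * sigma_ev / r2
            s12 = s2 * s2 * s2
            s12 = s12 * s12
            e += eps_ev * s12
            fr = -12.0 * eps_ev * s12 / r2
            forces[i, 0] -= fr * dx
            forces[i, 1] -= fr * dy
            forces[i, 2] -= fr * dz
            forces[j, 0] += fr * dx
            forces[j, 1] += fr * dy
            forces[j, 2] += fr * dz

    # 12-10 native contacts
    for k in range(ci.shape[0]):
        i = ci[k]
        j = cj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        q = cr0[k] / r
        q10 = q ** 10
        q12 = q10 * q * q
        e += cE[k] * (5.0 * q12 - 6.0 * q10)
        # dU/dr = -60 E (q12 - q10)/r
        fr = -60.0 * cE[k] * (q12 - q10) / (r * r)
        forces[i, 0] -= fr * dx
        forces[i, 1] -= fr * dy
        forces[i, 2] -= fr * dz
        forces[j, 0] += fr * dx
        forces[j, 1] += fr * dy
        forces[j, 2] += fr * dz

    e += _angular(pos, theta0, kbend, phi0, k1tor, k3tor, forces, ang_cap)
    return e, forces, 0


# ---------------------------------------------------------------------------
# BAOAB Langevin chunks
# ---------------------------------------------------------------------------

def make_baoab_chunk(force_func):
    """Compile a BAOAB chunk integrator bound to a jitted force function.

    The returned function advances ``normals.shape[0]`` steps in place and
    returns (energy_of_last_force_eval, status, step_of_failure).
    """

    @njit(cache=True)
    def chunk(pos, vel, forces, args, dt, gamma, kT, mass, normals):
        nsteps = normals.shape[0]
        n = pos.shape[0]
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt((1.0 - c1 * c1) * kT / mass)
        half = 0.5 * dt
        energy = 0.0
        for s in range(nsteps):
            for i in range(n):
                for d in range(3):
                    vel[i, d] += half * forces[i, d] / mass
                    pos[i, d] += half * vel[i, d]
                    vel[i, d] = c1 * vel[i, d] + c2 * normals[s, i, d]
                    pos[i, d] += half * vel[i, d]
            energy, f, status = force_func(pos, args)
            if status != 0:
                return energy, status, s
            for i in range(n):
                for d in range(3):
                    forces[i, d] = f[i, d]
                    vel[i, d] += half * f[i, d] / mass
            if not np.isfinite(pos[0, 0]):
                return energy, 1, s
        return energy, 0, nsteps

    return chunk


_CHUNK_CACHE = {}


def baoab_chunk_for(force_func):
    if force_func not in _CHUNK_CACHE:
        _CHUNK_CACHE[force_func] = make_baoab_chunk(force_func)
    return _CHUNK_CACHE[force_func]
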