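"""Numba kernels for the DPD engine.

Design notes
------------
* The thermostat noise is *counter-based*: each interacting pair (i, j) at
  integration step s draws its symmetric unit random variable zeta_ij from a
  splitmix64 hash of (seed, s, min(i,j), max(i,j)).  This guarantees
  zeta_ij == zeta_ji exactly, makes runs bit-reproducible for a fixed seed,
  and lets a brute-force all-pairs evaluation reproduce the cell-list
  evaluation pair-for-pair regardless of iteration order.
* zeta is uniform on [-sqrt(3), sqrt(3)] (zero mean, unit variance).
* The production path (``cell_forces``) bins beads into cells at least d0
  wide, gathers coordinates into cell order for cache locality, and sweeps
  each cell against itself and half its 26 neighbours; the periodic image
  of a neighbouring cell is applied as a per-cell coordinate shift, which
  realises the minimum image exactly without per-pair branches.
* ``eval_forces`` evaluates an explicit pair list with the same per-pair
  arithmetic; fed with an all-pairs list it is the independent brute-force
  reference for the cell sweep.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SQRT3 = np.sqrt(3.0)

_U64_1 = np.uint64(0x9E3779B97F4A7C15)
_U64_2 = np.uint64(0xBF58476D1CE4E5B9)
_U64_3 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S11 = np.uint64(11)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(inline="always", cache=True)
def _splitmix(z):
    z = z + _U64_1
    z = (z ^ (z >> _S30)) * _U64_2
    z = (z ^ (z >> _S27)) * _U64_3
    return z ^ (z >> _S31)


@njit(inline="always", cache=True)
def pair_noise(seed, step, i, j):
    """Symmetric unit-variance uniform variate for pair (i, j) at a step."""
    if i < j:
        lo, hi = i, j
    else:
        lo, hi = j, i
    z = _splitmix(np.uint64(seed) + np.uint64(step))
    z = _splitmix(z + np.uint64(lo))
    z = _splitmix(z + np.uint64(hi))
    u = np.float64(z >> _S11) * _INV_2_53
    return SQRT3 * (2.0 * u - 1.0)


@njit(inline="always", cache=True)
def _min_image(d, L):
    if d > 0.5 * L:
        d -= L
    elif d < -0.5 * L:
        d += L
    return d


@njit(inline="always", cache=True)
def _nb_pair(a_ij, gamma, sigma, dx, dy, dz, r2, dvx, dvy, dvz, zeta):
    """DPD non-bonded force on bead i from j; returns (fx, fy, fz, f*r)."""
    r = np.sqrt(r2)
    inv = 1.0 / r
    ex = dx * inv
    ey = dy * inv
    ez = dz * inv
    w = 1.0 - r
    rv = ex * dvx + ey * dvy + ez * dvz
    f = a_ij * w - gamma * w * w * rv + sigma * w * zeta
    return f * ex, f * ey, f * ez, f * r


@njit(cache=True, fastmath=True)
def cell_forces(pos, vel, types, amat, gamma, sigma, box, seed, step, frc, counters):
    """Non-bonded forces via the cell sweep; overwrites ``frc``.

    Requires at least 3 cells (of width >= d0) per dimension.  Returns the
    non-bonded virial sum r_ij . F_ij; counters[0] counts degenerate
    zero-separation pairs, which contribute no force.
    """
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    ncx = int(lx)
    ncy = int(ly)
    ncz = int(lz)
    ncell = ncx * ncy * ncz

    cell_of = np.empty(n, np.int64)
    start = np.zeros(ncell + 1, np.int64)
    for i in range(n):
        cx = int(pos[i, 0] * ncx / lx)
        cy = int(pos[i, 1] * ncy / ly)
        cz = int(pos[i, 2] * ncz / lz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cz * ncy + cy) * ncx + cx
        cell_of[i] = c
        start[c + 1] += 1
    for c in range(ncell):
        start[c + 1] += start[c]
    order = np.empty(n, np.int64)
    fill = start[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    # gather into cell order for contiguous access
    sx = np.empty(n)
    sy = np.empty(n)
    sz = np.empty(n)
    svx = np.empty(n)
    svy = np.empty(n)
    svz = np.empty(n)
    stt = np.empty(n, np.int64)
    fx = np.zeros(n)
    fy = np.zeros(n)
    fz = np.zeros(n)
    for p in range(n):
        i = order[p]
        sx[p] = pos[i, 0]
        sy[p] = pos[i, 1]
        sz[p] = pos[i, 2]
        svx[p] = vel[i, 0]
        svy[p] = vel[i, 1]
        svz[p] = vel[i, 2]
        stt[p] = types[i]

    virial = 0.0
    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = (cz * ncy + cy) * ncx + cx
                s0 = start[c]
                e0 = start[c + 1]
                # pairs within the cell (no image shift needed)
                for p in range(s0, e0):
                    xi = sx[p]
                    yi = sy[p]
                    zi = sz[p]
                    for q in range(p + 1, e0):
                        dx = xi - sx[q]
                        dy = yi - sy[q]
                        dz = zi - sz[q]
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < 1.0:
                            if r2 < 1e-24:
                                counters[0] += 1
                                continue
                            zeta = pair_noise(seed, step, order[p], order[q])
                            gx, gy, gz, fr = _nb_pair(
                                amat[stt[p], stt[q]], gamma, sigma,
                                dx, dy, dz, r2,
                                svx[p] - svx[q], svy[p] - svy[q], svz[p] - svz[q],
                                zeta,
                            )
                            fx[p] += gx
                            fy[p] += gy
                            fz[p] += gz
                            fx[q] -= gx
                            fy[q] -= gy
                            fz[q] -= gz
                            virial += fr
                # half of the neighbouring cells
                for k in range(13):
                    if k < 9:
                        ox = k % 3 - 1
                        oy = k // 3 - 1
                        oz = 1
                    elif k < 12:
                        ox = k - 10
                        oy = 1
                        oz = 0
                    else:
                        ox = 1
                        oy = 0
                        oz = 0
                    shx = 0.0
                    shy = 0.0
                    shz = 0.0
                    nx = cx + ox
                    if nx < 0:
                        nx += ncx
                        shx = -lx
                    elif nx >= ncx:
                        nx -= ncx
                        shx = lx
                    ny = cy + oy
                    if ny < 0:
                        ny += ncy
                        shy = -ly
                    elif ny >= ncy:
                        ny -= ncy
                        shy = ly
                    nz = cz + oz
                    if nz >= ncz:
                        nz -= ncz
                        shz = lz
                    c2 = (nz * ncy + ny) * ncx + nx
                    s1 = start[c2]
                    e1 = start[c2 + 1]
                    for p in range(s0, e0):
                        # shift bead p into the neighbour cell's frame
                        xi = sx[p] - shx
                        yi = sy[p] - shy
                        zi = sz[p] - shz
                        for q in range(s1, e1):
                            dx = xi - sx[q]
                            dy = yi - sy[q]
                            dz = zi - sz[q]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < 1.0:
                                if r2 < 1e-24:
                                    counters[0] += 1
                                    continue
                                zeta = pair_noise(seed, step, order[p], order[q])
                                gx, gy, gz, fr = _nb_pair(
                                    amat[stt[p], stt[q]], gamma, sigma,
                                    dx, dy, dz, r2,
                                    svx[p] - svx[q], svy[p] - svy[q], svz[p] - svz[q],
                                    zeta,
                                )
                                fx[p] += gx
                                fy[p] += gy
                                fz[p] += gz
                                fx[q] -= gx
                                fy[q] -= gy
                                fz[q] -= gz
                                virial += fr
    # scatter back to bead order
    for p in range(n):
        i = order[p]
        frc[i, 0] = fx[p]
        frc[i, 1] = fy[p]
        frc[i, 2] = fz[p]
    return virial


@njit(cache=True)
def build_pair_list_brute(pos, box, rlist, pairs_i, pairs_j):
    """All-pairs candidate list (minimum image); reference for small boxes."""
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    r2max = rlist * rlist
    cap = pairs_i.shape[0]
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], lx)
            dy = _min_image(pos[i, 1] - pos[j, 1], ly)
            dz = _min_image(pos[i, 2] - pos[j, 2], lz)
            if dx * dx + dy * dy + dz * dz < r2max:
                if count >= cap:
                    return -1
                pairs_i[count] = i
                pairs_j[count] = j
                count += 1
    return count


@njit(cache=True, fastmath=True)
def pair_list_forces(pos, vel, types, amat, gamma, sigma, box, seed, step,
                     pairs_i, pairs_j, n_pairs, frc, counters):
    """Non-bonded forces for an explicit pair list; overwrites ``frc``.

    Shares its per-pair arithmetic with :func:`cell_forces`; with an
    all-pairs list this is the brute-force oracle.  Returns the virial.
    """
    lx, ly, lz = box[0], box[1], box[2]
    frc[:, :] = 0.0
    virial = 0.0
    for p in range(n_pairs):
        i = pairs_i[p]
        j = pairs_j[p]
        dx = _min_image(pos[i, 0] - pos[j, 0], lx)
        dy = _min_image(pos[i, 1] - pos[j, 1], ly)
        dz = _min_image(pos[i, 2] - pos[j, 2], lz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= 1.0:
            continue
        if r2 < 1e-24:
            counters[0] += 1
            continue
        zeta = pair_noise(seed, step, i, j)
        gx, gy, gz, fr = _nb_pair(
            amat[types[i], types[j]], gamma, sigma, dx, dy, dz, r2,
            vel[i, 0] - vel[j, 0], vel[i, 1] - vel[j, 1], vel[i, 2] - vel[j, 2],
            zeta,
        )
        frc[i, 0] += gx
        frc[i, 1] += gy
        frc[i, 2] += gz
        frc[j, 0] -= gx
        frc[j, 1] -= gy
        frc[j, 2] -= gz
        virial += fr
    return virial


@njit(cache=True, fastmath=True)
def bonded_forces(pos, frc, bonds, angles, box, k2, l0, k3, phi0, counters):
    """Add Hookean-bond and chain-bending forces into ``frc``.

    Returns the bond virial contribution (angle terms are omitted from the
    virial: the pressure diagnostic is only used for homogeneous solvent).
    counters[1] / counters[2] count degenerate bonds / angle arms.
    """
    lx, ly, lz = box[0], box[1], box[2]
    virial = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], lx)
        dy = _min_image(pos[i, 1] - pos[j, 1], ly)
        dz = _min_image(pos[i, 2] - pos[j, 2], lz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-24:
            counters[1] += 1
            continue
        r = np.sqrt(r2)
        f = -k2 * (r - l0)  # along unit vector j->i: restores l0
        inv = 1.0 / r
        fx = f * dx * inv
        fy = f * dy * inv
        fz = f * dz * inv
        frc[i, 0] += fx
        frc[i, 1] += fy
        frc[i, 2] += fz
        frc[j, 0] -= fx
        frc[j, 1] -= fy
        frc[j, 2] -= fz
        virial += f * r

    for t in range(angles.shape[0]):
        ia = angles[t, 0]
        ib = angles[t, 1]
        ic = angles[t, 2]
        # bond vectors b1 = r_b - r_a, b2 = r_c - r_b (minimum image)
        b1x = _min_image(pos[ib, 0] - pos[ia, 0], lx)
        b1y = _min_image(pos[ib, 1] - pos[ia, 1], ly)
        b1z = _min_image(pos[ib, 2] - pos[ia, 2], lz)
        b2x = _min_image(pos[ic, 0] - pos[ib, 0], lx)
        b2y = _min_image(pos[ic, 1] - pos[ib, 1], ly)
        b2z = _min_image(pos[ic, 2] - pos[ib, 2], lz)
        d1s = b1x * b1x + b1y * b1y + b1z * b1z
        d2s = b2x * b2x + b2y * b2y + b2z * b2z
        if d1s < 1e-24 or d2s < 1e-24:
            counters[2] += 1
            continue
        d1 = np.sqrt(d1s)
        d2 = np.sqrt(d2s)
        dot = b1x * b2x + b1y * b2y + b1z * b2z
        c = dot / (d1 * d2)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        # dU/dcos(phi); exactly -k3 for the straight-chain preference phi0=0
        if phi0 == 0.0:
            dudc = -k3
        else:
            s2 = 1.0 - c * c
            if s2 < 1e-16:
                s2 = 1e-16
            dudc = -k3 * np.sin(np.arccos(c) - phi0) / np.sqrt(s2)
        inv12 = 1.0 / (d1 * d2)
        # dc/db1 and dc/db2
        g1x = b2x * inv12 - c * b1x / d1s
        g1y = b2y * inv12 - c * b1y / d1s
        g1z = b2z * inv12 - c * b1z / d1s
        g2x = b1x * inv12 - c * b2x / d2s
        g2y = b1y * inv12 - c * b2y / d2s
        g2z = b1z * inv12 - c * b2z / d2s
        # F_a = dU/dc * dc/db1 ; F_c = -dU/dc * dc/db2 ; F_b balances
        fax = dudc * g1x
        fay = dudc * g1y
        faz = dudc * g1z
        fcx = -dudc * g2x
        fcy = -dudc * g2y
        fcz = -dudc * g2z
        frc[ia, 0] += fax
        frc[ia, 1] += fay
        frc[ia, 2] += faz
        frc[ic, 0] += fcx
        frc[ic, 1] += fcy
        frc[ic, 2] += fcz
        frc[ib, 0] -= fax + fcx
        frc[ib, 1] -= fay + fcy
        frc[ib, 2] -= faz + fcz
    return virial


@njit(cache=True, fastmath=True)
def md_chunk(
    pos,
    vel,
    frc,
    fnew,
    vtilde,
    types,
    bonds,
    angles,
    amat,
    gamma,
    kBT,
    box,
    dt,
    seed,
    step0,
    nsteps,
    k2,
    l0,
    k3,
    phi0,
    use_cells,
    pairs_i,
    pairs_j,
    temps,
    virials,
    counters,
):
    """Advance ``nsteps`` steps of the modified velocity-Verlet integrator.

    Positions/velocities/forces are updated in place.  Returns 0 on
    success, -1 on pair-list overflow (brute path only), -3 on non-finite
    coordinates.  ``frc`` must hold the forces for the entering state; it
    holds the forces for the final state on exit.  ``use_cells`` selects
    the cell sweep; boxes under 3 d0 per edge use the all-pairs path with
    the supplied scratch pair arrays.
    """
    n = pos.shape[0]
    lx, ly, lz = box[0], box[1], box[2]
    sigma = np.sqrt(2.0 * gamma * kBT / dt)
    half = 0.5 * dt
    lam = 0.5 * dt  # Groot-Warren lambda = 0.5
    dof = 3.0 * n - 3.0
    if dof <= 0:
        dof = 1.0

    for s in range(nsteps):
        step = step0 + s
        for i in range(n):
            x = pos[i, 0] + dt * vel[i, 0] + half * dt * frc[i, 0]
            y = pos[i, 1] + dt * vel[i, 1] + half * dt * frc[i, 1]
            z = pos[i, 2] + dt * vel[i, 2] + half * dt * frc[i, 2]
            x -= lx * np.floor(x / lx)
            y -= ly * np.floor(y / ly)
            z -= lz * np.floor(z / lz)
            if x >= lx:
                x = 0.0
            if y >= ly:
                y = 0.0
            if z >= lz:
                z = 0.0
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
            vtilde[i, 0] = vel[i, 0] + lam * frc[i, 0]
            vtilde[i, 1] = vel[i, 1] + lam * frc[i, 1]
            vtilde[i, 2] = vel[i, 2] + lam * frc[i, 2]

        if use_cells:
            v_nb = cell_forces(
                pos, vtilde, types, amat, gamma, sigma, box,
                seed, step + 1, fnew, counters,
            )
        else:
            cnt = build_pair_list_brute(pos, box, 1.0, pairs_i, pairs_j)
            if cnt < 0:
                return -1
            v_nb = pair_list_forces(
                pos, vtilde, types, amat, gamma, sigma, box,
                seed, step + 1, pairs_i, pairs_j, cnt, fnew, counters,
            )
        v_b = bonded_forces(pos, fnew, bonds, angles, box, k2, l0, k3, phi0, counters)
        virials[s] = v_nb + v_b

        sumv2 = 0.0
        for i in range(n):
            vx = vel[i, 0] + half * (frc[i, 0] + fnew[i, 0])
            vy = vel[i, 1] + half * (frc[i, 1] + fnew[i, 1])
            vz = vel[i, 2] + half * (frc[i, 2] + fnew[i, 2])
            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz
            frc[i, 0] = fnew[i, 0]
            frc[i, 1] = fnew[i, 1]
            frc[i, 2] = fnew[i, 2]
            sumv2 += vx * vx + vy * vy + vz * vz
        temps[s] = sumv2 / dof
        if not np.isfinite(sumv2):
            return -3
    return 0
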