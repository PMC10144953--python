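"""Numba force kernels.

Design notes
------------
* The pair noise zeta_ij is produced by a counter-based hash (splitmix64)
  of (seed, step, i, j) with i < j canonical ordering, instead of a
  sequential RNG stream.  The noise a pair receives is therefore
  independent of the order in which pairs are visited, so the cell-list
  and all-pairs neighbour searches produce identical forces, one zeta is
  shared antisymmetrically by construction (momentum conservation), and
  runs are reproducible per seed.
* Neighbour search (cell list or all-pairs) and pair physics are split:
  the search emits a compact in-range pair list, one physics loop
  consumes it.  The physics is written once and the two search paths can
  be compared directly.
* Every kernel can optionally accumulate a per-slab diagonal virial for
  the Irving-Kirkwood tension profile: a pair contribution F_a * d_a is
  spread over the z-slabs crossed by the i-j segment in proportion to the
  segment length inside each slab (``slab_mode`` 1), or assigned to the
  slab of the segment midpoint (``slab_mode`` 2); 0 disables it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
NOISE_GAUSSIAN = 0
NOISE_UNIFORM = 1
SLAB_OFF = 0
SLAB_IK = 1
SLAB_MIDPOINT = 2


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & _MASK
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def pair_noise(seed, step, i, j, kind):
    """Unit-variance noise for bead pair (i, j) at one time step."""
    if i > j:
        i, j = j, i
    h = _splitmix64(np.uint64(seed) ^ ((np.uint64(step) << np.uint64(1)) + np.uint64(1)))
    h = _splitmix64(h ^ ((np.uint64(i) << np.uint64(32)) | np.uint64(j)))
    u1 = ((h >> np.uint64(11)) + np.uint64(1)) * 1.1102230246251565e-16  # (0, 1]
    h2 = _splitmix64(h)
    u2 = (h2 >> np.uint64(11)) * 1.1102230246251565e-16  # [0, 1)
    if kind == NOISE_UNIFORM:
        return 3.4641016151377544 * (u1 - 0.5)  # sqrt(12) * (U - 1/2)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2)


@njit(cache=True, inline="always")
def _min_image(d, L):
    # positions live in [0, L), so |d| < L: one branch suffices and is
    # cheaper than the division in d - L*rint(d/L)
    if d > 0.5 * L:
        return d - L
    if d < -0.5 * L:
        return d + L
    return d


# ---------------------------------------------------------------------------
# neighbour search: emit the in-range pair list
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def build_pairs_cells(pos, L, rc, pi, pj, pdx, pdy, pdz):
    """Cell-list search (>= 3 cells per side).  Fills the pair arrays with
    every distinct pair at r < rc and returns the pair count; when the
    count exceeds the array capacity it keeps counting without writing so
    the caller can re-allocate."""
    n = pos.shape[0]
    cap = pi.shape[0]
    nc = int(L / rc)
    cell_w = L / nc
    head = np.full(nc * nc * nc, -1, np.int64)
    nxt = np.empty(n, np.int64)
    for i in range(n):
        cx = min(int(pos[i, 0] / cell_w), nc - 1)
        cy = min(int(pos[i, 1] / cell_w), nc - 1)
        cz = min(int(pos[i, 2] / cell_w), nc - 1)
        c = (cx * nc + cy) * nc + cz
        nxt[i] = head[c]
        head[c] = i
    offs = np.array(
        [
            (1, 0, 0), (1, 1, 0), (0, 1, 0), (-1, 1, 0),
            (1, 0, 1), (1, 1, 1), (0, 1, 1), (-1, 1, 1),
            (1, 0, -1), (1, 1, -1), (0, 1, -1), (-1, 1, -1),
            (0, 0, 1),
        ],
        np.int64,
    )
    rc2 = rc * rc
    m = 0
    for cx in range(nc):
        for cy in range(nc):
            for cz in range(nc):
                c = (cx * nc + cy) * nc + cz
                for k in range(14):
                    if k == 13:
                        c2 = c
                    else:
                        ox = (cx + offs[k, 0]) % nc
                        oy = (cy + offs[k, 1]) % nc
                        oz = (cz + offs[k, 2]) % nc
                        c2 = (ox * nc + oy) * nc + oz
                    i = head[c]
                    while i >= 0:
                        j = nxt[i] if c2 == c else head[c2]
                        while j >= 0:
                            dx = _min_image(pos[i, 0] - pos[j, 0], L)
                            dy = _min_image(pos[i, 1] - pos[j, 1], L)
                            dz = _min_image(pos[i, 2] - pos[j, 2], L)
                            if dx * dx + dy * dy + dz * dz < rc2:
                                if m < cap:
                                    pi[m] = i
                                    pj[m] = j
                                    pdx[m] = dx
                                    pdy[m] = dy
                                    pdz[m] = dz
                                m += 1
                            j = nxt[j]
                        i = nxt[i]
    return m


@njit(cache=True, fastmath=True)
def build_pairs_naive(pos, L, rc, pi, pj, pdx, pdy, pdz):
    """All-pairs O(N^2) search; same contract as :func:`build_pairs_cells`."""
    n = pos.shape[0]
    cap = pi.shape[0]
    rc2 = rc * rc
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], L)
            dy = _min_image(pos[i, 1] - pos[j, 1], L)
            dz = _min_image(pos[i, 2] - pos[j, 2], L)
            if dx * dx + dy * dy + dz * dz < rc2:
                if m < cap:
                    pi[m] = i
                    pj[m] = j
                    pdx[m] = dx
                    pdy[m] = dy
                    pdz[m] = dz
                m += 1
    return m


# ---------------------------------------------------------------------------
# slab partition of a pair's diagonal virial
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def _slab_add(slab_virial, n_slabs, slab_w, L, z_from, dz, cx, cy, cz, mode):
    """Distribute one diagonal virial contribution (cx, cy, cz) over the
    z-slabs crossed by the segment z_from -> z_from + dz (which may leave
    [0, L); slab indices wrap)."""
    if mode == SLAB_MIDPOINT or (dz < 1e-12 and dz > -1e-12):
        zm = (z_from + 0.5 * dz) % L
        s = int(zm / slab_w)
        if s >= n_slabs:
            s = n_slabs - 1
        slab_virial[s, 0] += cx
        slab_virial[s, 1] += cy
        slab_virial[s, 2] += cz
        return
    if dz > 0.0:
        za = z_from
        zb = z_from + dz
    else:
        za = z_from + dz
        zb = z_from
    span = zb - za
    s0 = int(np.floor(za / slab_w))
    s1 = int(np.floor(zb / slab_w))
    for s in range(s0, s1 + 1):
        lo = s * slab_w
        hi = lo + slab_w
        if za > lo:
            lo = za
        if zb < hi:
            hi = zb
        if hi <= lo:
            continue
        w = (hi - lo) / span
        sm = s % n_slabs
        if sm < 0:
            sm += n_slabs
        slab_virial[sm, 0] += cx * w
        slab_virial[sm, 1] += cy * w
        slab_virial[sm, 2] += cz * w


# ---------------------------------------------------------------------------
# pair physics: conservative + dissipative + random DPD forces
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def pair_physics(
    pi, pj, pdx, pdy, pdz, npairs, pos, vel, types,
    amat, gamma, sigma, rc, inv_sqrt_dt,
    seed, step, noise_kind, with_cons, with_diss, with_rand,
    forces, virial, slab_virial, n_slabs, slab_w, slab_mode,
):
    """Apply the DPD pair forces to a pre-built in-range pair list.

    Accumulates forces, the full 3x3 virial W_ab = sum F_ij,a d_ij,b and
    (optionally) the per-slab diagonal virial.  Returns (potential energy,
    number of coincident pairs skipped).
    """
    epot = 0.0
    ndeg = 0
    for m in range(npairs):
        i = pi[m]
        j = pj[m]
        dx = pdx[m]
        dy = pdy[m]
        dz = pdz[m]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r < 1e-12:
            # soft core: finite energy, direction undefined -> no force
            if with_cons:
                epot += 0.5 * amat[types[i], types[j]] * rc
            ndeg += 1
            continue
        inv_r = 1.0 / r
        w = 1.0 - r / rc
        ex = dx * inv_r
        ey = dy * inv_r
        ez = dz * inv_r
        fmag = 0.0
        if with_cons:
            a = amat[types[i], types[j]]
            fmag += a * w
            epot += 0.5 * a * rc * w * w
        if with_diss:
            vdotr = (
                (vel[i, 0] - vel[j, 0]) * ex
                + (vel[i, 1] - vel[j, 1]) * ey
                + (vel[i, 2] - vel[j, 2]) * ez
            )
            fmag -= gamma * w * w * vdotr
        if with_rand:
            zeta = pair_noise(seed, step, i, j, noise_kind)
            fmag += sigma * w * zeta * inv_sqrt_dt
        fx = fmag * ex
        fy = fmag * ey
        fz = fmag * ez
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += fx * dx
        virial[0, 1] += fx * dy
        virial[0, 2] += fx * dz
        virial[1, 0] += fy * dx
        virial[1, 1] += fy * dy
        virial[1, 2] += fy * dz
        virial[2, 0] += fz * dx
        virial[2, 1] += fz * dy
        virial[2, 2] += fz * dz
        if n_slabs > 0:
            _slab_add(
                slab_virial, n_slabs, slab_w, L_from_slabs(slab_w, n_slabs),
                pos[j, 2], dz, fx * dx, fy * dy, fz * dz, slab_mode,
            )
    return epot, ndeg


@njit(cache=True, inline="always")
def L_from_slabs(slab_w, n_slabs):
    return slab_w * n_slabs


def pair_forces(
    pos, vel, types, L, amat, gamma, sigma, rc, inv_sqrt_dt,
    seed, step, noise_kind, with_cons, with_diss, with_rand,
    forces, virial, slab_virial, n_slabs, slab_w, slab_mode,
    neighbor="cell", _pair_buffer=[None],
):
    """Python orchestration: neighbour search + pair physics.

    A per-process pair buffer is grown on demand (the search reports the
    required capacity when it overflows).
    """
    n = pos.shape[0]
    build = build_pairs_cells if neighbor == "cell" else build_pairs_naive
    buf = _pair_buffer[0]
    if buf is None or buf[0].shape[0] < 16 * n:
        cap = max(1024, 16 * n)
        buf = (
            np.empty(cap, np.int64), np.empty(cap, np.int64),
            np.empty(cap, np.float64), np.empty(cap, np.float64),
            np.empty(cap, np.float64),
        )
        _pair_buffer[0] = buf
    npairs = build(pos, L, rc, *buf)
    if npairs > buf[0].shape[0]:
        cap = int(npairs * 1.2)
        buf = (
            np.empty(cap, np.int64), np.empty(cap, np.int64),
            np.empty(cap, np.float64), np.empty(cap, np.float64),
            np.empty(cap, np.float64),
        )
        _pair_buffer[0] = buf
        npairs = build(pos, L, rc, *buf)
    return pair_physics(
        buf[0], buf[1], buf[2], buf[3], buf[4], npairs, pos, vel, types,
        amat, gamma, sigma, rc, inv_sqrt_dt,
        seed, step, noise_kind, with_cons, with_diss, with_rand,
        forces, virial, slab_virial, n_slabs, slab_w, slab_mode,
    )


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def bond_forces(
    pos, bonds, ks, rs, L,
    forces, virial, slab_virial, n_slabs, slab_w, slab_mode,
):
    """Harmonic springs F = ks (1 - r/rs) r_hat; U = ks (r - rs)^2 / (2 rs)."""
    epot = 0.0
    ndeg = 0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], L)
        dy = _min_image(pos[i, 1] - pos[j, 1], L)
        dz = _min_image(pos[i, 2] - pos[j, 2], L)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            ndeg += 1
            continue
        fmag = ks * (1.0 - r / rs)
        epot += ks * (r - rs) * (r - rs) / (2.0 * rs)
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 0] += fx * dx
        virial[0, 1] += fx * dy
        virial[0, 2] += fx * dz
        virial[1, 0] += fy * dx
        virial[1, 1] += fy * dy
        virial[1, 2] += fy * dz
        virial[2, 0] += fz * dx
        virial[2, 1] += fz * dy
        virial[2, 2] += fz * dz
        if n_slabs > 0:
            _slab_add(
                slab_virial, n_slabs, slab_w, slab_w * n_slabs, pos[j, 2], dz,
                fx * dx, fy * dy, fz * dz, slab_mode,
            )
    return epot, ndeg


@njit(cache=True, fastmath=True)
def angle_forces(
    pos, angles, k_theta, theta0, L,
    forces, virial, slab_virial, n_slabs, slab_w, slab_mode,
):
    """Harmonic bending U = k_theta (theta - theta0)^2 on (i, j, k) with j
    the centre bead.  The virial is decomposed onto the two bond vectors
    u = r_i - r_j and w = r_k - r_j (exact: the three forces sum to zero).
    """
    epot = 0.0
    ndeg = 0
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        ux = _min_image(pos[i, 0] - pos[j, 0], L)
        uy = _min_image(pos[i, 1] - pos[j, 1], L)
        uz = _min_image(pos[i, 2] - pos[j, 2], L)
        wx = _min_image(pos[k, 0] - pos[j, 0], L)
        wy = _min_image(pos[k, 1] - pos[j, 1], L)
        wz = _min_image(pos[k, 2] - pos[j, 2], L)
        ru2 = ux * ux + uy * uy + uz * uz
        rw2 = wx * wx + wy * wy + wz * wz
        if ru2 < 1e-24 or rw2 < 1e-24:
            ndeg += 1
            continue
        ru = np.sqrt(ru2)
        rw = np.sqrt(rw2)
        c = (ux * wx + uy * wy + uz * wz) / (ru * rw)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        dtheta = np.arccos(c) - theta0
        epot += k_theta * dtheta * dtheta
        a = -2.0 * k_theta * dtheta / s
        a11 = a * c / ru2
        a12 = -a / (ru * rw)
        a22 = a * c / rw2
        fix = a11 * ux + a12 * wx
        fiy = a11 * uy + a12 * wy
        fiz = a11 * uz + a12 * wz
        fkx = a22 * wx + a12 * ux
        fky = a22 * wy + a12 * uy
        fkz = a22 * wz + a12 * uz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        # virial: u (x) F_i + w (x) F_k
        virial[0, 0] += fix * ux + fkx * wx
        virial[0, 1] += fix * uy + fkx * wy
        virial[0, 2] += fix * uz + fkx * wz
        virial[1, 0] += fiy * ux + fky * wx
        virial[1, 1] += fiy * uy + fky * wy
        virial[1, 2] += fiy * uz + fky * wz
        virial[2, 0] += fiz * ux + fkz * wx
        virial[2, 1] += fiz * uy + fkz * wy
        virial[2, 2] += fiz * uz + fkz * wz
        if n_slabs > 0:
            _slab_add(
                slab_virial, n_slabs, slab_w, slab_w * n_slabs, pos[j, 2], uz,
                fix * ux, fiy * uy, fiz * uz, slab_mode,
            )
            _slab_add(
                slab_virial, n_slabs, slab_w, slab_w * n_slabs, pos[j, 2], wz,
                fkx * wx, fky * wy, fkz * wz, slab_mode,
            )
    return epot, ndeg
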