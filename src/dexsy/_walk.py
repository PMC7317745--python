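"""Numba kernels for membrane-limited random walks.

Walkers take fixed-length steps ``sqrt(6 D dt)`` in uniformly random 3D
directions.  When a step's path crosses a membrane the walker transmits with
probability ``p`` (continuing along the same direction) or reflects
specularly, in either case spending the remaining path length; multiple
membrane interactions within one step are processed iteratively.  After each
interaction the walker is nudged ``NUDGE`` metres off the surface along the
local normal so the same membrane is not re-detected.

Positions are never wrapped: the unwrapped coordinate drives the gradient
phase integral, and the periodic image is recomputed for geometry queries
only.  Each walker owns an independent xoshiro256+ stream seeded by
splitmix64 from ``(master seed, walker index)``, so results do not depend on
batching order.
"""

import numba as nb
import numpy as np

NUDGE = 1e-12  # m, off-surface displacement after reflection/transmission
# Membrane events allowed within a single step before the remainder of that
# step is abandoned (a rare near-contact wedge pathology; counted, never
# silent).
MAX_INTERACTIONS = 4096

_U64 = np.uint64
_MASK = _U64(0xFFFFFFFFFFFFFFFF)
_DOUBLE_NORM = 1.0 / 9007199254740992.0  # 2^-53


@nb.njit(nb.uint64(nb.uint64), inline="always", cache=True)
def _splitmix64(z):
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@nb.njit(inline="always", cache=True)
def _seed_stream(master_seed, walker):
    """Four xoshiro256+ state words from a splitmix64 chain."""
    s = _U64(master_seed) * _U64(0x9E3779B97F4A7C15) + _U64(walker)
    g = _U64(0x9E3779B97F4A7C15)
    s0 = _splitmix64(s + g)
    s1 = _splitmix64(s + _U64(2) * g)
    s2 = _splitmix64(s + _U64(3) * g)
    s3 = _splitmix64(s + _U64(4) * g)
    return s0, s1, s2, s3


@nb.njit(inline="always", cache=True)
def _rotl(x, k):
    return (x << _U64(k)) | (x >> _U64(64 - k))


@nb.njit(inline="always", cache=True)
def _next_uniform(state):
    """xoshiro256+ step; returns (u in [0,1), new state)."""
    s0, s1, s2, s3 = state
    result = s0 + s3
    t = s1 << _U64(17)
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    s3 = _rotl(s3, 45)
    return (result >> _U64(11)) * _DOUBLE_NORM, (s0, s1, s2, s3)


@nb.njit(inline="always", cache=True)
def _sphere_direction(state):
    u1, state = _next_uniform(state)
    u2, state = _next_uniform(state)
    z = 1.0 - 2.0 * u1
    st = np.sqrt(max(0.0, 1.0 - z * z))
    phi = 2.0 * np.pi * u2
    return st * np.cos(phi), st * np.sin(phi), z, state


@nb.njit(inline="always", cache=True)
def _cell_index(wx, wy, wz, L, ncell):
    ix = int(wx / L * ncell)
    iy = int(wy / L * ncell)
    iz = int(wz / L * ncell)
    if ix >= ncell:
        ix = ncell - 1
    if iy >= ncell:
        iy = ncell - 1
    if iz >= ncell:
        iz = ncell - 1
    return (ix * ncell + iy) * ncell + iz


@nb.njit(cache=True)
def walk_spheres(centers, radius, L, cell_start, cell_items, ncell,
                 n_walkers, n_steps, dt, ell, p, seed,
                 W, ex, ey, ez, save_every, traj, integ, pos0, posT, errors):
    """Random walk among equal spheres in a periodic cubic box.

    ``W`` is an ``(n_seq, n_steps)`` unit-amplitude effective gradient
    waveform; ``integ[w, s]`` accumulates ``sum_t W[s, t] * x_proj(t) * dt``
    with the projection onto ``(ex, ey, ez)`` taken at the end of each step.
    ``traj`` stores the unwrapped position every ``save_every`` steps when
    ``save_every > 0`` (slot 0 is the initial position).
    """
    n_seq = W.shape[0]
    r2 = radius * radius
    for w in range(n_walkers):
        state = _seed_stream(seed, w)
        u1, state = _next_uniform(state)
        u2, state = _next_uniform(state)
        u3, state = _next_uniform(state)
        x = u1 * L
        y = u2 * L
        z = u3 * L
        pos0[w, 0] = x
        pos0[w, 1] = y
        pos0[w, 2] = z
        if save_every > 0:
            traj[w, 0, 0] = x
            traj[w, 0, 1] = y
            traj[w, 0, 2] = z
        for t in range(n_steps):
            dx, dy, dz, state = _sphere_direction(state)
            remaining = ell
            guard = 0
            while remaining > 0.0 and guard < MAX_INTERACTIONS:
                guard += 1
                wx = x - L * np.floor(x / L)
                wy = y - L * np.floor(y / L)
                wz = z - L * np.floor(z / L)
                cid = _cell_index(wx, wy, wz, L, ncell)
                s_hit = remaining
                hit = -1
                for ci in range(cell_start[cid], cell_start[cid + 1]):
                    k = cell_items[ci]
                    mx = centers[k, 0] - wx
                    my = centers[k, 1] - wy
                    mz = centers[k, 2] - wz
                    mx -= L * np.rint(mx / L)
                    my -= L * np.rint(my / L)
                    mz -= L * np.rint(mz / L)
                    b = dx * mx + dy * my + dz * mz
                    c0 = mx * mx + my * my + mz * mz - r2
                    disc = b * b - c0
                    if disc < 0.0:
                        continue
                    sq = np.sqrt(disc)
                    s = b - sq
                    if s <= 0.0:
                        s = b + sq
                    if 0.0 < s < s_hit:
                        s_hit = s
                        hit = k
                if hit < 0:
                    x += dx * remaining
                    y += dy * remaining
                    z += dz * remaining
                    remaining = 0.0
                else:
                    x += dx * s_hit
                    y += dy * s_hit
                    z += dz * s_hit
                    remaining -= s_hit
                    # outward normal at the hit point (min-image center)
                    wxh = x - L * np.floor(x / L)
                    wyh = y - L * np.floor(y / L)
                    wzh = z - L * np.floor(z / L)
                    nx = wxh - centers[hit, 0]
                    ny = wyh - centers[hit, 1]
                    nz = wzh - centers[hit, 2]
                    nx -= L * np.rint(nx / L)
                    ny -= L * np.rint(ny / L)
                    nz -= L * np.rint(nz / L)
                    nx /= radius
                    ny /= radius
                    nz /= radius
                    u, state = _next_uniform(state)
                    if u >= p:  # reflect
                        dn = dx * nx + dy * ny + dz * nz
                        dx -= 2.0 * dn * nx
                        dy -= 2.0 * dn * ny
                        dz -= 2.0 * dn * nz
                    # nudge off the surface along the travel side
                    sgn = 1.0 if (dx * nx + dy * ny + dz * nz) > 0.0 else -1.0
                    x += sgn * NUDGE * nx
                    y += sgn * NUDGE * ny
                    z += sgn * NUDGE * nz
            if guard >= MAX_INTERACTIONS:
                errors[w] += 1
            if n_seq > 0:
                proj = x * ex + y * ey + z * ez
                for sq_i in range(n_seq):
                    wv = W[sq_i, t]
                    if wv != 0.0:
                        integ[w, sq_i] += wv * proj * dt
            if save_every > 0 and (t + 1) % save_every == 0:
                idx = (t + 1) // save_every
                traj[w, idx, 0] = x
                traj[w, idx, 1] = y
                traj[w, idx, 2] = z
        posT[w, 0] = x
        posT[w, 1] = y
        posT[w, 2] = z


@nb.njit(cache=True)
def walk_cylinders(centers, radii, L, cell_start, cell_items, ncell,
                   n_walkers, n_steps, dt, ell, p, seed,
                   W, ex, ey, ez, save_every, traj, integ, pos0, posT,
                   errors):
    """Random walk among parallel z-axis cylinders, periodic in x and y.

    Same contract as :func:`walk_spheres`; membrane geometry lives in the
    transverse plane while motion remains three-dimensional.
    """
    n_seq = W.shape[0]
    for w in range(n_walkers):
        state = _seed_stream(seed, w)
        u1, state = _next_uniform(state)
        u2, state = _next_uniform(state)
        u3, state = _next_uniform(state)
        x = u1 * L
        y = u2 * L
        z = u3 * L
        pos0[w, 0] = x
        pos0[w, 1] = y
        pos0[w, 2] = z
        if save_every > 0:
            traj[w, 0, 0] = x
            traj[w, 0, 1] = y
            traj[w, 0, 2] = z
        for t in range(n_steps):
            dx, dy, dz, state = _sphere_direction(state)
            remaining = ell
            guard = 0
            while remaining > 0.0 and guard < MAX_INTERACTIONS:
                guard += 1
                wx = x - L * np.floor(x / L)
                wy = y - L * np.floor(y / L)
                a2 = dx * dx + dy * dy  # transverse speed^2
                if a2 < 1e-24:  # moving along the axis: no membrane
                    x += dx * remaining
                    y += dy * remaining
                    z += dz * remaining
                    remaining = 0.0
                    break
                ix = int(wx / L * ncell)
                iy = int(wy / L * ncell)
                if ix >= ncell:
                    ix = ncell - 1
                if iy >= ncell:
                    iy = ncell - 1
                cid = ix * ncell + iy
                s_hit = remaining
                hit = -1
                for ci in range(cell_start[cid], cell_start[cid + 1]):
                    k = cell_items[ci]
                    mx = centers[k, 0] - wx
                    my = centers[k, 1] - wy
                    mx -= L * np.rint(mx / L)
                    my -= L * np.rint(my / L)
                    b = dx * mx + dy * my
                    c0 = mx * mx + my * my - radii[k] * radii[k]
                    disc = b * b - a2 * c0
                    if disc < 0.0:
                        continue
                    sq = np.sqrt(disc)
                    s = (b - sq) / a2
                    if s <= 0.0:
                        s = (b + sq) / a2
                    if 0.0 < s < s_hit:
                        s_hit = s
                        hit = k
                if hit < 0:
                    x += dx * remaining
                    y += dy * remaining
                    z += dz * remaining
                    remaining = 0.0
                else:
                    x += dx * s_hit
                    y += dy * s_hit
                    z += dz * s_hit
                    remaining -= s_hit
                    wxh = x - L * np.floor(x / L)
                    wyh = y - L * np.floor(y / L)
                    nx = wxh - centers[hit, 0]
                    ny = wyh - centers[hit, 1]
                    nx -= L * np.rint(nx / L)
                    ny -= L * np.rint(ny / L)
                    nx /= radii[hit]
                    ny /= radii[hit]
                    u, state = _next_uniform(state)
                    if u >= p:  # specular reflection about the xy normal
                        dn = dx * nx + dy * ny
                        dx -= 2.0 * dn * nx
                        dy -= 2.0 * dn * ny
                    sgn = 1.0 if (dx * nx + dy * ny) > 0.0 else -1.0
                    x += sgn * NUDGE * nx
                    y += sgn * NUDGE * ny
            if guard >= MAX_INTERACTIONS:
                errors[w] += 1
            if n_seq > 0:
                proj = x * ex + y * ey + z * ez
                for sq_i in range(n_seq):
                    wv = W[sq_i, t]
                    if wv != 0.0:
                        integ[w, sq_i] += wv * proj * dt
            if save_every > 0 and (t + 1) % save_every == 0:
                idx = (t + 1) // save_every
                traj[w, idx, 0] = x
                traj[w, idx, 1] = y
                traj[w, idx, 2] = z
        posT[w, 0] = x
        posT[w, 1] = y
        posT[w, 2] = z
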