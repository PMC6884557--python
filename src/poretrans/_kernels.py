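"""Numba kernels for force evaluation and Langevin time stepping.

Everything here works on plain float64 arrays in reduced LJ units.  The
kernels are deliberately free of Python objects so a whole chunk of steps
runs inside one njit call; the public modules (`forcefield`, `integrator`,
`protocol`) wrap them with validated dataclasses.

Status codes returned by the kernels:
  0  ok / chunk exhausted
  1  pair overlap (r below the overlap guard; timestep too large)
  2  FENE bond overstretched (r >= R0)
  3  translocation completed (all N beads past the trans plane)
  4  retracted (every bead back on the cis side)
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERLAP = 1
STATUS_OVERSTRETCH = 2
STATUS_COMPLETED = 3
STATUS_RETRACTED = 4

NO_WALL = 1.0e9
_OVERLAP_R = 0.25  # pair separations below this (in sigma) abort the step


@njit(cache=True)
def wall_dist_grad(x, y, z, x0, x1, cy, cz, rp):
    """Distance to the annular wall faces and its gradient direction.

    Returns (d, ux, uy, uz) with u the unit direction of increasing
    distance (from the nearest surface point toward the query point).
    Points inside the bore return (NO_WALL, 0, 0, 0).
    """
    dy = y - cy
    dz = z - cz
    rho = np.sqrt(dy * dy + dz * dz)
    if x < x0 or x > x1:
        ax = x0 - x if x < x0 else x - x1
        sx = -1.0 if x < x0 else 1.0
        if rho >= rp:
            return ax, sx, 0.0, 0.0
        dr = rp - rho
        d = np.sqrt(ax * ax + dr * dr)
        if d < 1e-12:
            return 0.0, sx, 0.0, 0.0
        if rho > 1e-12:
            ery = dy / rho
            erz = dz / rho
        else:
            ery = 1.0
            erz = 0.0
        # nearest point is on the rim circle at radius rp
        return d, sx * ax / d, -ery * dr / d, -erz * dr / d
    # axial coordinate within the slab
    if rho < rp:
        return NO_WALL, 0.0, 0.0, 0.0
    # inside the solid: push out through the nearer face
    d1 = x - x0
    d2 = x1 - x
    if d1 <= d2:
        return d1, -1.0, 0.0, 0.0
    return d2, 1.0, 0.0, 0.0


@njit(cache=True)
def pore_dist_grad(x, y, z, x0, x1, cy, cz, rp):
    """Distance to the finite cylindrical bore surface and its gradient."""
    dy = y - cy
    dz = z - cz
    rho = np.sqrt(dy * dy + dz * dz)
    if rho > 1e-12:
        ery = dy / rho
        erz = dz / rho
    else:
        ery = 1.0
        erz = 0.0
    if x0 <= x <= x1:
        dr = rp - rho
        if rho < rp:
            if rho <= 1e-12:
                # on the axis the direction is degenerate (conical kink)
                return dr, 0.0, 0.0, 0.0
            return dr, 0.0, -ery, -erz
        return -dr, 0.0, ery, erz
    ax = x0 - x if x < x0 else x - x1
    sx = -1.0 if x < x0 else 1.0
    dr = rho - rp
    d = np.sqrt(ax * ax + dr * dr)
    if d < 1e-12:
        return 0.0, sx, 0.0, 0.0
    return d, sx * ax / d, ery * dr / d, erz * dr / d


@njit(cache=True)
def _lj_force_over_r(r2, sigma, eps):
    """(dU/dr)/(-r) for the 12-6 LJ, i.e. pair force magnitude / r."""
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    return 24.0 * eps * s6 * (2.0 * s6 - 1.0) / r2


@njit(cache=True)
def _lj_energy(r2, sigma, eps):
    s2 = sigma * sigma / r2
    s6 = s2 * s2 * s2
    return 4.0 * eps * (s6 * s6 - s6)


@njit(cache=True)
def compute_forces(pos, sigma, eps_mm, wca_cut, fene_k, fene_r0,
                   x0, x1, cy, cz, rp, eps_pore, pore_cut, pore_shifted,
                   f_pull, apply_external, want_energy,
                   f_wca, f_fene, f_wall, f_pore, f_ext, err_idx):
    """Fill the five force-component arrays for one configuration.

    Returns (status, potential_energy).  Energy is only meaningful when
    ``want_energy`` is true (the shifted/literal pore dialect only affects
    the energy, never the force).
    """
    n = pos.shape[0]
    f_wca[:] = 0.0
    f_fene[:] = 0.0
    f_wall[:] = 0.0
    f_pore[:] = 0.0
    f_ext[:] = 0.0
    pe = 0.0
    wca_cut2 = wca_cut * wca_cut
    # pair WCA between all monomers (bonded pairs included)
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < _OVERLAP_R * _OVERLAP_R * sigma * sigma:
                err_idx[0] = i
                err_idx[1] = j
                return STATUS_OVERLAP, 0.0
            if r2 <= wca_cut2:
                fr = _lj_force_over_r(r2, sigma, eps_mm)
                f_wca[i, 0] += fr * dx
                f_wca[i, 1] += fr * dy
                f_wca[i, 2] += fr * dz
                f_wca[j, 0] -= fr * dx
                f_wca[j, 1] -= fr * dy
                f_wca[j, 2] -= fr * dz
                if want_energy:
                    pe += _lj_energy(r2, sigma, eps_mm) + eps_mm
    # FENE bonds between adjacent monomers
    r02 = fene_r0 * fene_r0
    for i in range(n - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            err_idx[0] = i
            err_idx[1] = i + 1
            return STATUS_OVERSTRETCH, 0.0
        denom = 1.0 - r2 / r02
        fr = -fene_k / denom  # attractive: force on i points toward i+1
        f_fene[i, 0] += fr * dx
        f_fene[i, 1] += fr * dy
        f_fene[i, 2] += fr * dz
        f_fene[i + 1, 0] -= fr * dx
        f_fene[i + 1, 1] -= fr * dy
        f_fene[i + 1, 2] -= fr * dz
        if want_energy:
            pe += -0.5 * fene_k * r02 * np.log(denom)
    # membrane: repulsive WCA walls, attractive pore LJ, pulling force
    pore_cut2 = pore_cut  # cutoffs compared on distances here, not squares
    for i in range(n):
        x = pos[i, 0]
        y = pos[i, 1]
        z = pos[i, 2]
        d, ux, uy, uz = wall_dist_grad(x, y, z, x0, x1, cy, cz, rp)
        if d <= wca_cut:
            if d < _OVERLAP_R * sigma:
                err_idx[0] = i
                err_idx[1] = -1
                return STATUS_OVERLAP, 0.0
            fr = _lj_force_over_r(d * d, sigma, eps_mm) * d
            f_wall[i, 0] += fr * ux
            f_wall[i, 1] += fr * uy
            f_wall[i, 2] += fr * uz
            if want_energy:
                pe += _lj_energy(d * d, sigma, eps_mm) + eps_mm
        d, ux, uy, uz = pore_dist_grad(x, y, z, x0, x1, cy, cz, rp)
        if d <= pore_cut2:
            if d < _OVERLAP_R * sigma:
                err_idx[0] = i
                err_idx[1] = -2
                return STATUS_OVERLAP, 0.0
            fr = _lj_force_over_r(d * d, sigma, eps_pore) * d
            f_pore[i, 0] += fr * ux
            f_pore[i, 1] += fr * uy
            f_pore[i, 2] += fr * uz
            if want_energy:
                if pore_shifted:
                    pe += _lj_energy(d * d, sigma, eps_pore) \
                        - _lj_energy(pore_cut * pore_cut, sigma, eps_pore)
                else:
                    pe += _lj_energy(d * d, sigma, eps_pore) + eps_pore
        if apply_external:
            dyc = y - cy
            dzc = z - cz
            if x0 <= x <= x1 and dyc * dyc + dzc * dzc < rp * rp:
                f_ext[i, 0] += f_pull
    return STATUS_OK, pe


@njit(cache=True)
def potential_energy(pos, sigma, eps_mm, wca_cut, fene_k, fene_r0,
                     x0, x1, cy, cz, rp, eps_pore, pore_cut, pore_shifted):
    """Total potential energy of a configuration (external force excluded)."""
    n = pos.shape[0]
    scratch = np.zeros((n, 3))
    err = np.empty(2, dtype=np.int64)
    status, pe = compute_forces(
        pos, sigma, eps_mm, wca_cut, fene_k, fene_r0,
        x0, x1, cy, cz, rp, eps_pore, pore_cut, pore_shifted,
        0.0, False, True,
        scratch, np.zeros((n, 3)), np.zeros((n, 3)), np.zeros((n, 3)),
        np.zeros((n, 3)), err)
    if status != STATUS_OK:
        return np.nan
    return pe


@njit(cache=True)
def run_chunk(pos, vel, noise, noise_scale, dt, mass, friction,
              sigma, eps_mm, wca_cut, fene_k, fene_r0,
              x0, x1, cy, cz, rp, eps_pore, pore_cut,
              f_pull, apply_external, pinned,
              record_exits, exit_times, snapshots, exited, t_start,
              err_idx, v2_accum):
    """Advance the chain by up to noise.shape[0] Langevin steps.

    One step of the stochastic velocity-Verlet update (m = bead mass,
    xi = friction, R the per-step Gaussian random force):

        v(t+dt/2) = v(t) + dt/2m [F(x(t)) - xi v(t) + R]
        x(t+dt)   = x(t) + dt v(t+dt/2)
        v(t+dt)   = v(t+dt/2) + dt/2m [F(x(t+dt)) - xi v(t+dt/2) + R]

    With xi = 0 and zero noise this is exactly velocity Verlet.  Pinned
    beads keep zero velocity and fixed positions.  When ``record_exits``
    is set, ``exited`` marks beads that have crossed the trans plane at
    least once; exit_times[s] (s = 1..N) receives the first time at which
    s beads have done so, and snapshots[s] a copy of the positions at that
    instant.  Re-entering beads never rewind the counter.

    Returns (status, steps_done, t_end).
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    half = 0.5 * dt / mass
    f_wca = np.zeros((n, 3))
    f_fene = np.zeros((n, 3))
    f_wall = np.zeros((n, 3))
    f_pore = np.zeros((n, 3))
    f_ext = np.zeros((n, 3))
    ftot = np.zeros((n, 3))
    vhalf = np.zeros((n, 3))

    status, _ = compute_forces(
        pos, sigma, eps_mm, wca_cut, fene_k, fene_r0,
        x0, x1, cy, cz, rp, eps_pore, pore_cut, True,
        f_pull, apply_external, False,
        f_wca, f_fene, f_wall, f_pore, f_ext, err_idx)
    if status != STATUS_OK:
        return status, 0, t_start
    for i in range(n):
        for k in range(3):
            ftot[i, k] = (f_wca[i, k] + f_fene[i, k] + f_wall[i, k]
                          + f_pore[i, k] + f_ext[i, k])

    s_reached = 0
    if record_exits:
        for s in range(1, n + 1):
            if exit_times[s] >= 0.0:
                s_reached = s

    t = t_start
    for step in range(nsteps):
        for i in range(n):
            if pinned[i]:
                vhalf[i, 0] = 0.0
                vhalf[i, 1] = 0.0
                vhalf[i, 2] = 0.0
                continue
            for k in range(3):
                r = noise_scale * noise[step, i, k]
                vhalf[i, k] = vel[i, k] + half * (
                    ftot[i, k] - friction * vel[i, k] + r)
                pos[i, k] += dt * vhalf[i, k]
        status, _ = compute_forces(
            pos, sigma, eps_mm, wca_cut, fene_k, fene_r0,
            x0, x1, cy, cz, rp, eps_pore, pore_cut, True,
            f_pull, apply_external, False,
            f_wca, f_fene, f_wall, f_pore, f_ext, err_idx)
        if status != STATUS_OK:
            return status, step, t
        for i in range(n):
            if pinned[i]:
                vel[i, 0] = 0.0
                vel[i, 1] = 0.0
                vel[i, 2] = 0.0
                continue
            for k in range(3):
                r = noise_scale * noise[step, i, k]
                ftot[i, k] = (f_wca[i, k] + f_fene[i, k] + f_wall[i, k]
                              + f_pore[i, k] + f_ext[i, k])
                vel[i, k] = vhalf[i, k] + half * (
                    ftot[i, k] - friction * vhalf[i, k] + r)
        t = t_start + (step + 1) * dt
        for i in range(n):
            v2_accum[0] += vel[i, 0] * vel[i, 0]
            v2_accum[1] += vel[i, 1] * vel[i, 1]
            v2_accum[2] += vel[i, 2] * vel[i, 2]
        v2_accum[3] += n

        if record_exits:
            count = 0
            all_cis = True
            for i in range(n):
                if pos[i, 0] > x1:
                    exited[i] = True
                if exited[i]:
                    count += 1
                if pos[i, 0] >= x0:
                    all_cis = False
            while s_reached < count:
                s_reached += 1
                exit_times[s_reached] = t
                for i in range(n):
                    for k in range(3):
                        snapshots[s_reached, i, k] = pos[i, k]
            if s_reached == n:
                return STATUS_COMPLETED, step + 1, t
            if all_cis:
                return STATUS_RETRACTED, step + 1, t
    return STATUS_OK, nsteps, t
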