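"""Numba photon-transport kernel (Woodcock delta tracking).

Single compiled entry point `run_kernel`; everything is passed as plain
arrays/scalars.  Geometry frame: z up from the detector plane (mm); the
support-table slab sits on the detector, the phantom on the table, the
compression paddle above the phantom.  One history is one primary photon
(the kerma approximation creates no secondary particles).

Energy bookkeeping is exact per history: emitted = deposited + escaped,
with photons killed in the pre-paddle air column counted as escaped.
"""
import numpy as np
from numba import njit

MEC2 = 510.99895  # keV


@njit(cache=False)
def _he(d_cm, a, b, c):
    d2 = d_cm * d_cm
    return a + b * d2 + c * d2 * d2


@njit(cache=False)
def _rotate(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) < 0.99999:
        rho = np.sqrt(1.0 - uz * uz)
        vx = ux * cost + sint * (ux * uz * cosp - uy * sinp) / rho
        vy = uy * cost + sint * (uy * uz * cosp + ux * sinp) / rho
        vz = uz * cost - rho * sint * cosp
    else:
        sign = 1.0 if uz > 0.0 else -1.0
        vx = sint * cosp
        vy = sint * sinp * sign
        vz = cost * sign
    norm = 1.0 / np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx * norm, vy * norm, vz * norm


@njit(cache=False)
def _kahn_compton(e_kev):
    """Sample a free-electron Klein-Nishina scatter (Kahn's rejection).

    Returns (cos_theta, e_scattered_keV)."""
    alpha = e_kev / MEC2
    t = 1.0 + 2.0 * alpha
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= t / (t + 8.0):
            eta = 1.0 + 2.0 * alpha * r2        # eta = E/E'
            if r3 <= 4.0 * (1.0 / eta - 1.0 / (eta * eta)):
                break
        else:
            eta = t / (1.0 + 2.0 * alpha * r2)
            mu = 1.0 - (eta - 1.0) / alpha
            if r3 <= 0.5 * (mu * mu + 1.0 / eta):
                break
    cost = 1.0 - (eta - 1.0) / alpha
    if cost < -1.0:
        cost = -1.0
    elif cost > 1.0:
        cost = 1.0
    return cost, e_kev / eta


@njit(cache=False)
def _thomson_cost():
    while True:
        mu = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + mu * mu):
            return mu


@njit(cache=False)
def run_kernel(seed, n_hist,
               # source / heel (distances mm; heel distances in cm)
               src_z, half_fx, field_y,
               ay, by, cy, ax, bx, cx, wmax,
               # spectrum sampling
               cum_phi, e_edges,
               # cross-section lookup grid
               e0, de,
               mu_tot, mu_pe, mu_incoh,   # (n_mat, n_e) linear, 1/mm
               mu_maj,                    # (n_e,)
               rho_mat,                   # (n_mat,) g/cm^3
               # slab geometry
               z_support, z_pad_bot, z_pad_top,
               # phantom voxel grid
               ph_ox, ph_oy, ph_oz, voxel, labels, lab2mat,
               # world bounding box
               wx0, wx1, wy0, wy1, wz0, wz1,
               # box tallies
               boxes, box_muen, box_vol, collision_boxes,
               # 2D map (TLD-material layer)
               map_on, map_x0, map_y0, map_pitch, map_nx, map_ny,
               map_z0, map_z1, map_mat,
               # per-voxel deposition / glandular scoring
               vox_on, gland_share,
               cutoff):
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    n_e = mu_maj.shape[0]
    n_box = boxes.shape[0]

    tally_sum = np.zeros(n_box)
    tally_sum2 = np.zeros(n_box)
    h_tally = np.zeros(n_box)
    npix = map_nx * map_ny
    map_sum = np.zeros(npix)
    map_sum2 = np.zeros(npix)
    map_tmp = np.zeros(npix)
    map_last = np.full(npix, -1, dtype=np.int64)
    edep_vox = np.zeros((nx, ny, nz)) if vox_on else np.zeros((1, 1, 1))
    gland_sum = 0.0
    gland_sum2 = 0.0
    emitted = 0.0
    edep_total = 0.0
    escaped = 0.0

    for h in range(n_hist):
        # --- source sampling: uniform field point, rejection on heel x
        #     isotropic solid-angle weight
        xd = 0.0
        yd = 0.0
        rr = 1.0
        while True:
            xd = (np.random.random() - 0.5) * 2.0 * half_fx
            yd = np.random.random() * field_y
            r2 = xd * xd + yd * yd + src_z * src_z
            rr = np.sqrt(r2)
            w = (_he(yd / 10.0, ay, by, cy) * _he(abs(xd) / 10.0, ax, bx, cx)
                 * (src_z / rr) / r2)
            if np.random.random() * wmax <= w:
                break
        u = np.random.random()
        ib = np.searchsorted(cum_phi, u)
        if ib >= cum_phi.shape[0]:
            ib = cum_phi.shape[0] - 1
        e = e_edges[ib] + np.random.random() * (e_edges[ib + 1] - e_edges[ib])
        emitted += e
        ux = xd / rr
        uy = yd / rr
        uz = -src_z / rr

        # --- air column down to the paddle top (analytic attenuation,
        #     scattered-in-air photons treated as lost)
        s_top = (z_pad_top - src_z) / uz
        ie = int((e - e0) / de)
        if ie < 0:
            ie = 0
        elif ie >= n_e:
            ie = n_e - 1
        if np.random.random() > np.exp(-mu_tot[0, ie] * s_top):
            escaped += e
            continue
        x = ux * s_top
        y = uy * s_top
        z = z_pad_top - 1e-9

        h_gland = 0.0
        for k in range(n_box):
            h_tally[k] = 0.0

        alive = True
        steps = 0
        while alive and steps < 100000:
            steps += 1
            ie = int((e - e0) / de)
            if ie < 0:
                ie = 0
            elif ie >= n_e:
                ie = n_e - 1
            s = -np.log(np.random.random()) / mu_maj[ie]

            # distance to world exit
            s_exit = 1e30
            if ux > 0.0:
                s_exit = min(s_exit, (wx1 - x) / ux)
            elif ux < 0.0:
                s_exit = min(s_exit, (wx0 - x) / ux)
            if uy > 0.0:
                s_exit = min(s_exit, (wy1 - y) / uy)
            elif uy < 0.0:
                s_exit = min(s_exit, (wy0 - y) / uy)
            if uz > 0.0:
                s_exit = min(s_exit, (wz1 - z) / uz)
            elif uz < 0.0:
                s_exit = min(s_exit, (wz0 - z) / uz)
            s_seg = s if s < s_exit else s_exit

            # track-length box tallies over this flight segment
            if n_box > 0 and not collision_boxes:
                za = z
                zb = z + uz * s_seg
                zlo = za if za < zb else zb
                zhi = za if za > zb else zb
                for k in range(n_box):
                    if boxes[k, 5] < zlo or boxes[k, 4] > zhi:
                        continue
                    tmin = 0.0
                    tmax = s_seg
                    hit = True
                    for axis in range(3):
                        p = x if axis == 0 else (y if axis == 1 else z)
                        d = ux if axis == 0 else (uy if axis == 1 else uz)
                        lo = boxes[k, 2 * axis]
                        hi = boxes[k, 2 * axis + 1]
                        if d > 1e-12 or d < -1e-12:
                            t1 = (lo - p) / d
                            t2 = (hi - p) / d
                            if t1 > t2:
                                t1, t2 = t2, t1
                            if t1 > tmin:
                                tmin = t1
                            if t2 < tmax:
                                tmax = t2
                            if tmin >= tmax:
                                hit = False
                                break
                        elif p < lo or p > hi:
                            hit = False
                            break
                    if hit and tmax > tmin:
                        # fluence x E x (muen/rho): keV/g
                        h_tally[k] += ((tmax - tmin) / 10.0) * e \
                            * box_muen[k, ie] / box_vol[k]

            if s >= s_exit:
                escaped += e
                alive = False
                break
            x += ux * s
            y += uy * s
            z += uz * s

            # material lookup
            if map_on and map_z0 <= z < map_z1 \
                    and map_x0 <= x < map_x0 + map_nx * map_pitch \
                    and map_y0 <= y < map_y0 + map_ny * map_pitch:
                m = map_mat
            elif z < z_support:
                m = 2
            elif z_pad_bot <= z < z_pad_top:
                m = 1
            else:
                m = 0
                ix = int((x - ph_ox) / voxel)
                iy = int((y - ph_oy) / voxel)
                iz = int((z - ph_oz) / voxel)
                if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                    m = lab2mat[labels[ix, iy, iz]]

            if np.random.random() * mu_maj[ie] > mu_tot[m, ie]:
                continue  # fictitious interaction

            xi = np.random.random() * mu_tot[m, ie]
            e_dep = 0.0
            if xi < mu_pe[m, ie]:
                e_dep = e
                alive = False
            elif xi < mu_pe[m, ie] + mu_incoh[m, ie]:
                cost, e_new = _kahn_compton(e)
                e_dep = e - e_new
                if e_new < cutoff:
                    e_dep += e_new
                    alive = False
                else:
                    e = e_new
                    ux, uy, uz = _rotate(ux, uy, uz, cost,
                                         2.0 * np.pi * np.random.random())
            else:
                cost = _thomson_cost()
                ux, uy, uz = _rotate(ux, uy, uz, cost,
                                     2.0 * np.pi * np.random.random())

            if e_dep > 0.0:
                edep_total += e_dep
                # collision-estimator box tallies
                if n_box > 0 and collision_boxes:
                    for k in range(n_box):
                        if boxes[k, 0] <= x < boxes[k, 1] \
                                and boxes[k, 2] <= y < boxes[k, 3] \
                                and boxes[k, 4] <= z < boxes[k, 5]:
                            h_tally[k] += e_dep / (box_vol[k] * rho_mat[m])
                if map_on and map_z0 <= z < map_z1 \
                        and map_x0 <= x < map_x0 + map_nx * map_pitch \
                        and map_y0 <= y < map_y0 + map_ny * map_pitch:
                    px = int((x - map_x0) / map_pitch)
                    py = int((y - map_y0) / map_pitch)
                    p = px * map_ny + py
                    if map_last[p] != h:
                        map_sum[p] += map_tmp[p]
                        map_sum2[p] += map_tmp[p] * map_tmp[p]
                        map_tmp[p] = 0.0
                        map_last[p] = h
                    map_tmp[p] += e_dep
                ix = int((x - ph_ox) / voxel)
                iy = int((y - ph_oy) / voxel)
                iz = int((z - ph_oz) / voxel)
                if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                    if vox_on:
                        edep_vox[ix, iy, iz] += e_dep
                    h_gland += e_dep * gland_share[labels[ix, iy, iz]]

        for k in range(n_box):
            tally_sum[k] += h_tally[k]
            tally_sum2[k] += h_tally[k] * h_tally[k]
        gland_sum += h_gland
        gland_sum2 += h_gland * h_gland

    # flush pending per-pixel history sums
    for p in range(npix):
        if map_last[p] >= 0 and map_tmp[p] != 0.0:
            map_sum[p] += map_tmp[p]
            map_sum2[p] += map_tmp[p] * map_tmp[p]
            map_tmp[p] = 0.0

    return (tally_sum, tally_sum2, map_sum, map_sum2, edep_vox,
            gland_sum, gland_sum2, emitted, edep_total, escaped)
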