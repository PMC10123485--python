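"""Numba-compiled core of the Brownian-dynamics engine.

State is held in flat int64/float64 arrays so the per-step loop compiles to
machine code.  Layouts:

``rec_i`` (n_rec, 9): chain-left neighbour, chain-right neighbour, Igα
status, Igβ status, Igα occupant kind, Igα occupant id, Igβ occupant kind,
Igβ occupant id, current domain index (-1 outside).  A chain is a doubly
linked path; its head has left == -1 and all members share one position.

``lyn_i`` (n_lyn, 4): Y397 status, bound receptor (-1 free), bound site
(0 Igα / 1 Igβ), binding mode (0 none / 1 unique domain / 2 SH2).

``syk_i`` (n_syk, 4): catalytic status, linker status, bound receptor,
bound site.

Rate tables are passed as small arrays of *per-step probabilities*
(1 - exp(-k dt)) precomputed by :mod:`prebcr.dynamics`.

The step order is first-order events -> diffusion -> collision detection
and binding, so a newly formed pair survives at least one step.
"""

import math

import numpy as np
from numba import njit

# rec_i columns
R_LEFT, R_RIGHT, R_IGA, R_IGB, R_AK, R_AID, R_BK, R_BID, R_DOM = range(9)
# lyn_i columns
L_Y397, L_REC, L_SITE, L_MODE = range(4)
# syk_i columns
S_CAT, S_LNK, S_REC, S_SITE = range(4)
# occupant kinds
OCC_NONE, OCC_LYN, OCC_SYK = 0, 1, 2
# counters
(C_ATT, C_ESC, C_MERGE, C_SPLIT, C_LBIND, C_LUNB, C_SBIND, C_SUNB,
 C_PHOS, C_DEPH, C_BOND_OPP, C_PAIR_OPP, C_CAND_OVF) = range(13)
N_COUNTERS = 13
# observable-count columns written by _record
(O_IGA1, O_IGA2, O_IGB1, O_IGB2, O_LBND, O_LACT, O_SBND, O_SCAT, O_SLNK,
 O_NCHAIN) = range(10)
N_OBS = 10

TWO_PI = 2.0 * math.pi


@njit(cache=True, inline="always")
def _wrap1(x, length):
    if x < 0.0 or x >= length:
        x = x % length
    return x


@njit(cache=True, inline="always")
def _minimg(d, length):
    if d > 0.5 * length:
        d -= length
    elif d < -0.5 * length:
        d += length
    return d


@njit(cache=True, inline="always")
def _fold(z, length):
    """Mirror a coordinate into [0, length] (reflective boundary)."""
    if 0.0 <= z <= length:
        return z
    z = z % (2.0 * length)
    if z > length:
        z = 2.0 * length - z
    return z


@njit(cache=True)
def _point_in_poly(px, py, poly_x, poly_y, i0, i1):
    """Ray-casting point-in-polygon over vertices [i0, i1)."""
    inside = False
    j = i1 - 1
    for i in range(i0, i1):
        yi = poly_y[i]
        yj = poly_y[j]
        if (yi > py) != (yj > py):
            xi = poly_x[i]
            xcross = (poly_x[j] - xi) * (py - yi) / (yj - yi) + xi
            if px < xcross:
                inside = not inside
        j = i
    return inside


@njit(cache=True)
def _find_domain(x, y, poly_x, poly_y, poly_off, poly_bb):
    for d in range(poly_off.shape[0] - 1):
        if (x < poly_bb[d, 0] or x > poly_bb[d, 2]
                or y < poly_bb[d, 1] or y > poly_bb[d, 3]):
            continue
        if _point_in_poly(x, y, poly_x, poly_y, poly_off[d], poly_off[d + 1]):
            return d
    return -1


@njit(cache=True)
def _first_crossing(x0, y0, x1, y1, poly_x, poly_y, i0, i1, skip_edge):
    """First intersection of segment (x0,y0)->(x1,y1) with the polygon
    boundary; returns (t, edge_index) or (2.0, -1) if none.  ``skip_edge``
    excludes the edge just reflected about."""
    dx = x1 - x0
    dy = y1 - y0
    best_t = 2.0
    best_e = -1
    for e in range(i0, i1):
        if e == skip_edge:
            continue
        ax = poly_x[e]
        ay = poly_y[e]
        n = e + 1 if e + 1 < i1 else i0
        ex = poly_x[n] - ax
        ey = poly_y[n] - ay
        denom = dx * ey - dy * ex
        if denom == 0.0:
            continue
        t = ((ax - x0) * ey - (ay - y0) * ex) / denom
        u = ((ax - x0) * dy - (ay - y0) * dx) / denom
        if 1e-12 < t <= 1.0 and -1e-12 <= u <= 1.0 + 1e-12 and t < best_t:
            best_t = t
            best_e = e
    return best_t, best_e


@njit(cache=True)
def _confine_move(x0, y0, jx, jy, dom, poly_x, poly_y, poly_off,
                  p_exit, rng, counters):
    """Advance a confined point by one jump, applying the exit penalty.

    The point starts inside polygon ``dom``.  If the jump crosses the
    contour, the segment is split at the crossing; with probability
    ``p_exit`` the remainder continues outside, otherwise it is reflected
    specularly about the crossed edge (repeatedly if needed).  Returns
    (x, y, domain) where domain == -2 signals "left the contour; caller
    must re-resolve membership after wrapping".
    """
    i0 = poly_off[dom]
    i1 = poly_off[dom + 1]
    cx = x0
    cy = y0
    x1 = x0 + jx
    y1 = y0 + jy
    skip = -1
    for _ in range(16):
        if _point_in_poly(x1, y1, poly_x, poly_y, i0, i1):
            return x1, y1, dom
        t, e = _first_crossing(cx, cy, x1, y1, poly_x, poly_y, i0, i1, skip)
        if e < 0:
            # started on/outside the contour without a detectable crossing
            return x1, y1, -2
        nx = cx + t * (x1 - cx)
        ny = cy + t * (y1 - cy)
        counters[C_ATT] += 1
        if rng.random() < p_exit:
            counters[C_ESC] += 1
            return x1, y1, -2
        # specular reflection of the remainder about the crossed edge
        ax = poly_x[e]
        ay = poly_y[e]
        n = e + 1 if e + 1 < i1 else i0
        ex = poly_x[n] - ax
        ey = poly_y[n] - ay
        el2 = ex * ex + ey * ey
        vx = x1 - nx
        vy = y1 - ny
        dot = (vx * ex + vy * ey) / el2
        x1 = nx + 2.0 * dot * ex - vx
        y1 = ny + 2.0 * dot * ey - vy
        cx = nx
        cy = ny
        skip = e
    return cx, cy, dom


@njit(cache=True)
def _reverse_chain(rec_i, head):
    """Reverse a chain's orientation in place; returns the new head."""
    cur = head
    new_head = head
    while cur >= 0:
        nxt = rec_i[cur, R_RIGHT]
        rec_i[cur, R_RIGHT] = rec_i[cur, R_LEFT]
        rec_i[cur, R_LEFT] = nxt
        new_head = cur
        cur = nxt
    return new_head


@njit(cache=True)
def _fire_first_order(rec_i, rec_f, lyn_i, lyn_f, syk_i, syk_f,
                      poly_x, poly_y, poly_off, poly_bb,
                      p_off_bond, p_lyn_unbind, lyn_radius,
                      p_syk_unbind, syk_radius,
                      pb_itam, pb_lyny, pb_slnk, pb_scat,
                      pb_deph_itam, pb_deph_lyn, pb_deph_syk,
                      bx, by, bz, sep, sigma_rec, rng, counters):
    n_rec = rec_i.shape[0]
    n_lyn = lyn_i.shape[0]
    n_syk = syk_i.shape[0]
    n_poly = poly_off.shape[0] - 1

    # --- trans-phosphorylation by docked kinases (adjacent receptors only)
    for l in range(n_lyn):
        r = lyn_i[l, L_REC]
        if r < 0:
            continue
        act = lyn_i[l, L_Y397]
        for side in range(2):
            nb = rec_i[r, R_LEFT] if side == 0 else rec_i[r, R_RIGHT]
            if nb < 0:
                continue
            s = rec_i[nb, R_IGA]
            if s < 2 and rng.random() < pb_itam[act, s]:
                rec_i[nb, R_IGA] = s + 1
                counters[C_PHOS] += 1
            s = rec_i[nb, R_IGB]
            if s < 2 and rng.random() < pb_itam[act, s]:
                rec_i[nb, R_IGB] = s + 1
                counters[C_PHOS] += 1
            for site in range(2):
                kk = rec_i[nb, R_AK] if site == 0 else rec_i[nb, R_BK]
                kid = rec_i[nb, R_AID] if site == 0 else rec_i[nb, R_BID]
                if kk == OCC_LYN:
                    if lyn_i[kid, L_Y397] == 0 and rng.random() < pb_lyny[act]:
                        lyn_i[kid, L_Y397] = 1
                        counters[C_PHOS] += 1
                elif kk == OCC_SYK:
                    if syk_i[kid, S_LNK] == 0 and rng.random() < pb_slnk[act]:
                        syk_i[kid, S_LNK] = 1
                        counters[C_PHOS] += 1
    for s_ in range(n_syk):
        r = syk_i[s_, S_REC]
        if r < 0:
            continue
        act = syk_i[s_, S_CAT]
        for side in range(2):
            nb = rec_i[r, R_LEFT] if side == 0 else rec_i[r, R_RIGHT]
            if nb < 0:
                continue
            for site in range(2):
                kk = rec_i[nb, R_AK] if site == 0 else rec_i[nb, R_BK]
                kid = rec_i[nb, R_AID] if site == 0 else rec_i[nb, R_BID]
                if kk == OCC_SYK:
                    if syk_i[kid, S_CAT] == 0 and rng.random() < pb_scat[act]:
                        syk_i[kid, S_CAT] = 1
                        counters[C_PHOS] += 1

    # --- dephosphorylation (fires regardless of site occupancy)
    for r in range(n_rec):
        s = rec_i[r, R_IGA]
        if s > 0 and rng.random() < pb_deph_itam[s]:
            rec_i[r, R_IGA] = s - 1
            counters[C_DEPH] += 1
        s = rec_i[r, R_IGB]
        if s > 0 and rng.random() < pb_deph_itam[s]:
            rec_i[r, R_IGB] = s - 1
            counters[C_DEPH] += 1
    for l in range(n_lyn):
        if lyn_i[l, L_Y397] == 1 and rng.random() < pb_deph_lyn:
            lyn_i[l, L_Y397] = 0
            counters[C_DEPH] += 1
    for s_ in range(n_syk):
        if syk_i[s_, S_CAT] == 1 and rng.random() < pb_deph_syk:
            syk_i[s_, S_CAT] = 0
            counters[C_DEPH] += 1
        if syk_i[s_, S_LNK] == 1 and rng.random() < pb_deph_syk:
            syk_i[s_, S_LNK] = 0
            counters[C_DEPH] += 1

    # --- kinase unbinding; released molecule placed sep x binding radius away
    for l in range(n_lyn):
        r = lyn_i[l, L_REC]
        if r < 0:
            continue
        site = lyn_i[l, L_SITE]
        st = rec_i[r, R_IGA] if site == 0 else rec_i[r, R_IGB]
        if rng.random() < p_lyn_unbind[site, st]:
            if site == 0:
                rec_i[r, R_AK] = OCC_NONE
                rec_i[r, R_AID] = -1
            else:
                rec_i[r, R_BK] = OCC_NONE
                rec_i[r, R_BID] = -1
            lyn_i[l, L_REC] = -1
            lyn_i[l, L_SITE] = -1
            lyn_i[l, L_MODE] = 0
            theta = rng.random() * TWO_PI
            d = sep * lyn_radius[site, st]
            lyn_f[l, 0] = _wrap1(rec_f[r, 0] + d * math.cos(theta), bx)
            lyn_f[l, 1] = _wrap1(rec_f[r, 1] + d * math.sin(theta), by)
            counters[C_LUNB] += 1
    for s_ in range(n_syk):
        r = syk_i[s_, S_REC]
        if r < 0:
            continue
        site = syk_i[s_, S_SITE]
        st = rec_i[r, R_IGA] if site == 0 else rec_i[r, R_IGB]
        if rng.random() < p_syk_unbind[site, st]:
            if site == 0:
                rec_i[r, R_AK] = OCC_NONE
                rec_i[r, R_AID] = -1
            else:
                rec_i[r, R_BK] = OCC_NONE
                rec_i[r, R_BID] = -1
            syk_i[s_, S_REC] = -1
            syk_i[s_, S_SITE] = -1
            gx = rng.standard_normal()
            gy = rng.standard_normal()
            gz = rng.standard_normal()
            norm = math.sqrt(gx * gx + gy * gy + gz * gz)
            if norm == 0.0:
                gx, gy, gz, norm = 0.0, 0.0, 1.0, 1.0
            d = sep * syk_radius[site, st]
            syk_f[s_, 0] = _wrap1(rec_f[r, 0] + d * gx / norm, bx)
            syk_f[s_, 1] = _wrap1(rec_f[r, 1] + d * gy / norm, by)
            syk_f[s_, 2] = _fold(abs(d * gz / norm), bz)
            counters[C_SUNB] += 1

    # --- receptor-receptor bond breaking
    half_sep = 0.5 * sep * sigma_rec
    for r in range(n_rec):
        j = rec_i[r, R_RIGHT]
        if j < 0:
            continue
        counters[C_BOND_OPP] += 1
        if rng.random() < p_off_bond:
            counters[C_SPLIT] += 1
            rec_i[r, R_RIGHT] = -1
            rec_i[j, R_LEFT] = -1
            theta = rng.random() * TWO_PI
            ux = math.cos(theta)
            uy = math.sin(theta)
            # fragment containing r moves one way, fragment with j the other
            xa = _wrap1(rec_f[r, 0] - half_sep * ux, bx)
            ya = _wrap1(rec_f[r, 1] - half_sep * uy, by)
            xb = _wrap1(rec_f[j, 0] + half_sep * ux, bx)
            yb = _wrap1(rec_f[j, 1] + half_sep * uy, by)
            da = _find_domain(xa, ya, poly_x, poly_y, poly_off, poly_bb) \
                if n_poly > 0 else -1
            db = _find_domain(xb, yb, poly_x, poly_y, poly_off, poly_bb) \
                if n_poly > 0 else -1
            cur = r
            while cur >= 0:
                rec_f[cur, 0] = xa
                rec_f[cur, 1] = ya
                rec_i[cur, R_DOM] = da
                cur = rec_i[cur, R_LEFT]
            cur = j
            while cur >= 0:
                rec_f[cur, 0] = xb
                rec_f[cur, 1] = yb
                rec_i[cur, R_DOM] = db
                cur = rec_i[cur, R_RIGHT]


@njit(cache=True)
def _propagate(rec_i, rec_f, lyn_i, lyn_f, syk_i, syk_f,
               poly_x, poly_y, poly_off, poly_bb,
               bx, by, bz, d_rec, d_lyn, d_syk, dt, p_exit,
               members, rng, counters):
    n_rec = rec_i.shape[0]
    n_lyn = lyn_i.shape[0]
    n_syk = syk_i.shape[0]
    n_poly = poly_off.shape[0] - 1
    # chains: one jump per chain scaled by D_rec / M; receptors observe domains
    for r in range(n_rec):
        if rec_i[r, R_LEFT] != -1:
            continue
        m = 0
        cur = r
        while cur >= 0:
            members[m] = cur
            m += 1
            cur = rec_i[cur, R_RIGHT]
        rms = math.sqrt(2.0 * (d_rec / m) * dt)
        jx = rms * rng.standard_normal()
        jy = rms * rng.standard_normal()
        x0 = rec_f[r, 0]
        y0 = rec_f[r, 1]
        dom = rec_i[r, R_DOM]
        if n_poly > 0 and dom >= 0:
            x1, y1, nd = _confine_move(x0, y0, jx, jy, dom,
                                       poly_x, poly_y, poly_off,
                                       p_exit, rng, counters)
        else:
            x1 = x0 + jx
            y1 = y0 + jy
            nd = -2
        x1 = _wrap1(x1, bx)
        y1 = _wrap1(y1, by)
        if nd == -2:
            nd = _find_domain(x1, y1, poly_x, poly_y, poly_off, poly_bb) \
                if n_poly > 0 else -1
        for k in range(m):
            rr = members[k]
            rec_f[rr, 0] = x1
            rec_f[rr, 1] = y1
            rec_i[rr, R_DOM] = nd
    # free Lyn: 2-D, periodic, ignores domains
    rms_l = math.sqrt(2.0 * d_lyn * dt)
    for l in range(n_lyn):
        if lyn_i[l, L_REC] >= 0:
            lyn_f[l, 0] = rec_f[lyn_i[l, L_REC], 0]
            lyn_f[l, 1] = rec_f[lyn_i[l, L_REC], 1]
            continue
        lyn_f[l, 0] = _wrap1(lyn_f[l, 0] + rms_l * rng.standard_normal(), bx)
        lyn_f[l, 1] = _wrap1(lyn_f[l, 1] + rms_l * rng.standard_normal(), by)
    # free Syk: 3-D, periodic in x/y, reflective in z; bound Syk at membrane
    rms_s = math.sqrt(2.0 * d_syk * dt)
    for s_ in range(n_syk):
        if syk_i[s_, S_REC] >= 0:
            syk_f[s_, 0] = rec_f[syk_i[s_, S_REC], 0]
            syk_f[s_, 1] = rec_f[syk_i[s_, S_REC], 1]
            syk_f[s_, 2] = 0.0
            continue
        syk_f[s_, 0] = _wrap1(syk_f[s_, 0] + rms_s * rng.standard_normal(), bx)
        syk_f[s_, 1] = _wrap1(syk_f[s_, 1] + rms_s * rng.standard_normal(), by)
        syk_f[s_, 2] = _fold(syk_f[s_, 2] + rms_s * rng.standard_normal(), bz)


@njit(cache=True)
def _detect_and_bind(rec_i, rec_f, lyn_i, lyn_f, syk_i, syk_f,
                     poly_x, poly_y, poly_off, poly_bb,
                     sigma_rec, lyn_mode, lyn_radius2, syk_radius2, syk_rmax2,
                     bx, by, heads, cand, used_rec, used_lyn, used_syk,
                     rng, counters):
    n_rec = rec_i.shape[0]
    n_lyn = lyn_i.shape[0]
    n_syk = syk_i.shape[0]
    n_poly = poly_off.shape[0] - 1
    maxc = cand.shape[0]
    sigma2 = sigma_rec * sigma_rec

    nh = 0
    for r in range(n_rec):
        if rec_i[r, R_LEFT] == -1:
            heads[nh] = r
            nh += 1
    counters[C_PAIR_OPP] += nh * (nh - 1) // 2

    ncand = 0
    # (i) chain-chain encounters
    if sigma2 > 0.0:
        for i in range(nh):
            a = heads[i]
            xa = rec_f[a, 0]
            ya = rec_f[a, 1]
            for j in range(i + 1, nh):
                b = heads[j]
                dx = _minimg(rec_f[b, 0] - xa, bx)
                if dx * dx >= sigma2:
                    continue
                dy = _minimg(rec_f[b, 1] - ya, by)
                if dx * dx + dy * dy < sigma2:
                    if ncand < maxc:
                        cand[ncand, 0] = 0
                        cand[ncand, 1] = a
                        cand[ncand, 2] = b
                        cand[ncand, 3] = -1
                        ncand += 1
                    else:
                        counters[C_CAND_OVF] += 1
    # (ii) free Lyn against empty ITAM sites (2-D distance to chain point)
    for l in range(n_lyn):
        if lyn_i[l, L_REC] >= 0:
            continue
        xl = lyn_f[l, 0]
        yl = lyn_f[l, 1]
        for r in range(n_rec):
            dx = _minimg(rec_f[r, 0] - xl, bx)
            dy = _minimg(rec_f[r, 1] - yl, by)
            d2 = dx * dx + dy * dy
            for site in range(2):
                kk = rec_i[r, R_AK] if site == 0 else rec_i[r, R_BK]
                if kk != OCC_NONE:
                    continue
                st = rec_i[r, R_IGA] if site == 0 else rec_i[r, R_IGB]
                if lyn_mode[site, st] > 0 and d2 < lyn_radius2[site, st]:
                    if ncand < maxc:
                        cand[ncand, 0] = 1
                        cand[ncand, 1] = l
                        cand[ncand, 2] = r
                        cand[ncand, 3] = site
                        ncand += 1
                    else:
                        counters[C_CAND_OVF] += 1
    # (iii) free Syk against phosphorylated empty ITAM sites (3-D distance)
    for s_ in range(n_syk):
        if syk_i[s_, S_REC] >= 0:
            continue
        z = syk_f[s_, 2]
        z2 = z * z
        if z2 >= syk_rmax2:
            continue
        xs = syk_f[s_, 0]
        ys = syk_f[s_, 1]
        for r in range(n_rec):
            dx = _minimg(rec_f[r, 0] - xs, bx)
            dy = _minimg(rec_f[r, 1] - ys, by)
            d2 = dx * dx + dy * dy + z2
            if d2 >= syk_rmax2:
                continue
            for site in range(2):
                kk = rec_i[r, R_AK] if site == 0 else rec_i[r, R_BK]
                if kk != OCC_NONE:
                    continue
                st = rec_i[r, R_IGA] if site == 0 else rec_i[r, R_IGB]
                if st >= 1 and d2 < syk_radius2[site, st]:
                    if ncand < maxc:
                        cand[ncand, 0] = 2
                        cand[ncand, 1] = s_
                        cand[ncand, 2] = r
                        cand[ncand, 3] = site
                        ncand += 1
                    else:
                        counters[C_CAND_OVF] += 1

    if ncand == 0:
        return

    # uniform shuffle of the candidate list (Fisher-Yates)
    for i in range(ncand - 1, 0, -1):
        j = rng.integers(0, i + 1)
        for c in range(4):
            tmp = cand[i, c]
            cand[i, c] = cand[j, c]
            cand[j, c] = tmp

    for r in range(n_rec):
        used_rec[r] = False
    for l in range(n_lyn):
        used_lyn[l] = False
    for s_ in range(n_syk):
        used_syk[s_] = False

    for c in range(ncand):
        typ = cand[c, 0]
        if typ == 0:
            a = cand[c, 1]
            b = cand[c, 2]
            ha = a
            while rec_i[ha, R_LEFT] >= 0:
                ha = rec_i[ha, R_LEFT]
            hb = b
            while rec_i[hb, R_LEFT] >= 0:
                hb = rec_i[hb, R_LEFT]
            if ha == hb:
                continue  # already the same chain: a ring would form
            ok = True
            ta = ha
            cur = ha
            while cur >= 0:
                if used_rec[cur]:
                    ok = False
                    break
                ta = cur
                cur = rec_i[cur, R_RIGHT]
            if not ok:
                continue
            tb = hb
            cur = hb
            while cur >= 0:
                if used_rec[cur]:
                    ok = False
                    break
                tb = cur
                cur = rec_i[cur, R_RIGHT]
            if not ok:
                continue
            # randomize end orientation (adjacency is symmetric)
            if rng.random() < 0.5:
                nh_ = _reverse_chain(rec_i, ha)
                ta = ha
                ha = nh_
            if rng.random() < 0.5:
                nh_ = _reverse_chain(rec_i, hb)
                tb = hb
                hb = nh_
            rec_i[ta, R_RIGHT] = hb
            rec_i[hb, R_LEFT] = ta
            xa = rec_f[ta, 0]
            ya = rec_f[ta, 1]
            dx = _minimg(rec_f[hb, 0] - xa, bx)
            dy = _minimg(rec_f[hb, 1] - ya, by)
            xm = _wrap1(xa + 0.5 * dx, bx)
            ym = _wrap1(ya + 0.5 * dy, by)
            nd = _find_domain(xm, ym, poly_x, poly_y, poly_off, poly_bb) \
                if n_poly > 0 else -1
            cur = ha
            while cur >= 0:
                rec_f[cur, 0] = xm
                rec_f[cur, 1] = ym
                rec_i[cur, R_DOM] = nd
                used_rec[cur] = True
                cur = rec_i[cur, R_RIGHT]
            counters[C_MERGE] += 1
        elif typ == 1:
            l = cand[c, 1]
            r = cand[c, 2]
            site = cand[c, 3]
            if used_lyn[l] or used_rec[r] or lyn_i[l, L_REC] >= 0:
                continue
            kk = rec_i[r, R_AK] if site == 0 else rec_i[r, R_BK]
            if kk != OCC_NONE:
                continue
            st = rec_i[r, R_IGA] if site == 0 else rec_i[r, R_IGB]
            mode = lyn_mode[site, st]
            if mode == 0:
                continue
            if site == 0:
                rec_i[r, R_AK] = OCC_LYN
                rec_i[r, R_AID] = l
            else:
                rec_i[r, R_BK] = OCC_LYN
                rec_i[r, R_BID] = l
            lyn_i[l, L_REC] = r
            lyn_i[l, L_SITE] = site
            lyn_i[l, L_MODE] = mode
            lyn_f[l, 0] = rec_f[r, 0]
            lyn_f[l, 1] = rec_f[r, 1]
            used_lyn[l] = True
            used_rec[r] = True
            counters[C_LBIND] += 1
        else:
            s_ = cand[c, 1]
            r = cand[c, 2]
            site = cand[c, 3]
            if used_syk[s_] or used_rec[r] or syk_i[s_, S_REC] >= 0:
                continue
            kk = rec_i[r, R_AK] if site == 0 else rec_i[r, R_BK]
            if kk != OCC_NONE:
                continue
            st = rec_i[r, R_IGA] if site == 0 else rec_i[r, R_IGB]
            if st < 1:
                continue
            if site == 0:
                rec_i[r, R_AK] = OCC_SYK
                rec_i[r, R_AID] = s_
            else:
                rec_i[r, R_BK] = OCC_SYK
                rec_i[r, R_BID] = s_
            syk_i[s_, S_REC] = r
            syk_i[s_, S_SITE] = site
            syk_f[s_, 0] = rec_f[r, 0]
            syk_f[s_, 1] = rec_f[r, 1]
            syk_f[s_, 2] = 0.0
            used_syk[s_] = True
            used_rec[r] = True
            counters[C_SBIND] += 1


@njit(cache=True)
def _record(rec_i, lyn_i, syk_i, sizes_row, obs_row):
    n_rec = rec_i.shape[0]
    for m in range(sizes_row.shape[0]):
        sizes_row[m] = 0
    for k in range(N_OBS):
        obs_row[k] = 0
    for r in range(n_rec):
        if rec_i[r, R_LEFT] == -1:
            m = 0
            cur = r
            while cur >= 0:
                m += 1
                cur = rec_i[cur, R_RIGHT]
            sizes_row[m] += m  # receptor-weighted count
            obs_row[O_NCHAIN] += 1
        s = rec_i[r, R_IGA]
        if s == 1:
            obs_row[O_IGA1] += 1
        elif s == 2:
            obs_row[O_IGA2] += 1
        s = rec_i[r, R_IGB]
        if s == 1:
            obs_row[O_IGB1] += 1
        elif s == 2:
            obs_row[O_IGB2] += 1
    for l in range(lyn_i.shape[0]):
        if lyn_i[l, L_REC] >= 0:
            obs_row[O_LBND] += 1
        if lyn_i[l, L_Y397] == 1:
            obs_row[O_LACT] += 1
    for s_ in range(syk_i.shape[0]):
        if syk_i[s_, S_REC] >= 0:
            obs_row[O_SBND] += 1
        if syk_i[s_, S_CAT] == 1:
            obs_row[O_SCAT] += 1
        if syk_i[s_, S_LNK] == 1:
            obs_row[O_SLNK] += 1


@njit(cache=True)
def _step_kernel(rec_i, rec_f, lyn_i, lyn_f, syk_i, syk_f,
                 poly_x, poly_y, poly_off, poly_bb,
                 p_off_bond, p_lyn_unbind, lyn_radius, p_syk_unbind,
                 syk_radius, pb_itam, pb_lyny, pb_slnk, pb_scat,
                 pb_deph_itam, pb_deph_lyn, pb_deph_syk,
                 sigma_rec, lyn_mode, lyn_radius2, syk_radius2, syk_rmax2,
                 bx, by, bz, d_rec, d_lyn, d_syk, dt, p_exit, sep,
                 members, cand, used_rec, used_lyn, used_syk,
                 rng, counters):
    _fire_first_order(rec_i, rec_f, lyn_i, lyn_f, syk_i, syk_f,
                      poly_x, poly_y, poly_off, poly_bb,
                      p_off_bond, p_lyn_unbind, lyn_radius,
                      p_syk_unbind, syk_radius,
                      pb_itam, pb_lyny, pb_slnk, pb_scat,
                      pb_deph_itam, pb_deph_lyn, pb_deph_syk,
                      bx, by, bz, sep, sigma_rec, rng, counters)
    _propagate(rec_i, rec_f, lyn_i, lyn_f, syk_i, syk_f,
               poly_x, poly_y, poly_off, poly_bb,
               bx, by, bz, d_rec, d_lyn, d_syk, dt, p_exit,
               members, rng, counters)
    _detect_and_bind(rec_i, rec_f, lyn_i, lyn_f, syk_i, syk_f,
                     poly_x, poly_y, poly_off, poly_bb,
                     sigma_rec, lyn_mode, lyn_radius2, syk_radius2, syk_rmax2,
                     bx, by, members, cand, used_rec, used_lyn, used_syk,
                     rng, counters)


@njit(cache=True)
def _run_kernel(rec_i, rec_f, lyn_i, lyn_f, syk_i, syk_f,
                poly_x, poly_y, poly_off, poly_bb,
                p_off_bond, p_lyn_unbind, lyn_radius, p_syk_unbind,
                syk_radius, pb_itam, pb_lyny, pb_slnk, pb_scat,
                pb_deph_itam, pb_deph_lyn, pb_deph_syk,
                sigma_rec, lyn_mode, lyn_radius2, syk_radius2, syk_rmax2,
                bx, by, bz, d_rec, d_lyn, d_syk, dt, p_exit, sep,
                members, cand, used_rec, used_lyn, used_syk,
                n_steps, sample_every, sample_index, out_sizes, out_obs,
                rng, counters):
    """Advance ``n_steps`` steps, recording observables every
    ``sample_every`` steps starting from sample slot ``sample_index``.
    Returns the next free sample slot."""
    si = sample_index
    for step in range(n_steps):
        _step_kernel(rec_i, rec_f, lyn_i, lyn_f, syk_i, syk_f,
                     poly_x, poly_y, poly_off, poly_bb,
                     p_off_bond, p_lyn_unbind, lyn_radius, p_syk_unbind,
                     syk_radius, pb_itam, pb_lyny, pb_slnk, pb_scat,
                     pb_deph_itam, pb_deph_lyn, pb_deph_syk,
                     sigma_rec, lyn_mode, lyn_radius2, syk_radius2, syk_rmax2,
                     bx, by, bz, d_rec, d_lyn, d_syk, dt, p_exit, sep,
                     members, cand, used_rec, used_lyn, used_syk,
                     rng, counters)
        if sample_every > 0 and (step + 1) % sample_every == 0 \
                and si < out_sizes.shape[0]:
            _record(rec_i, lyn_i, syk_i, out_sizes[si], out_obs[si])
            si += 1
    return si
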