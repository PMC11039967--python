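"""Numba-compiled numerical core.

Everything in here operates on flat arrays packed by :mod:`sit2walk.model_core`
(`ModelArrays`) so the whole rollout loop can be jit-compiled.  Conventions:

* sagittal plane, x forward, y up, angles CCW-positive (so anterior pelvis
  tilt and lumbar flexion are negative, matching the joint-range limits of
  the objective);
* bodies stored in topological order (``parent[i] < i``); each pin-jointed
  body's frame origin sits exactly at its joint, so the rotation pivot of
  dof ``j`` is the owning body's origin;
* the mass matrix and bias forces come from a planar recursive Newton-Euler
  inverse dynamics (unit-acceleration method), which is exact for tree
  structures.
"""

import numpy as np
from numba import njit

# dof kinds
DOF_TX = 0
DOF_TY = 1
DOF_RZ = 2

# joint types
JT_FREE = 0  # 3-dof planar free joint (roots only)
JT_PIN = 1

# gait phases
PH_EARLY_STANCE = 0
PH_LATE_STANCE = 1
PH_LIFTOFF = 2
PH_SWING = 3
PH_LANDING = 4

# controller modes
MODE_STAND1 = 0
MODE_STAND2 = 1
MODE_GAIT = 2

# rollout status
ROLLOUT_OK = 0
ROLLOUT_FELL = 1
ROLLOUT_BLOWUP = 2

NH = 32  # control-rate history ring-buffer slots


@njit(cache=True)
def kinematics(nb, parent, jtype, jq, anc_p, q, qd, th, p, w, v):
    """Forward position/velocity pass. Fills th, p (origin), w, v (origin vel)."""
    for i in range(nb):
        pa = parent[i]
        if pa == -1:
            if jtype[i] == JT_FREE:
                k = jq[i]
                p[i, 0] = q[k]
                p[i, 1] = q[k + 1]
                th[i] = q[k + 2]
                v[i, 0] = qd[k]
                v[i, 1] = qd[k + 1]
                w[i] = qd[k + 2]
            else:  # pin to world; anc_p holds the world pivot
                th[i] = q[jq[i]]
                w[i] = qd[jq[i]]
                p[i, 0] = anc_p[i, 0]
                p[i, 1] = anc_p[i, 1]
                v[i, 0] = 0.0
                v[i, 1] = 0.0
        else:
            ca = np.cos(th[pa])
            sa = np.sin(th[pa])
            rx = ca * anc_p[i, 0] - sa * anc_p[i, 1]
            ry = sa * anc_p[i, 0] + ca * anc_p[i, 1]
            th[i] = th[pa] + q[jq[i]]
            w[i] = w[pa] + qd[jq[i]]
            p[i, 0] = p[pa, 0] + rx
            p[i, 1] = p[pa, 1] + ry
            v[i, 0] = v[pa, 0] - w[pa] * ry
            v[i, 1] = v[pa, 1] + w[pa] * rx


@njit(cache=True)
def invdyn(nb, ndof, parent, jtype, jq, anc_p, mass, inertia, com, grav,
           q, qd, qdd, grav_on, tau):
    """Planar recursive Newton-Euler: generalized forces for given (q, qd, qdd).

    With qdd=0 this yields the bias (Coriolis/centrifugal + gravity when
    grav_on); with qd=0, gravity off and unit qdd it yields mass-matrix columns.
    """
    th = np.empty(nb)
    p = np.empty((nb, 2))
    w = np.empty(nb)
    v = np.empty((nb, 2))
    kinematics(nb, parent, jtype, jq, anc_p, q, qd, th, p, w, v)

    a = np.empty((nb, 2))   # body-origin linear acceleration
    al = np.empty(nb)       # angular acceleration
    fx = np.empty(nb)       # accumulated subtree force
    fy = np.empty(nb)
    nz = np.empty(nb)       # accumulated subtree moment about body origin

    for i in range(nb):
        pa = parent[i]
        if pa == -1:
            if jtype[i] == JT_FREE:
                k = jq[i]
                a[i, 0] = qdd[k]
                a[i, 1] = qdd[k + 1]
                al[i] = qdd[k + 2]
            else:
                a[i, 0] = 0.0
                a[i, 1] = 0.0
                al[i] = qdd[jq[i]]
        else:
            rx = p[i, 0] - p[pa, 0]
            ry = p[i, 1] - p[pa, 1]
            a[i, 0] = a[pa, 0] - al[pa] * ry - w[pa] * w[pa] * rx
            a[i, 1] = a[pa, 1] + al[pa] * rx - w[pa] * w[pa] * ry
            al[i] = al[pa] + qdd[jq[i]]

        # COM acceleration and net inertial force/moment
        ca = np.cos(th[i])
        sa = np.sin(th[i])
        rcx = ca * com[i, 0] - sa * com[i, 1]
        rcy = sa * com[i, 0] + ca * com[i, 1]
        acx = a[i, 0] - al[i] * rcy - w[i] * w[i] * rcx
        acy = a[i, 1] + al[i] * rcx - w[i] * w[i] * rcy
        Fx = mass[i] * acx
        Fy = mass[i] * acy
        if grav_on:
            Fy += mass[i] * grav
        fx[i] = Fx
        fy[i] = Fy
        nz[i] = inertia[i] * al[i] + rcx * Fy - rcy * Fx

    for i in range(ndof):
        tau[i] = 0.0
    for i in range(nb - 1, -1, -1):
        pa = parent[i]
        if jtype[i] == JT_FREE:
            k = jq[i]
            tau[k] = fx[i]
            tau[k + 1] = fy[i]
            tau[k + 2] = nz[i]
        else:
            tau[jq[i]] = nz[i]
        if pa >= 0:
            fx[pa] += fx[i]
            fy[pa] += fy[i]
            nz[pa] += nz[i] + (p[i, 0] - p[pa, 0]) * fy[i] - (p[i, 1] - p[pa, 1]) * fx[i]


@njit(cache=True)
def forward_dynamics(nb, ndof, parent, jtype, jq, anc_p, mass, inertia, com, grav,
                     q, qd, q_applied, free_mask, qdd_out):
    """Solve M(q) qdd = Q_applied - bias(q, qd) on the free coordinates.

    Locked coordinates (free_mask false) are treated as prescribed at zero
    velocity/acceleration: the system is reduced before solving.
    """
    bias = np.empty(ndof)
    qd_eff = np.empty(ndof)
    for i in range(ndof):
        qd_eff[i] = qd[i] if free_mask[i] else 0.0
    qdd0 = np.zeros(ndof)
    invdyn(nb, ndof, parent, jtype, jq, anc_p, mass, inertia, com, grav,
           q, qd_eff, qdd0, True, bias)

    nf = 0
    for i in range(ndof):
        if free_mask[i]:
            nf += 1
    idx = np.empty(nf, dtype=np.int64)
    k = 0
    for i in range(ndof):
        if free_mask[i]:
            idx[k] = i
            k += 1

    M = np.empty((nf, nf))
    qd0 = np.zeros(ndof)
    col = np.empty(ndof)
    ek = np.zeros(ndof)
    for jj in range(nf):
        ek[idx[jj]] = 1.0
        invdyn(nb, ndof, parent, jtype, jq, anc_p, mass, inertia, com, grav,
               q, qd0, ek, False, col)
        ek[idx[jj]] = 0.0
        for ii in range(nf):
            M[ii, jj] = col[idx[ii]]

    rhs = np.empty(nf)
    for ii in range(nf):
        rhs[ii] = q_applied[idx[ii]] - bias[idx[ii]]
    sol = np.linalg.solve(M, rhs)
    for i in range(ndof):
        qdd_out[i] = 0.0
    for ii in range(nf):
        qdd_out[idx[ii]] = sol[ii]


@njit(cache=True)
def point_world(th, p, b, lx, ly):
    ca = np.cos(th[b])
    sa = np.sin(th[b])
    return p[b, 0] + ca * lx - sa * ly, p[b, 1] + sa * lx + ca * ly


@njit(cache=True)
def point_jac_col(ancm, dof_kind, dof_body, p, b, px, py, j):
    """Column j of the world-position Jacobian of point (px,py) on body b."""
    if not ancm[b, j]:
        return 0.0, 0.0
    k = dof_kind[j]
    if k == DOF_TX:
        return 1.0, 0.0
    if k == DOF_TY:
        return 0.0, 1.0
    ob = dof_body[j]
    return -(py - p[ob, 1]), (px - p[ob, 0])


@njit(cache=True)
def muscle_geometry(nm, ndof, th, p, ancm, dof_kind, dof_body,
                    mp_body, mp_loc, mp_n, L, dLdq):
    """MTU path lengths and length gradients dL/dq for all muscles."""
    for m in range(nm):
        L[m] = 0.0
        for j in range(ndof):
            dLdq[m, j] = 0.0
        for s in range(mp_n[m] - 1):
            bA = mp_body[m, s]
            bB = mp_body[m, s + 1]
            ax, ay = point_world(th, p, bA, mp_loc[m, s, 0], mp_loc[m, s, 1])
            bx, by = point_world(th, p, bB, mp_loc[m, s + 1, 0], mp_loc[m, s + 1, 1])
            dx = bx - ax
            dy = by - ay
            ls = np.sqrt(dx * dx + dy * dy)
            if ls < 1e-9:
                continue
            L[m] += ls
            ux = dx / ls
            uy = dy / ls
            for j in range(ndof):
                if ancm[bA, j] or ancm[bB, j]:
                    jbx, jby = point_jac_col(ancm, dof_kind, dof_body, p, bB, bx, by, j)
                    jax, jay = point_jac_col(ancm, dof_kind, dof_body, p, bA, ax, ay, j)
                    dLdq[m, j] += ux * (jbx - jax) + uy * (jby - jay)


@njit(cache=True)
def hill_force(fmax, lopt, lslack, vmax, a, L, vL, hp):
    """Rigid-tendon Hill MTU force.

    hp = [fl_width, hill_shape, ecc_plateau, ecc_rate, pas_kpe, pas_e0, fiber_floor]
    Returns (F, lnorm, vnorm, f_L, f_V, f_pas).
    """
    lf = L - lslack
    floor = hp[6] * lopt
    if lf < floor:
        lf = floor
    ln = lf / lopt
    vn = vL / (vmax * lopt)

    d = (ln - 1.0) / hp[0]
    fl = np.exp(-d * d)

    if vn < 0.0:
        if vn <= -1.0:
            fv = 0.0
        else:
            fv = (1.0 + vn) / (1.0 - vn / hp[1])
    else:
        fv = 1.0 + (hp[2] - 1.0) * (1.0 - np.exp(-hp[3] * vn))

    if ln > 1.0:
        fp = (np.exp(hp[4] * (ln - 1.0) / hp[5]) - 1.0) / (np.exp(hp[4]) - 1.0)
    else:
        fp = 0.0

    F = fmax * (a * fl * fv + fp)
    if F < 0.0:
        F = 0.0
    return F, ln, vn, fl, fv, fp


@njit(cache=True)
def contact_sphere_force(cx, cy, vx, vy, r, k, c, mu, target,
                         ground_y, chair_x0, chair_x1, chair_top, chair_on):
    """Hunt-Crossley normal force + regularized Coulomb friction for one sphere.

    Returns (fx, fy, fn, px, py): world force, normal magnitude, contact point.
    """
    if target == 0:
        delta = (ground_y + r) - cy
    else:
        if chair_on == 0 or cx < chair_x0 or cx > chair_x1:
            return 0.0, 0.0, 0.0, cx, cy - r
        delta = (chair_top + r) - cy
    if delta <= 0.0:
        return 0.0, 0.0, 0.0, cx, cy - r
    ddot = -vy
    fn = k * delta ** 1.5 * (1.0 + 1.5 * c * ddot)
    if fn < 0.0:
        fn = 0.0
    ft = -mu * fn * np.tanh(vx / 0.008)
    return ft, fn, fn, cx, cy - r


@njit(cache=True)
def delayed_lookup(buf, kt, nh, steps_back):
    """Linear interpolation steps_back (float, >=0) control ticks into the past."""
    s = kt - steps_back
    if s < 0.0:
        s = 0.0
    i0 = int(np.floor(s))
    frac = s - i0
    v0 = buf[i0 % nh]
    i1 = i0 + 1
    if i1 > kt:
        i1 = kt
    v1 = buf[i1 % nh]
    return (1.0 - frac) * v0 + frac * v1


@njit(cache=True)
def delayed_lookup2(buf, m, kt, nh, steps_back):
    """Same as delayed_lookup but for per-muscle 2-d ring buffers buf[nh, nm]."""
    s = kt - steps_back
    if s < 0.0:
        s = 0.0
    i0 = int(np.floor(s))
    frac = s - i0
    v0 = buf[i0 % nh, m]
    i1 = i0 + 1
    if i1 > kt:
        i1 = kt
    v1 = buf[i1 % nh, m]
    return (1.0 - frac) * v0 + frac * v1


@njit(cache=True)
def rollout(
    # --- rigid-body model ---
    nb, ndof, parent, jtype, jq, anc_p, mass, inertia, com, grav,
    ancm, dof_kind, dof_body,
    # --- muscles ---
    nm, fmax, lopt, lslack, vmax, mp_body, mp_loc, mp_n, hp,
    tau_act, tau_deact,
    # --- contact ---
    ns, sp_body, sp_off, sp_r, sp_k, sp_c, sp_mu, sp_target, sp_leg,
    ground_y, chair_x0, chair_x1, chair_top, chair_on,
    # --- passive joint limits & trunk dofs ---
    knee_dofs, knee_lo, knee_hi, knee_k, lumbar_dof, thoracic_dof,
    # --- controller (packed dense arrays; see controller.py) ---
    ctrl_on,
    st_KC, st_KL, st_LO, st_KFp, st_KFm, st_KP, st_KV, st_theta_o, st_trunk,
    g_KC, g_KL, g_LO, g_KF, g_KFm, g_KP, g_KV, g_theta_o, g_trunk,
    ant, side, delays, delay_vest,
    t_state2, t_gait, stance_thr, d_latestance, d_landing,
    # --- run setup ---
    q0, qd0, a0, free_mask, duration, dt, cdt, out_every,
    body_weight, foot_body, pelvis_ty_dof, fall_y, qd_cap,
    # --- outputs (preallocated) ---
    o_t, o_q, o_qd, o_qdd, o_u, o_a, o_F, o_ln, o_vn, o_sphf, o_sphn,
    o_trunk_tau, o_knee_lim, o_mode, o_phase,
):
    """Fixed-step semi-implicit Euler rollout of the full scene.

    Returns (n_recorded, status).
    """
    q = q0.copy()
    qd = qd0.copy()
    a = a0.copy()
    u = np.zeros(nm)
    qdd = np.zeros(ndof)
    Q = np.zeros(ndof)
    L = np.zeros(nm)
    dLdq = np.zeros((nm, ndof))
    Fm = np.zeros(nm)
    ln_arr = np.zeros(nm)
    vn_arr = np.zeros(nm)
    th = np.empty(nb)
    p = np.empty((nb, 2))
    w = np.empty(nb)
    v = np.empty((nb, 2))

    # control-rate signal histories
    Lh = np.zeros((NH, nm))
    Fh = np.zeros((NH, nm))
    TH = np.zeros(NH)
    THD = np.zeros(NH)

    leg_phase = np.empty(2, dtype=np.int64)
    leg_phase[0] = PH_EARLY_STANCE
    leg_phase[1] = PH_EARLY_STANCE
    gait_started = False
    mode = MODE_STAND1

    trunk_tau = np.zeros(2)
    knee_lim = np.zeros(2)
    trunk_set0 = 0.0
    trunk_kp0 = 0.0
    trunk_kv0 = 0.0
    trunk_set1 = 0.0
    trunk_kp1 = 0.0
    trunk_kv1 = 0.0
    leg_load = np.zeros(2)
    sph_f = np.zeros((ns, 2))
    sph_n = np.zeros(ns)

    nsteps = int(round(duration / dt))
    ctrl_every = max(1, int(round(cdt / dt)))
    kt = -1  # control tick counter
    n_rec = 0
    status = ROLLOUT_OK
    pelvis_th_dof = pelvis_ty_dof + 1  # planar-free layout: x, y, tilt

    for step in range(nsteps + 1):
        t = step * dt
        kinematics(nb, parent, jtype, jq, anc_p, q, qd, th, p, w, v)
        if nm > 0:
            muscle_geometry(nm, ndof, th, p, ancm, dof_kind, dof_body,
                            mp_body, mp_loc, mp_n, L, dLdq)
        for m in range(nm):
            vL = 0.0
            for j in range(ndof):
                vL += dLdq[m, j] * qd[j]
            F, lnm, vnm, _, _, _ = hill_force(fmax[m], lopt[m], lslack[m],
                                              vmax[m], a[m], L[m], vL, hp)
            Fm[m] = F
            ln_arr[m] = lnm
            vn_arr[m] = vnm

        # ---- contact ----
        leg_load[0] = 0.0
        leg_load[1] = 0.0
        for s in range(ns):
            b = sp_body[s]
            cx, cy = point_world(th, p, b, sp_off[s, 0], sp_off[s, 1])
            rx = cx - p[b, 0]
            ry = cy - p[b, 1]
            vx = v[b, 0] - w[b] * ry
            vy = v[b, 1] + w[b] * rx
            fxs, fys, fns, pxs, pys = contact_sphere_force(
                cx, cy, vx, vy, sp_r[s], sp_k[s], sp_c[s], sp_mu[s], sp_target[s],
                ground_y, chair_x0, chair_x1, chair_top, chair_on)
            sph_f[s, 0] = fxs
            sph_f[s, 1] = fys
            sph_n[s] = fns
            if sp_leg[s] >= 0 and sp_target[s] == 0:
                leg_load[sp_leg[s]] += fns

        # ---- controller tick ----
        if ctrl_on and nm > 0 and step % ctrl_every == 0:
            kt += 1
            slot = kt % NH
            pel_th = q[pelvis_th_dof]
            pel_thd = qd[pelvis_th_dof]
            for m in range(nm):
                Lh[slot, m] = ln_arr[m]
                Fh[slot, m] = Fm[m] / fmax[m]
            TH[slot] = pel_th
            THD[slot] = pel_thd
            if kt == 0:  # pre-fill history with the initial signal values
                for hh in range(1, NH):
                    for m in range(nm):
                        Lh[hh, m] = Lh[0, m]
                        Fh[hh, m] = Fh[0, m]
                    TH[hh] = TH[0]
                    THD[hh] = THD[0]

            if t >= t_gait:
                mode = MODE_GAIT
            elif t >= t_state2:
                mode = MODE_STAND2
            else:
                mode = MODE_STAND1

            vsteps = delay_vest / cdt
            th_d = delayed_lookup(TH, kt, NH, vsteps)
            thd_d = delayed_lookup(THD, kt, NH, vsteps)

            if mode != MODE_GAIT:
                st = mode
                for m in range(nm):
                    dstep = delays[m] / cdt
                    Ld = delayed_lookup2(Lh, m, kt, NH, dstep)
                    Fs = delayed_lookup2(Fh, m, kt, NH, dstep)
                    Fa = delayed_lookup2(Fh, ant[m], kt, NH, dstep)
                    ex = st_KC[st, m]
                    dL_off = Ld - st_LO[st, m]
                    if dL_off > 0.0:
                        ex += st_KL[st, m] * dL_off
                    ex += st_KFp[st, m] * Fs - st_KFm[st, m] * Fa
                    ex += st_KP[st, m] * (th_d - st_theta_o[st]) + st_KV[st, m] * thd_d
                    if ex < 0.0:
                        ex = 0.0
                    if ex > 1.0:
                        ex = 1.0
                    u[m] = ex
                trunk_set0 = st_trunk[st, 0, 0]
                trunk_kp0 = st_trunk[st, 0, 1]
                trunk_kv0 = st_trunk[st, 0, 2]
                trunk_set1 = st_trunk[st, 1, 0]
                trunk_kp1 = st_trunk[st, 1, 1]
                trunk_kv1 = st_trunk[st, 1, 2]
            else:
                if not gait_started:
                    gait_started = True
                    leg_phase[0] = PH_LIFTOFF       # stepping (left) leg swings first
                    leg_phase[1] = PH_EARLY_STANCE  # stance (right) leg
                # per-leg finite-state machine
                for leg in range(2):
                    other = 1 - leg
                    lf = leg_load[leg] / body_weight
                    lof = leg_load[other] / body_weight
                    ank_x = p[foot_body[leg], 0]
                    pel_x = p[0, 0]
                    ph = leg_phase[leg]
                    if ph == PH_EARLY_STANCE:
                        if pel_x - ank_x > d_latestance:
                            leg_phase[leg] = PH_LATE_STANCE
                    elif ph == PH_LATE_STANCE:
                        if lof >= stance_thr:
                            leg_phase[leg] = PH_LIFTOFF
                    elif ph == PH_LIFTOFF:
                        if lf < stance_thr:
                            leg_phase[leg] = PH_SWING
                    elif ph == PH_SWING:
                        if ank_x - pel_x > d_landing:
                            leg_phase[leg] = PH_LANDING
                    else:  # PH_LANDING
                        if lf >= stance_thr:
                            leg_phase[leg] = PH_EARLY_STANCE
                for m in range(nm):
                    ph = leg_phase[side[m]]
                    dstep = delays[m] / cdt
                    Ld = delayed_lookup2(Lh, m, kt, NH, dstep)
                    Fs = delayed_lookup2(Fh, m, kt, NH, dstep)
                    Fa = delayed_lookup2(Fh, ant[m], kt, NH, dstep)
                    ex = g_KC[ph, m]
                    dL_off = Ld - g_LO[ph, m]
                    if dL_off > 0.0:
                        ex += g_KL[ph, m] * dL_off
                    ex += g_KF[ph, m] * Fs - g_KFm[ph, m] * Fa
                    if ph == PH_EARLY_STANCE or ph == PH_LATE_STANCE:
                        ex += g_KP[ph, m] * (th_d - g_theta_o[0]) + g_KV[ph, m] * thd_d
                    if ex < 0.0:
                        ex = 0.0
                    if ex > 1.0:
                        ex = 1.0
                    u[m] = ex
                trunk_set0 = g_trunk[0, 0]
                trunk_kp0 = g_trunk[0, 1]
                trunk_kv0 = g_trunk[0, 2]
                trunk_set1 = g_trunk[1, 0]
                trunk_kp1 = g_trunk[1, 1]
                trunk_kv1 = g_trunk[1, 2]
        # ---- assemble generalized forces ----
        for j in range(ndof):
            Q[j] = 0.0
        for m in range(nm):
            for j in range(ndof):
                if dLdq[m, j] != 0.0:
                    Q[j] -= Fm[m] * dLdq[m, j]
        for s in range(ns):
            if sph_n[s] > 0.0:
                b = sp_body[s]
                cx, cy = point_world(th, p, b, sp_off[s, 0], sp_off[s, 1])
                pxs = cx
                pys = cy - sp_r[s]
                for j in range(ndof):
                    jx, jy = point_jac_col(ancm, dof_kind, dof_body, p, b, pxs, pys, j)
                    if jx != 0.0 or jy != 0.0:
                        Q[j] += jx * sph_f[s, 0] + jy * sph_f[s, 1]
        # trunk PD torques
        if ctrl_on and lumbar_dof >= 0:
            tl = trunk_kp0 * (trunk_set0 - q[lumbar_dof]) - trunk_kv0 * qd[lumbar_dof]
            tt = trunk_kp1 * (trunk_set1 - q[thoracic_dof]) - trunk_kv1 * qd[thoracic_dof]
            trunk_tau[0] = tl
            trunk_tau[1] = tt
            Q[lumbar_dof] += tl
            Q[thoracic_dof] += tt
        # knee passive limit springs
        for kk in range(2):
            kd = knee_dofs[kk]
            knee_lim[kk] = 0.0
            if kd >= 0:
                qk = q[kd]
                if qk > knee_hi:
                    tlim = -knee_k * (qk - knee_hi)
                elif qk < knee_lo:
                    tlim = -knee_k * (qk - knee_lo)
                else:
                    tlim = 0.0
                knee_lim[kk] = np.abs(tlim)
                Q[kd] += tlim

        forward_dynamics(nb, ndof, parent, jtype, jq, anc_p, mass, inertia,
                         com, grav, q, qd, Q, free_mask, qdd)

        # ---- record ----
        if step % out_every == 0:
            o_t[n_rec] = t
            for j in range(ndof):
                o_q[n_rec, j] = q[j]
                o_qd[n_rec, j] = qd[j]
                o_qdd[n_rec, j] = qdd[j]
            for m in range(nm):
                o_u[n_rec, m] = u[m]
                o_a[n_rec, m] = a[m]
                o_F[n_rec, m] = Fm[m]
                o_ln[n_rec, m] = ln_arr[m]
                o_vn[n_rec, m] = vn_arr[m]
            for s in range(ns):
                o_sphf[n_rec, s, 0] = sph_f[s, 0]
                o_sphf[n_rec, s, 1] = sph_f[s, 1]
                o_sphn[n_rec, s] = sph_n[s]
            o_trunk_tau[n_rec, 0] = trunk_tau[0]
            o_trunk_tau[n_rec, 1] = trunk_tau[1]
            o_knee_lim[n_rec, 0] = knee_lim[0]
            o_knee_lim[n_rec, 1] = knee_lim[1]
            o_mode[n_rec] = mode
            o_phase[n_rec, 0] = leg_phase[0]
            o_phase[n_rec, 1] = leg_phase[1]
            n_rec += 1

        if step == nsteps:
            break

        # ---- integrate (semi-implicit Euler) ----
        for m in range(nm):
            tau = tau_act if u[m] > a[m] else tau_deact
            am = u[m] + (a[m] - u[m]) * np.exp(-dt / tau)
            if am < 0.0:
                am = 0.0
            if am > 1.0:
                am = 1.0
            a[m] = am
        for j in range(ndof):
            if free_mask[j]:
                qd[j] += qdd[j] * dt
                q[j] += qd[j] * dt

        # ---- failure detection ----
        if pelvis_ty_dof >= 0 and q[pelvis_ty_dof] < fall_y:
            status = ROLLOUT_FELL
            break
        bad = False
        for j in range(ndof):
            if np.abs(qd[j]) > qd_cap or not np.isfinite(q[j]):
                bad = True
        if bad:
            status = ROLLOUT_BLOWUP
            break

    return n_rec, status
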