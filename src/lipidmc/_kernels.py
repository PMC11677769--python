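"""Compiled inner loops: pair energies and the Metropolis sweep driver.

Particle layout is flat arrays with dipoles first: indices ``0..n_dip-1``
are headgroup dipoles (two opposite point charges of magnitude ``q[i]`` at
``pos[i] +/- (ax[i], ay[i])`` where (ax, ay) = arm * (cos a, sin a)), the
remaining indices are dopants (a single point charge ``q[i]``).  Energies
are in kB*T, lengths in nm, charges in elementary charges.

The Coulomb term of every point-charge pair is ``A*q1*q2/max(r, r_soft)``
where ``A`` already contains 1/(4 pi eps0 epsr) in kBT*nm units and
``r_soft`` is a finite charge-site size that keeps opposite point charges
from collapsing (the Lennard-Jones term acts on center-center distance
only and cannot protect the end sites).  The LJ term is
``4*eps*[(s/d)^12 - (s/d)^6]`` on the center-center distance with
``s = (sig_i + sig_j)/2``.

``rc2`` truncates dipole-dipole pairs only (their far field decays as
r^-3); pairs involving a dopant are always evaluated in full because the
monopole 1/r tail is long-ranged.

A center-center distance below the hard-core floor is reported as an
overlap (``OVERLAP_ENERGY``); the Metropolis driver treats it as an
automatic rejection.
"""

import math

import numpy as np
from numba import njit

#: sentinel energy for a hard-core overlap; any dE >= this is auto-rejected
OVERLAP_ENERGY = 1.0e30

_TWO_PI = 2.0 * math.pi


@njit(cache=True, fastmath=True, inline="always")
def _inv_r(dx, dy, soft):
    r = math.sqrt(dx * dx + dy * dy)
    if r < soft:
        r = soft
    return 1.0 / r


@njit(cache=True, fastmath=True, inline="always")
def _pair_u(dx, dy, d2, axi, ayi, qi, sigi, i_dip,
            axj, ayj, qj, sigj, j_dip, A, eps, soft):
    """Coulomb + LJ energy of one pair; center separation (dx, dy), d2 its
    squared norm (already floor/cutoff checked by the caller)."""
    u = 0.0
    if eps > 0.0:
        s = 0.5 * (sigi + sigj)
        sr2 = s * s / d2
        sr6 = sr2 * sr2 * sr2
        u = 4.0 * eps * (sr6 * sr6 - sr6)
    if A != 0.0 and qi != 0.0 and qj != 0.0:
        uc = 0.0
        if i_dip and j_dip:
            # sign of each term = product of the interacting end charges
            uc += _inv_r(dx + axj - axi, dy + ayj - ayi, soft)  # (+,+)
            uc += _inv_r(dx - axj + axi, dy - ayj + ayi, soft)  # (-,-)
            uc -= _inv_r(dx - axj - axi, dy - ayj - ayi, soft)  # (+,-)
            uc -= _inv_r(dx + axj + axi, dy + ayj + ayi, soft)  # (-,+)
        elif i_dip:
            uc += _inv_r(dx - axi, dy - ayi, soft)  # dopant vs + end
            uc -= _inv_r(dx + axi, dy + ayi, soft)  # dopant vs - end
        elif j_dip:
            uc += _inv_r(dx + axj, dy + ayj, soft)
            uc -= _inv_r(dx - axj, dy - ayj, soft)
        else:
            uc = _inv_r(dx, dy, soft)
        u += A * qi * qj * uc
    return u


@njit(cache=True, fastmath=True)
def pair_energy(xi, yi, ai, qi, armi, sigi, i_dip,
                xj, yj, aj, qj, armj, sigj, j_dip,
                A, eps, floor2, soft, periodic, lx, ly, rc2):
    """Energy of one pair from raw coordinates/orientations.

    OVERLAP_ENERGY on hard-core overlap."""
    dx = xj - xi
    dy = yj - yi
    if periodic:
        dx -= lx * math.floor(dx / lx + 0.5)
        dy -= ly * math.floor(dy / ly + 0.5)
    d2 = dx * dx + dy * dy
    if d2 < floor2:
        return OVERLAP_ENERGY
    if i_dip and j_dip and d2 > rc2:
        return 0.0
    axi = armi * math.cos(ai) if i_dip else 0.0
    ayi = armi * math.sin(ai) if i_dip else 0.0
    axj = armj * math.cos(aj) if j_dip else 0.0
    ayj = armj * math.sin(aj) if j_dip else 0.0
    return _pair_u(dx, dy, d2, axi, ayi, qi, sigi, i_dip,
                   axj, ayj, qj, sigj, j_dip, A, eps, soft)


@njit(cache=True, fastmath=True)
def particle_energy(pos, ax, ay, q, sig, n_dip, i, xi, yi, axi, ayi,
                    A, eps, floor2, soft, periodic, lx, ly, rc2):
    """Interaction energy of particle ``i`` placed at (xi, yi) with arm
    vector (axi, ayi), against every other particle.  O(N)."""
    n = pos.shape[0]
    i_dip = i < n_dip
    u = 0.0
    for j in range(n):
        if j == i:
            continue
        dx = pos[j, 0] - xi
        dy = pos[j, 1] - yi
        if periodic:
            dx -= lx * math.floor(dx / lx + 0.5)
            dy -= ly * math.floor(dy / ly + 0.5)
        d2 = dx * dx + dy * dy
        if d2 < floor2:
            return OVERLAP_ENERGY
        j_dip = j < n_dip
        if i_dip and j_dip and d2 > rc2:
            continue
        u += _pair_u(dx, dy, d2, axi, ayi, q[i], sig[i], i_dip,
                     ax[j], ay[j], q[j], sig[j], j_dip, A, eps, soft)
    return u


@njit(cache=True, fastmath=True)
def move_delta(pos, ax, ay, q, sig, n_dip, i, nx, ny, nax, nay,
               A, eps, floor2, soft, periodic, lx, ly, rc2):
    """E(new placement of i) - E(current placement) in one fused pass.

    Returns OVERLAP_ENERGY if the trial position overlaps any center."""
    n = pos.shape[0]
    i_dip = i < n_dip
    xi = pos[i, 0]
    yi = pos[i, 1]
    axi = ax[i]
    ayi = ay[i]
    de = 0.0
    for j in range(n):
        if j == i:
            continue
        xj = pos[j, 0]
        yj = pos[j, 1]
        j_dip = j < n_dip
        both_dip = i_dip and j_dip

        dxn = xj - nx
        dyn = yj - ny
        dxo = xj - xi
        dyo = yj - yi
        if periodic:
            dxn -= lx * math.floor(dxn / lx + 0.5)
            dyn -= ly * math.floor(dyn / ly + 0.5)
            dxo -= lx * math.floor(dxo / lx + 0.5)
            dyo -= ly * math.floor(dyo / ly + 0.5)
        d2n = dxn * dxn + dyn * dyn
        if d2n < floor2:
            return OVERLAP_ENERGY
        d2o = dxo * dxo + dyo * dyo
        if not (both_dip and d2n > rc2):
            de += _pair_u(dxn, dyn, d2n, nax, nay, q[i], sig[i], i_dip,
                          ax[j], ay[j], q[j], sig[j], j_dip, A, eps, soft)
        if not (both_dip and d2o > rc2):
            de -= _pair_u(dxo, dyo, d2o, axi, ayi, q[i], sig[i], i_dip,
                          ax[j], ay[j], q[j], sig[j], j_dip, A, eps, soft)
    return de


@njit(cache=True, fastmath=True)
def total_energy(pos, alpha, q, arm, sig, n_dip,
                 A, eps, floor2, soft, periodic, lx, ly, rc2):
    """Energy breakdown over all unordered pairs.

    Returns (dd_coul, dp_coul, pp_coul, lj, total, oi, oj); oi/oj identify
    the first overlapping pair, -1/-1 if none."""
    n = pos.shape[0]
    ax = np.zeros(n)
    ay = np.zeros(n)
    for i in range(n_dip):
        ax[i] = arm[i] * math.cos(alpha[i])
        ay[i] = arm[i] * math.sin(alpha[i])
    dd = 0.0
    dp = 0.0
    pp = 0.0
    lj = 0.0
    for i in range(n):
        i_dip = i < n_dip
        for j in range(i + 1, n):
            j_dip = j < n_dip
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            if periodic:
                dx -= lx * math.floor(dx / lx + 0.5)
                dy -= ly * math.floor(dy / ly + 0.5)
            d2 = dx * dx + dy * dy
            if d2 < floor2:
                return 0.0, 0.0, 0.0, 0.0, OVERLAP_ENERGY, i, j
            if i_dip and j_dip and d2 > rc2:
                continue
            # split Coulomb and LJ for the breakdown
            ulj = 0.0
            if eps > 0.0:
                s = 0.5 * (sig[i] + sig[j])
                sr2 = s * s / d2
                sr6 = sr2 * sr2 * sr2
                ulj = 4.0 * eps * (sr6 * sr6 - sr6)
            lj += ulj
            uc = _pair_u(dx, dy, d2, ax[i], ay[i], q[i], sig[i], i_dip,
                         ax[j], ay[j], q[j], sig[j], j_dip,
                         A, 0.0, soft) if (A != 0.0 and q[i] != 0.0
                                           and q[j] != 0.0) else 0.0
            if i_dip and j_dip:
                dd += uc
            elif i_dip or j_dip:
                dp += uc
            else:
                pp += uc
    return dd, dp, pp, lj, dd + dp + pp + lj, -1, -1


@njit(cache=True, fastmath=True)
def _plain_total(pos, alpha, q, arm, sig, n_dip,
                 A, eps, floor2, soft, periodic, lx, ly, rc2):
    dd, dp, pp, lj, tot, oi, oj = total_energy(
        pos, alpha, q, arm, sig, n_dip, A, eps, floor2, soft,
        periodic, lx, ly, rc2)
    return tot


@njit(cache=True, fastmath=True)
def mc_run(pos, alpha, q, arm, sig, n_dip,
           A, eps, floor2, soft, periodic, lx, ly, rc2,
           x0, y0, x1, y1,
           dx_max, da_max, dopants_mobile,
           max_sweeps, window, rel_tol, seed, record_every):
    """Metropolis minimization: one attempted move per particle per sweep,
    randomized order, best-seen state tracked.

    Terminates when the best energy has improved by no more than
    ``rel_tol * |best|`` over ``window`` sweeps, or at ``max_sweeps``.
    Modifies pos/alpha in place (final sampled state).  Returns
    (best_e, best_pos, best_alpha, trace, n_trace, sweeps_run, converged,
    accepted, attempted); trace rows are (sweep, current_e, best_e).
    """
    np.random.seed(seed)
    n = pos.shape[0]

    ax = np.zeros(n)
    ay = np.zeros(n)
    for i in range(n_dip):
        ax[i] = arm[i] * math.cos(alpha[i])
        ay[i] = arm[i] * math.sin(alpha[i])

    e_cur = _plain_total(pos, alpha, q, arm, sig, n_dip,
                         A, eps, floor2, soft, periodic, lx, ly, rc2)
    best_e = e_cur
    best_pos = pos.copy()
    best_alpha = alpha.copy()

    n_rec_max = max_sweeps // record_every + 2
    trace = np.empty((n_rec_max, 3))
    trace[0, 0] = 0.0
    trace[0, 1] = e_cur
    trace[0, 2] = best_e
    n_trace = 1

    order = np.empty(n, dtype=np.int64)
    for i in range(n):
        order[i] = i

    accepted = 0
    attempted = 0
    window_best = best_e
    sweeps_run = 0
    converged = False

    for sweep in range(max_sweeps):
        # Fisher-Yates shuffle of the visiting order
        for t in range(n - 1, 0, -1):
            u = np.random.randint(0, t + 1)
            tmp = order[t]
            order[t] = order[u]
            order[u] = tmp

        for t in range(n):
            i = order[t]
            is_dip = i < n_dip
            if not is_dip and not dopants_mobile:
                continue
            nx = pos[i, 0] + (2.0 * np.random.random() - 1.0) * dx_max
            ny = pos[i, 1] + (2.0 * np.random.random() - 1.0) * dx_max
            if is_dip:
                na = (alpha[i] + (2.0 * np.random.random() - 1.0) * da_max) % _TWO_PI
                nax = arm[i] * math.cos(na)
                nay = arm[i] * math.sin(na)
            else:
                na = alpha[i]
                nax = 0.0
                nay = 0.0
            attempted += 1
            if periodic:
                nx = x0 + (nx - x0) % lx
                ny = y0 + (ny - y0) % ly
            elif nx < x0 or nx > x1 or ny < y0 or ny > y1:
                continue  # open boundary: reject moves leaving the domain
            de = move_delta(pos, ax, ay, q, sig, n_dip, i, nx, ny, nax, nay,
                            A, eps, floor2, soft, periodic, lx, ly, rc2)
            if de >= OVERLAP_ENERGY:
                continue
            if de <= 0.0 or np.random.random() < math.exp(-de):
                pos[i, 0] = nx
                pos[i, 1] = ny
                alpha[i] = na
                ax[i] = nax
                ay[i] = nay
                e_cur += de
                accepted += 1
                if e_cur < best_e:
                    best_e = e_cur
                    for m in range(n):
                        best_pos[m, 0] = pos[m, 0]
                        best_pos[m, 1] = pos[m, 1]
                        best_alpha[m] = alpha[m]

        sweeps_run = sweep + 1
        if sweeps_run % record_every == 0 and n_trace < n_rec_max:
            trace[n_trace, 0] = sweeps_run
            trace[n_trace, 1] = e_cur
            trace[n_trace, 2] = best_e
            n_trace += 1
        if sweeps_run % window == 0:
            # refresh the running total from scratch: the incremental sum
            # accumulates rounding error after huge initial-overlap relaxations
            e_cur = _plain_total(pos, alpha, q, arm, sig, n_dip,
                                 A, eps, floor2, soft, periodic, lx, ly, rc2)
            if e_cur < best_e:
                best_e = e_cur
                for m in range(n):
                    best_pos[m, 0] = pos[m, 0]
                    best_pos[m, 1] = pos[m, 1]
                    best_alpha[m] = alpha[m]
            if window_best - best_e <= rel_tol * abs(best_e):
                converged = True
                break
            window_best = best_e

    # exact energy of the best state (kills incremental drift)
    best_e = _plain_total(best_pos, best_alpha, q, arm, sig, n_dip,
                          A, eps, floor2, soft, periodic, lx, ly, rc2)
    return (best_e, best_pos, best_alpha, trace, n_trace,
            sweeps_run, converged, accepted, attempted)
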