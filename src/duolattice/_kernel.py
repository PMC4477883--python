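"""JIT-compiled inner loop of the asynchronous Monte Carlo dynamics.

One full Monte Carlo step (MCS) performs 2*L*L elementary steps: a focal
player drawn uniformly from the union of both layers imitates one of its
four neighbors with the Fermi probability 1/(1 + exp((U_x - U_y)/K)),
where each utility is the player's own accumulated payoff plus its coupling
strength times the co-located partner's payoff.  Payoffs are recomputed
from the current grids at every elementary step; cooperation counts and
partner-pair counts are maintained incrementally and written out once per
MCS.

Layout: both layers are packed into one flat array of length 2N (upper
first), the neighbor table is duplicated with an offset for the lower
layer, and the partner of site ``i`` is ``i + N`` (mod 2N).  The focal
player and the neighbor direction come from a single uniform draw over
``8N`` outcomes.  When the focal player and the chosen neighbor already
share a strategy the adoption is a guaranteed no-op, so the utility
evaluation is skipped; the trajectory distribution is unchanged.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# exponent clamp for the Fermi rule: beyond +-700 exp() would overflow and
# the probability is exactly 0 or 1 in float64 anyway
_CLAMP = 700.0


@njit(cache=True)
def run_kernel(
    s,           # int8[2N] strategies, upper layer then lower (mutated)
    a,           # float64[2N] coupling strengths, same packing (mutated if annealed)
    nbr,         # int32[2N,4] neighbor table, lower rows offset by N
    m,           # float64[2,2] row-player payoff matrix, D=0 / C=1
    K,           # Fermi noise
    n_mcs,       # number of full MCS to run
    seed,        # kernel RNG seed
    early_stop,  # stop stepping once both layers are homogeneous
    annealed,    # redraw the coupling field once per MCS
    symmetric,   # annealed redraw shares one chi per site pair
    A,           # coupling amplitude (annealed redraw only)
    fc_u,        # float64[n_mcs+1] output, index 0 prefilled by caller
    fc_l,
    f_cc,
    f_dd,
):
    """Run ``n_mcs`` full MCS in place; returns the MCS index after which
    stepping stopped (== n_mcs unless early-stopped)."""
    np.random.seed(seed)
    two_n = s.shape[0]
    N = two_n // 2

    c_u = 0
    c_l = 0
    cc = 0
    dd = 0
    for i in range(N):
        c_u += s[i]
        c_l += s[i + N]
        if s[i] == 1 and s[i + N] == 1:
            cc += 1
        elif s[i] == 0 and s[i + N] == 0:
            dd += 1

    stopped_at = n_mcs
    for t in range(1, n_mcs + 1):
        if annealed:
            for i in range(N):
                a[i] = A * (2.0 * np.random.random() - 1.0)
                if symmetric:
                    a[i + N] = a[i]
                else:
                    a[i + N] = A * (2.0 * np.random.random() - 1.0)

        for _ in range(two_n):
            r = np.random.randint(0, 4 * two_n)
            x = r >> 2
            j = nbr[x, r & 3]
            sy = s[j]
            if s[x] == sy:
                continue

            xp = x + N if x < N else x - N
            jp = j + N if j < N else j - N
            sx = s[x]
            pix = (
                m[sx, s[nbr[x, 0]]]
                + m[sx, s[nbr[x, 1]]]
                + m[sx, s[nbr[x, 2]]]
                + m[sx, s[nbr[x, 3]]]
            )
            piy = (
                m[sy, s[nbr[j, 0]]]
                + m[sy, s[nbr[j, 1]]]
                + m[sy, s[nbr[j, 2]]]
                + m[sy, s[nbr[j, 3]]]
            )
            sxp = s[xp]
            pixp = (
                m[sxp, s[nbr[xp, 0]]]
                + m[sxp, s[nbr[xp, 1]]]
                + m[sxp, s[nbr[xp, 2]]]
                + m[sxp, s[nbr[xp, 3]]]
            )
            sjp = s[jp]
            pijp = (
                m[sjp, s[nbr[jp, 0]]]
                + m[sjp, s[nbr[jp, 1]]]
                + m[sjp, s[nbr[jp, 2]]]
                + m[sjp, s[nbr[jp, 3]]]
            )
            ux = pix + a[x] * pixp
            uy = piy + a[j] * pijp

            z = (ux - uy) / K
            if z > _CLAMP:
                w = 0.0
            elif z < -_CLAMP:
                w = 1.0
            else:
                w = 1.0 / (1.0 + np.exp(z))
            if np.random.random() < w:
                s[x] = sy
                partner_c = s[xp] == 1
                if sy == 1:  # D -> C flip
                    if x < N:
                        c_u += 1
                    else:
                        c_l += 1
                    if partner_c:
                        cc += 1
                    else:
                        dd -= 1
                else:  # C -> D flip
                    if x < N:
                        c_u -= 1
                    else:
                        c_l -= 1
                    if partner_c:
                        cc -= 1
                    else:
                        dd += 1

        fc_u[t] = c_u / N
        fc_l[t] = c_l / N
        f_cc[t] = cc / N
        f_dd[t] = dd / N

        total = c_u + c_l
        if early_stop and (total == 0 or total == two_n):
            stopped_at = t
            for u in range(t + 1, n_mcs + 1):
                fc_u[u] = fc_u[t]
                fc_l[u] = fc_l[t]
                f_cc[u] = f_cc[t]
                f_dd[u] = f_dd[t]
            break

    return stopped_at
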