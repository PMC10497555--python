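"""Compiled batch kernel for large replicate ensembles.

Numba reimplementation of the event loop in :mod:`paccsim.engine`,
returning per-trial summaries only (extinction flag/time, final state and
traits, event count). The random-draw order is identical to the pure-Python
engine and numba's ``np.random`` reproduces the NumPy legacy
``RandomState`` streams, so for a given seed the two paths generate
bit-identical trajectories — a property pinned by the test suite.

Mutation acceptance is resolved as "targeted drug active and delta > 0".
Because the model has no cost of resistance, invasion fitness through the
susceptible 2N+ state is strictly increasing in an active drug's trait and
flat in an inactive one, so this coincides with a strict resident-vs-mutant
fitness comparison (validated numerically against
:func:`paccsim.rates.fitness` in the test suite).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_batch", "FLAG_FIELDS"]

#: order of the scenario flag vector passed to the kernel
FLAG_FIELDS = ("enable_pacc", "enable_resistant", "depoly_to_sensitive",
               "lambda_r_vdep", "c_r_vdep")


@njit(cache=True)
def _mutate(v1, v2, m1, m2, phi, sigma, depoly):
    # mutation only under active therapy. Division mutations target the
    # active drug's trait (uniform among active); depolyploidization
    # mutations target a uniformly chosen drug trait. Strict invasion-
    # fitness improvement through the 2N+ state reduces to: targeted drug
    # active and delta > 0 (inactive-trait mutants are neutral -> purged).
    a1 = m1 > 0.0
    a2 = m2 > 0.0
    if not (a1 or a2):
        return v1, v2
    if np.random.random() >= phi:
        return v1, v2
    if depoly or (a1 and a2):
        i = 0 if np.random.random() < 0.5 else 1
    elif a1:
        i = 0
    else:
        i = 1
    delta = np.random.normal(0.0, sigma)
    if delta > 0.0 and ((i == 0 and a1) or (i == 1 and a2)):
        if i == 0:
            v1 += delta
        else:
            v2 += delta
    return v1, v2


@njit(cache=True)
def _simulate_one(seed, n0, p0, r0, v10, v20, ends, dose1, dose2,
                  r, K, gamma, lamN, lamR_base, beta, cN, cR_base,
                  a, b, mu, zeta, phi, s1, s2,
                  enable_P, enable_R, depoly_to_N, lamR_vdep, cR_vdep):
    np.random.seed(seed)
    horizon = ends[-1]
    t = 0.0
    k = 0
    N = n0
    P = p0
    R = r0
    v1 = v10
    v2 = v20
    n_events = 0
    extinct = False
    ext_time = np.nan

    while True:
        if N + P + R == 0:
            extinct = True
            ext_time = t
            break
        if t >= horizon:
            break
        while t >= ends[k]:
            k += 1
        m1 = dose1[k]
        m2 = dose2[k]
        boundary = ends[k]

        # nine channel propensities (order fixed: birth_N, birth_R,
        # death_N, death_P, death_R, N->P, P->R, R->P, R->N).
        # expression shapes mirror paccsim.rates exactly so that the
        # float streams (and hence the RNG consumption) are bit-identical
        T = float(N + P + R)
        kill_N = m1 / (lamN + beta * v1) + m2 / (lamN + beta * v2)
        denom = 1.0 + np.exp(-2.0 * (v1 + v2))
        lamR = lamR_base / denom if lamR_vdep else lamR_base
        cR = cR_base / denom if cR_vdep else cR_base
        if enable_R:
            kill_R = m1 / (lamR + beta * v1) + m2 / (lamR + beta * v2)
        else:
            kill_R = 0.0

        rate0 = max(0.0, r * N * (K - T) / K)
        rate1 = max(0.0, r * R * (K - T) / K) if enable_R else 0.0
        rate2 = N * kill_N
        rate3 = b * P if enable_P else 0.0
        rate4 = R * kill_R
        rate5 = (gamma * N + cN * N * kill_N) if enable_P else 0.0
        rate6 = a * P if enable_P else 0.0
        rate7 = (gamma * R + cR * R * kill_R) if enable_R else 0.0
        rate8 = mu * R if enable_R else 0.0
        total = (rate0 + rate1 + rate2 + rate3 + rate4
                 + rate5 + rate6 + rate7 + rate8)

        if total <= 0.0:
            t = boundary
            continue
        dt = np.random.exponential(1.0 / total)
        if t + dt >= boundary:
            t = boundary
            continue
        t = t + dt

        u = np.random.random() * total
        n_events += 1
        if u < rate0:
            N += 1
            v1, v2 = _mutate(v1, v2, m1, m2, phi, s1, False)
        elif u < rate0 + rate1:
            R += 1
            v1, v2 = _mutate(v1, v2, m1, m2, phi, s1, False)
        elif u < rate0 + rate1 + rate2:
            N -= 1
        elif u < rate0 + rate1 + rate2 + rate3:
            P -= 1
        elif u < rate0 + rate1 + rate2 + rate3 + rate4:
            R -= 1
        elif u < rate0 + rate1 + rate2 + rate3 + rate4 + rate5:
            N -= 1
            if zeta >= 1.0 or np.random.random() < zeta:
                P += 1
        elif u < rate0 + rate1 + rate2 + rate3 + rate4 + rate5 + rate6:
            P -= 1
            if depoly_to_N:
                N += 2
            else:
                R += 2
            v1, v2 = _mutate(v1, v2, m1, m2, phi, s2, True)
        elif u < rate0 + rate1 + rate2 + rate3 + rate4 + rate5 + rate6 + rate7:
            R -= 1
            if zeta >= 1.0 or np.random.random() < zeta:
                P += 1
        else:
            R -= 1
            N += 1

    if t > horizon:
        t = horizon
    return extinct, ext_time, N, P, R, v1, v2, n_events, t


@njit(cache=True)
def simulate_batch(seeds, n0, p0, r0, v10, v20, ends, dose1, dose2,
                   r, K, gamma, lamN, lamR_base, beta, cN, cR_base,
                   a, b, mu, zeta, phi, s1, s2,
                   enable_P, enable_R, depoly_to_N, lamR_vdep, cR_vdep):
    """Run one independent trial per seed; return per-trial summary arrays."""
    n = seeds.size
    extinct = np.zeros(n, np.bool_)
    ext_time = np.full(n, np.nan)
    Nf = np.zeros(n, np.int64)
    Pf = np.zeros(n, np.int64)
    Rf = np.zeros(n, np.int64)
    v1f = np.zeros(n)
    v2f = np.zeros(n)
    nev = np.zeros(n, np.int64)
    tf = np.zeros(n)
    for j in range(n):
        res = _simulate_one(seeds[j], n0, p0, r0, v10, v20, ends, dose1, dose2,
                            r, K, gamma, lamN, lamR_base, beta, cN, cR_base,
                            a, b, mu, zeta, phi, s1, s2,
                            enable_P, enable_R, depoly_to_N, lamR_vdep, cR_vdep)
        extinct[j], ext_time[j] = res[0], res[1]
        Nf[j], Pf[j], Rf[j] = res[2], res[3], res[4]
        v1f[j], v2f[j], nev[j], tf[j] = res[5], res[6], res[7], res[8]
    return extinct, ext_time, Nf, Pf, Rf, v1f, v2f, nev, tf
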