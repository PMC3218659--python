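"""Numba kernels for the haplotype-copying (PAC) rate likelihood.

Each haplotype is modelled as an imperfect mosaic of the haplotypes seen
before it in a (seeded) ordering.  The hidden copying path switches between
template haplotypes with an exponential clock whose intensity over the
segment between adjacent SNPs is rho_per_kb * d_kb / k (k templates).
The E-step accumulates, per segment, the expected number of copying-switch
events and the total clock exposure; the M-step (in ``rates.py``) refits a
piecewise-constant rate with a per-changepoint penalty.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["accumulate_expectations", "segment_dp"]


@njit(cache=True)
def accumulate_expectations(H, d_kb, rho, counts, expo):
    """Forward-backward over every target haplotype of one ordering.

    H : (K, S) uint8 ordered haplotype matrix
    d_kb : (S-1,) inter-SNP distances in kb
    rho : (S-1,) current per-segment rates (per kb)
    counts, expo : (S-1,) accumulators (expected switch events, exposure)

    Returns the log composite likelihood of this ordering.
    """
    K, S = H.shape
    # Li & Stephens mutation parameter from the harmonic number
    a = 0.0
    for i in range(1, K):
        a += 1.0 / i
    theta = 1.0 / a if a > 0 else 1.0
    loglik = 0.0

    alpha = np.empty((S, K))
    beta = np.empty((S, K))
    scale = np.empty(S)

    for t in range(1, K):
        k = t  # number of copying templates
        mis = 0.5 * theta / (k + theta)
        mat = 1.0 - mis

        # forward, scaled
        tot = 0.0
        for s in range(k):
            em = mat if H[s, 0] == H[t, 0] else mis
            alpha[0, s] = em / k
            tot += alpha[0, s]
        scale[0] = tot
        for s in range(k):
            alpha[0, s] /= tot
        for j in range(S - 1):
            c = rho[j] * d_kb[j] / k
            pstay = np.exp(-c)
            pjump = (1.0 - pstay) / k
            tot = 0.0
            for s in range(k):
                em = mat if H[s, j + 1] == H[t, j + 1] else mis
                alpha[j + 1, s] = (pstay * alpha[j, s] + pjump) * em
                tot += alpha[j + 1, s]
            scale[j + 1] = tot
            for s in range(k):
                alpha[j + 1, s] /= tot
        for j in range(S):
            loglik += np.log(scale[j])

        # backward, scaled by the same constants
        for s in range(k):
            beta[S - 1, s] = 1.0
        for j in range(S - 2, -1, -1):
            c = rho[j] * d_kb[j] / k
            pstay = np.exp(-c)
            pjump = (1.0 - pstay) / k
            acc = 0.0
            for s in range(k):
                em = mat if H[s, j + 1] == H[t, j + 1] else mis
                acc += em * beta[j + 1, s]
            for s in range(k):
                em = mat if H[s, j + 1] == H[t, j + 1] else mis
                beta[j, s] = (pstay * em * beta[j + 1, s] + pjump * acc) / scale[j + 1]

        # posterior switch-branch probability per segment
        for j in range(S - 1):
            c = rho[j] * d_kb[j] / k
            pstay = np.exp(-c)
            pjump = (1.0 - pstay) / k
            num = 0.0
            den = 0.0
            for s in range(k):
                em = mat if H[s, j + 1] == H[t, j + 1] else mis
                b = em * beta[j + 1, s]
                num += pjump * b
                den += (pstay * alpha[j, s] + pjump) * b
            if den > 0.0:
                q = num / den
            else:
                q = 0.0
            # expected event count given the exponential clock (>= q)
            if c > 1e-12:
                q *= c / (1.0 - np.exp(-c))
            counts[j] += q
            expo[j] += d_kb[j] / k
    return loglik


@njit(cache=True)
def segment_dp(counts, expo, penalty, lam_min, lam_max):
    """Optimal-partitioning M-step.

    Maximizes sum_j [c_j log(lam_j) - lam_j w_j] - penalty * (#changepoints)
    over piecewise-constant lam, exactly, by O(S^2) dynamic programming.
    Rates are clamped to [lam_min, lam_max].
    """
    S = counts.shape[0]
    cc = np.empty(S + 1)
    cw = np.empty(S + 1)
    cc[0] = 0.0
    cw[0] = 0.0
    for j in range(S):
        cc[j + 1] = cc[j] + counts[j]
        cw[j + 1] = cw[j] + expo[j]

    NEG = -1e300
    best = np.full(S + 1, NEG)
    prev = np.zeros(S + 1, dtype=np.int64)
    best[0] = 0.0
    for j in range(1, S + 1):
        for i in range(j):
            C = cc[j] - cc[i]
            W = cw[j] - cw[i]
            if W <= 0.0:
                lam = lam_min
            else:
                lam = C / W
                if lam < lam_min:
                    lam = lam_min
                elif lam > lam_max:
                    lam = lam_max
            seg = C * np.log(lam) - lam * W
            val = best[i] + seg
            if i > 0:
                val -= penalty
            if val > best[j]:
                best[j] = val
                prev[j] = i
    lam_out = np.empty(S)
    j = S
    while j > 0:
        i = prev[j]
        C = cc[j] - cc[i]
        W = cw[j] - cw[i]
        if W <= 0.0:
            lam = lam_min
        else:
            lam = C / W
            if lam < lam_min:
                lam = lam_min
            elif lam > lam_max:
                lam = lam_max
        for m in range(i, j):
            lam_out[m] = lam
        j = i
    return lam_out
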