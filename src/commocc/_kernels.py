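"""Hot inner loops of the Gibbs sweep.

The Bernoulli-logit log-likelihood is written as ``z*eta - softplus(eta)``.
Transcendentals are evaluated once per proposal with numpy's vectorized
``exp``/``log1p`` (SIMD); the masked log-likelihood sums and the in-place
accept/update passes — pure additions and branches — are JIT-compiled with
numba when available, with equivalent numpy fallbacks otherwise.

Each ``*_accept`` kernel receives the current predictor ``eta`` and its
cached softplus ``sp`` together with the proposed ``e`` and ``sp_new``,
decides acceptance per independent block element from pre-drawn log-uniforms
``logu`` and prior log-density differences ``dpri``, and overwrites the
accepted slices of ``eta``/``sp`` in place.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


def softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)), overflow-safe and vectorized."""
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


if HAVE_NUMBA:

    @njit(cache=True)
    def occ_it_accept(eta, sp, e, sp_new, z, sv, logu, dpri):
        """Accept/reject the (species, year) occupancy-intercept proposals."""
        S, N, Y = eta.shape
        old = np.zeros((N, Y))
        new = np.zeros((N, Y))
        for j in range(S):
            for i in range(N):
                for t in range(Y):
                    if sv[j, t]:
                        old[i, t] += z[j, i, t] * eta[j, i, t] - sp[j, i, t]
                        new[i, t] += z[j, i, t] * e[j, i, t] - sp_new[j, i, t]
        acc = np.zeros((N, Y), dtype=np.bool_)
        for i in range(N):
            for t in range(Y):
                acc[i, t] = logu[i, t] < new[i, t] - old[i, t] + dpri[i, t]
        for j in range(S):
            for i in range(N):
                for t in range(Y):
                    if acc[i, t]:
                        eta[j, i, t] = e[j, i, t]
                        sp[j, i, t] = sp_new[j, i, t]
        return acc

    @njit(cache=True)
    def occ_sp_accept(eta, sp, e, sp_new, z, sv, logu, dpri):
        """Accept/reject one occupancy-slope column, per species."""
        S, N, Y = eta.shape
        old = np.zeros(N)
        new = np.zeros(N)
        for j in range(S):
            for i in range(N):
                for t in range(Y):
                    if sv[j, t]:
                        old[i] += z[j, i, t] * eta[j, i, t] - sp[j, i, t]
                        new[i] += z[j, i, t] * e[j, i, t] - sp_new[j, i, t]
        acc = np.zeros(N, dtype=np.bool_)
        for i in range(N):
            acc[i] = logu[i] < new[i] - old[i] + dpri[i]
        for j in range(S):
            for i in range(N):
                if acc[i]:
                    for t in range(Y):
                        eta[j, i, t] = e[j, i, t]
                        sp[j, i, t] = sp_new[j, i, t]
        return acc

    @njit(cache=True)
    def det_it_accept(eta, sp, e, sp_new, y, ymask, z, logu, dpri):
        """Accept/reject the (species, year) detection-intercept proposals.
        Only occupied non-missing cells contribute to the likelihood; the
        softplus cache stays valid at every non-missing cell."""
        S, K, N, Y = eta.shape
        old = np.zeros((N, Y))
        new = np.zeros((N, Y))
        for j in range(S):
            for k in range(K):
                for i in range(N):
                    for t in range(Y):
                        if ymask[j, k, i, t] and z[j, i, t] > 0.5:
                            old[i, t] += y[j, k, i, t] * eta[j, k, i, t] - sp[j, k, i, t]
                            new[i, t] += y[j, k, i, t] * e[j, k, i, t] - sp_new[j, k, i, t]
        acc = np.zeros((N, Y), dtype=np.bool_)
        for i in range(N):
            for t in range(Y):
                acc[i, t] = logu[i, t] < new[i, t] - old[i, t] + dpri[i, t]
        for j in range(S):
            for k in range(K):
                for i in range(N):
                    for t in range(Y):
                        if acc[i, t] and ymask[j, k, i, t]:
                            eta[j, k, i, t] = e[j, k, i, t]
                            sp[j, k, i, t] = sp_new[j, k, i, t]
        return acc

    @njit(cache=True)
    def det_sp_accept(eta, sp, e, sp_new, y, ymask, z, logu, dpri):
        """Accept/reject the detection-slope proposals, per species."""
        S, K, N, Y = eta.shape
        old = np.zeros(N)
        new = np.zeros(N)
        for j in range(S):
            for k in range(K):
                for i in range(N):
                    for t in range(Y):
                        if ymask[j, k, i, t] and z[j, i, t] > 0.5:
                            old[i] += y[j, k, i, t] * eta[j, k, i, t] - sp[j, k, i, t]
                            new[i] += y[j, k, i, t] * e[j, k, i, t] - sp_new[j, k, i, t]
        acc = np.zeros(N, dtype=np.bool_)
        for i in range(N):
            acc[i] = logu[i] < new[i] - old[i] + dpri[i]
        for j in range(S):
            for k in range(K):
                for i in range(N):
                    if acc[i]:
                        for t in range(Y):
                            if ymask[j, k, i, t]:
                                eta[j, k, i, t] = e[j, k, i, t]
                                sp[j, k, i, t] = sp_new[j, k, i, t]
        return acc

else:  # numpy fallbacks with identical semantics

    def occ_it_accept(eta, sp, e, sp_new, z, sv, logu, dpri):
        m = sv[:, None, :]
        old = np.where(m, z * eta - sp, 0.0).sum(axis=0)
        new = np.where(m, z * e - sp_new, 0.0).sum(axis=0)
        acc = logu < new - old + dpri
        sel = acc[None]
        eta[...] = np.where(sel, e, eta)
        sp[...] = np.where(sel, sp_new, sp)
        return acc

    def occ_sp_accept(eta, sp, e, sp_new, z, sv, logu, dpri):
        m = sv[:, None, :]
        old = np.where(m, z * eta - sp, 0.0).sum(axis=(0, 2))
        new = np.where(m, z * e - sp_new, 0.0).sum(axis=(0, 2))
        acc = logu < new - old + dpri
        sel = acc[None, :, None]
        eta[...] = np.where(sel, e, eta)
        sp[...] = np.where(sel, sp_new, sp)
        return acc

    def det_it_accept(eta, sp, e, sp_new, y, ymask, z, logu, dpri):
        w = ymask & (z[:, None, :, :] > 0.5)
        old = np.where(w, y * eta - sp, 0.0).sum(axis=(0, 1))
        new = np.where(w, y * e - sp_new, 0.0).sum(axis=(0, 1))
        acc = logu < new - old + dpri
        sel = acc[None, None] & ymask
        eta[...] = np.where(sel, e, eta)
        sp[...] = np.where(sel, sp_new, sp)
        return acc

    def det_sp_accept(eta, sp, e, sp_new, y, ymask, z, logu, dpri):
        w = ymask & (z[:, None, :, :] > 0.5)
        old = np.where(w, y * eta - sp, 0.0).sum(axis=(0, 1, 3))
        new = np.where(w, y * e - sp_new, 0.0).sum(axis=(0, 1, 3))
        acc = logu < new - old + dpri
        sel = acc[None, None, :, None] & ymask
        eta[...] = np.where(sel, e, eta)
        sp[...] = np.where(sel, sp_new, sp)
        return acc
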