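"""Fused pairwise kernel sums for the functional-varifold terms.

The varifold inner product and its gradient are O(F_a × F_b) sums over
face pairs.  The numba implementations fuse the position, normal and
signal factors into one pass without materializing pair matrices; the
numpy fallbacks compute identical quantities and are used when numba is
unavailable.  Both paths are exercised by the oracle-equivalence tests.
"""

from __future__ import annotations

import numpy as np

try:
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally installed
    _HAVE_NUMBA = False


def _vf_value_np(Ca, Na, La, fa, Cb, Nb, Lb, fb, sw2, ss2):
    d2 = ((Ca[:, None, :] - Cb[None, :, :]) ** 2).sum(-1)
    dot = Na @ Nb.T
    df = fa[:, None] - fb[None, :]
    return float(
        np.sum(np.exp(-d2 / sw2 - df**2 / ss2) * dot**2 / (4.0 * La[:, None] * Lb[None, :]))
    )


def _vf_grad_np(Ca, Na, La, fa, Cb, Nb, Lb, fb, sw2, ss2):
    d2 = ((Ca[:, None, :] - Cb[None, :, :]) ** 2).sum(-1)
    dot = Na @ Nb.T
    df = fa[:, None] - fb[None, :]
    ke = np.exp(-d2 / sw2 - df**2 / ss2)
    P = ke * dot**2 / (4.0 * La[:, None] * Lb[None, :])
    dC = (-2.0 / sw2) * (P.sum(axis=1)[:, None] * Ca - P @ Cb)
    dF = (-2.0 / ss2) * (P.sum(axis=1) * fa - P @ fb)
    E = ke * dot / (2.0 * La[:, None] * Lb[None, :])
    F2 = ke * dot**2 / (4.0 * (La**3)[:, None] * Lb[None, :])
    dN = E @ Nb - F2.sum(axis=1)[:, None] * Na
    return dC, dN, dF


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _vf_value_nb(Ca, Na, La, fa, Cb, Nb, Lb, fb, sw2, ss2):  # pragma: no cover
        total = 0.0
        for i in range(Ca.shape[0]):
            for j in range(Cb.shape[0]):
                d2 = (
                    (Ca[i, 0] - Cb[j, 0]) ** 2
                    + (Ca[i, 1] - Cb[j, 1]) ** 2
                    + (Ca[i, 2] - Cb[j, 2]) ** 2
                )
                dot = Na[i, 0] * Nb[j, 0] + Na[i, 1] * Nb[j, 1] + Na[i, 2] * Nb[j, 2]
                df = fa[i] - fb[j]
                total += (
                    np.exp(-d2 / sw2 - df * df / ss2) * dot * dot / (4.0 * La[i] * Lb[j])
                )
        return total

    @numba.njit(cache=True, fastmath=True)
    def _vf_grad_nb(Ca, Na, La, fa, Cb, Nb, Lb, fb, sw2, ss2):  # pragma: no cover
        na = Ca.shape[0]
        dC = np.zeros((na, 3))
        dN = np.zeros((na, 3))
        dF = np.zeros(na)
        for i in range(na):
            for j in range(Cb.shape[0]):
                d2 = (
                    (Ca[i, 0] - Cb[j, 0]) ** 2
                    + (Ca[i, 1] - Cb[j, 1]) ** 2
                    + (Ca[i, 2] - Cb[j, 2]) ** 2
                )
                dot = Na[i, 0] * Nb[j, 0] + Na[i, 1] * Nb[j, 1] + Na[i, 2] * Nb[j, 2]
                df = fa[i] - fb[j]
                ke = np.exp(-d2 / sw2 - df * df / ss2)
                inv = 1.0 / (4.0 * La[i] * Lb[j])
                P = ke * dot * dot * inv
                cc = -2.0 / sw2 * P
                for d in range(3):
                    dC[i, d] += cc * (Ca[i, d] - Cb[j, d])
                dF[i] += (-2.0 / ss2) * P * df
                e = ke * dot * 2.0 * inv
                f2 = P / (La[i] * La[i])
                for d in range(3):
                    dN[i, d] += e * Nb[j, d] - f2 * Na[i, d]
        return dC, dN, dF

    vf_value = _vf_value_nb
    vf_grad = _vf_grad_nb
else:  # pragma: no cover
    vf_value = _vf_value_np
    vf_grad = _vf_grad_np
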