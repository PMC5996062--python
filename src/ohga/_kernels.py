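"""Numba-compiled likelihood kernel for the bivariate cross-lagged model.

The quadrature sum over the bivariate random-intercept grid dominates fit
time; this kernel fuses the per-row, per-node, per-walker loops that the
vectorized numpy path materializes as large temporaries.  The numpy path in
:mod:`ohga.crosslag` remains the reference implementation and the two are
asserted equal in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _log_expit(x: float) -> float:
    if x >= 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@njit(cache=True, fastmath=True)
def var_loglik(
    y1, y2, lag1, lag2, xd1, xd2, starts,
    alpha, g11, g12, g21, g22, c2, s1, s2, r, z, logw,
):
    """Marginal log-likelihood per walker.

    Shapes: responses/lags (R,); xd1/xd2 (R, B) fixed-covariate parts;
    alpha (B, K-1); per-walker scalars (B,); z/logw (Q,).  Returns (B,).
    """
    R = y1.shape[0]
    B = alpha.shape[0]
    Q = z.shape[0]
    K1 = alpha.shape[1]  # K - 1
    S = starts.shape[0]
    out = np.zeros(B)
    M = np.empty((Q, Q))
    glp = np.empty(Q)
    for b in range(B):
        rt = math.sqrt(max(1.0 - r[b] * r[b], 0.0))
        total = 0.0
        for s in range(S):
            row_end = starts[s + 1] if s + 1 < S else R
            for q1 in range(Q):
                for q2 in range(Q):
                    M[q1, q2] = logw[q1] + logw[q2]
            for row in range(starts[s], row_end):
                eta1 = g11[b] * lag1[row] + g12[b] * lag2[row] + xd1[row, b]
                eta2 = c2[b] + g21[b] * lag1[row] + g22[b] * lag2[row] + xd2[row, b]
                k = y1[row]
                sgn = 1.0 if y2[row] == 1 else -1.0
                for q1 in range(Q):
                    u1 = s1[b] * z[q1]
                    # ordinal log-probability log(F(hi) - F(lo)), stable
                    if k == K1:
                        # top category: log(1 - F(alpha_{K-1} - eta - u))
                        glp[q1] = _log_expit(-(alpha[b, k - 1] - eta1 - u1))
                    elif k == 0:
                        glp[q1] = _log_expit(alpha[b, 0] - eta1 - u1)
                    else:
                        lhi = _log_expit(alpha[b, k] - eta1 - u1)
                        llo = _log_expit(alpha[b, k - 1] - eta1 - u1)
                        d = llo - lhi
                        glp[q1] = lhi + math.log1p(-math.exp(d)) if d < 0.0 else -np.inf
                for q1 in range(Q):
                    a1 = s2[b] * r[b] * z[q1]
                    g = glp[q1]
                    for q2 in range(Q):
                        u2 = a1 + s2[b] * rt * z[q2]
                        M[q1, q2] += g + _log_expit(sgn * (eta2 + u2))
            # logsumexp over the grid
            m = M[0, 0]
            for q1 in range(Q):
                for q2 in range(Q):
                    if M[q1, q2] > m:
                        m = M[q1, q2]
            if not np.isfinite(m):
                total = -np.inf
                break
            acc = 0.0
            for q1 in range(Q):
                for q2 in range(Q):
                    acc += math.exp(M[q1, q2] - m)
            total += m + math.log(acc)
        out[b] = total
    return out
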