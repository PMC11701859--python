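"""JIT-compiled GRU backward-through-time kernel.

The recurrence over a cohort's ROI signals is the only hot loop in the
package.  The forward pass stays in vectorized numpy (its cost is SIMD
transcendentals), while the backward pass — pure polynomial gate algebra
with two small matmuls per step — is fused with numba when available.  The
pure-numpy backward in ``layers._GRUDirection`` remains the reference path;
the suite asserts the two agree.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised indirectly
    import numba

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


if HAVE_NUMBA:

    @numba.njit(fastmath=True, cache=True)
    def gru_backward(dh_final, c_hprev, c_r, c_z, c_n, c_ghn, w_hh, reverse,
                     dgi_all):
        """Backward pass over cached gate activations.

        Caches are time-major ``(T, B, H)`` in iteration order (position
        ``s``); ``reverse`` maps positions back to sequence indices ``t``.
        Fills the provided time-major ``dgi_all`` (T, B, 3H) buffer (every
        element is overwritten) and returns the hidden-side weight and bias
        gradients; input-side gradients follow from ``dgi_all`` outside.
        """
        T, B, H = c_r.shape
        dh = dh_final.copy()
        d_whh = np.zeros_like(w_hh)
        d_bhh = np.zeros(3 * H, dtype=np.float32)
        dgates_h = np.empty((B, 3 * H), dtype=np.float32)
        for s in range(T - 1, -1, -1):
            t = T - 1 - s if reverse else s
            for b in range(B):
                for k in range(H):
                    r = c_r[s, b, k]
                    z = c_z[s, b, k]
                    n = c_n[s, b, k]
                    ghn = c_ghn[s, b, k]
                    d = dh[b, k]
                    dn = d * (1.0 - z)
                    dz = d * (c_hprev[s, b, k] - n)
                    dgn = dn * (1.0 - n * n)
                    dr = dgn * ghn
                    dghn = dgn * r
                    dgz = dz * z * (1.0 - z)
                    dgr = dr * r * (1.0 - r)
                    dgi_all[t, b, k] = dgr
                    dgi_all[t, b, k + H] = dgz
                    dgi_all[t, b, k + 2 * H] = dgn
                    dgates_h[b, k] = dgr
                    dgates_h[b, k + H] = dgz
                    dgates_h[b, k + 2 * H] = dghn
                    dh[b, k] = d * z
            d_whh += np.dot(c_hprev[s].T, dgates_h)
            for b in range(B):
                for k in range(3 * H):
                    d_bhh[k] += dgates_h[b, k]
            dh += np.dot(dgates_h, w_hh.T)
        return d_whh, d_bhh
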