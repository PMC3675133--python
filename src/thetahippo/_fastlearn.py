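"""Compiled weight-update kernel.

Fuses the CPCA/CHL blend, per-receiver error centering, masking and hard
clipping of one projection's update into a single pass, avoiding the
half-dozen temporaries of the numpy expression.  Only the default
configuration (hard bounds) is compiled; soft bounding falls back to the
reference numpy path in :mod:`thetahippo.network`.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

if HAVE_NUMBA:

    @njit(cache=True)
    def update_projection(w, mask, fanin, x_plus, y_plus, x_minus, y_minus,
                          eps, lmix, use_err, center):
        """In-place blended update with hard [0,1] clipping.

        use_err=False applies the pure CPCA delta (Hebbian-tagged
        projections); otherwise the CHL error delta (optionally centered
        per receiver) is blended at (1-lmix).
        """
        n_s, n_r = w.shape
        for j in range(n_r):
            yp = y_plus[j]
            ym = y_minus[j]
            # a receiver silent in every involved phase gets a zero delta
            if yp == 0.0 and (not use_err or ym == 0.0):
                continue
            if use_err and center:
                mean_err = 0.0
                for i in range(n_s):
                    if mask[i, j] != 0.0:
                        mean_err += x_plus[i] * yp - x_minus[i] * ym
                mean_err /= fanin[j]
            else:
                mean_err = 0.0
            for i in range(n_s):
                if mask[i, j] == 0.0:
                    continue
                hebb = yp * (x_plus[i] - w[i, j])
                if use_err:
                    err = x_plus[i] * yp - x_minus[i] * ym - mean_err
                    d = eps * (lmix * hebb + (1.0 - lmix) * err)
                else:
                    d = eps * hebb
                nw = w[i, j] + d
                if nw < 0.0:
                    nw = 0.0
                elif nw > 1.0:
                    nw = 1.0
                w[i, j] = nw
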