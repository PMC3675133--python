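"""Compiled fast path for phase settling.

Implements exactly the same synchronous update as
:func:`thetahippo.dynamics.settle` on a packed representation (one state
vector for all layers, per-projection weight matrices pre-scaled by
scale / (sender_activity * fanin)).  Slot-topographic (block-diagonal)
projections are packed as per-slot blocks so their structural zeros cost
nothing.  Used by :class:`thetahippo.network.Network` when numba is
importable; results agree with the reference to floating-point
reassociation (~1e-12) and are bit-reproducible run to run.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    from numba.typed import List as NumbaList

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep of the env
    HAVE_NUMBA = False

if HAVE_NUMBA:

    @njit(cache=True)
    def _settle_kernel(y, vm, n_steps,
                       Ws, send, recv, scale, popen,
                       Bs, bsend, brecv, bscale, bpopen,
                       offs, clamped, n_pools, pool_size, k_active,
                       dt, gl, gain, thresh, ee, ei, el, kwta_pt):
        n_layers = offs.shape[0] - 1
        n_proj = len(Ws)
        n_block = len(Bs)
        N = y.shape[0]
        ge = np.zeros(N)
        wsum = np.zeros(n_layers)
        for _ in range(n_steps):
            ge[:] = 0.0
            wsum[:] = 0.0
            for p in range(n_proj):
                if popen[p] <= 0.0:
                    continue
                s = send[p]
                r = recv[p]
                x = y[offs[s]:offs[s + 1]]
                ge[offs[r]:offs[r + 1]] += popen[p] * np.dot(x, Ws[p])
                wsum[r] += popen[p] * scale[p]
            for p in range(n_block):
                if bpopen[p] <= 0.0:
                    continue
                B = Bs[p]  # (n_slots, send_per_slot, recv_per_slot)
                s = bsend[p]
                r = brecv[p]
                sps = B.shape[1]
                rps = B.shape[2]
                for sl in range(B.shape[0]):
                    x = y[offs[s] + sl * sps:offs[s] + (sl + 1) * sps]
                    out = np.dot(x, B[sl])
                    for u in range(rps):
                        ge[offs[r] + sl * rps + u] += bpopen[p] * out[u]
                wsum[r] += bpopen[p] * bscale[p]
            for l in range(n_layers):
                if clamped[l]:
                    continue
                a = offs[l]
                n_u = offs[l + 1] - a
                gel = np.zeros(n_u)
                if wsum[l] > 0.0:
                    for u in range(n_u):
                        gel[u] = ge[a + u] / wsum[l]
                denom = thresh - ei
                ps = pool_size[l]
                k = k_active[l]
                for pool in range(n_pools[l]):
                    lo = pool * ps
                    gtheta = np.empty(ps)
                    for u in range(ps):
                        gtheta[u] = (gel[lo + u] * (ee - thresh)
                                     + gl * (el - thresh)) / denom
                    gt = np.sort(gtheta)  # ascending
                    g_k = gt[ps - k]
                    if k < ps:
                        g_k1 = gt[ps - k - 1]
                    else:
                        g_k1 = min(0.0, g_k)
                    gi = g_k1 + kwta_pt * (g_k - g_k1)
                    if gi < 0.0:
                        gi = 0.0
                    for u in range(lo, lo + ps):
                        i = a + u
                        dvm = (gel[u] * (ee - vm[i]) + gi * (ei - vm[i])
                               + gl * (el - vm[i]))
                        vm[i] = vm[i] + dt * dvm
                        d = gain * (vm[i] - thresh)
                        y[i] = d / (d + 1.0) if d > 0.0 else 0.0


def _is_block_diagonal(mask: np.ndarray, n_slots: int) -> bool:
    n_s, n_r = mask.shape
    if n_s % n_slots or n_r % n_slots:
        return False
    sps, rps = n_s // n_slots, n_r // n_slots
    blocks = mask.reshape(n_slots, sps, n_slots, rps)
    on = np.einsum("isjr->ij", blocks)
    off_diag = on - np.diag(np.diag(on))
    return bool(np.all(np.diag(on) == sps * rps) and np.all(off_diag == 0))


class FastState:
    """Packed network state reused across phases of one theta cycle.

    Weight matrices are re-packed (pre-scaled) whenever the network's
    weights change; the state vectors are copied in/out of the layer
    objects around each settle call.
    """

    def __init__(self, layers: dict, projections: list, n_slots: int = 1):
        self.layer_names = list(layers)
        self.index = {n: i for i, n in enumerate(self.layer_names)}
        sizes = [layers[n].n_units for n in self.layer_names]
        self.offs = np.concatenate([[0], np.cumsum(sizes)]).astype(np.int64)
        self.n_pools = np.array([layers[n].n_pools for n in self.layer_names],
                                dtype=np.int64)
        self.pool_size = np.array([layers[n].pool_size for n in self.layer_names],
                                  dtype=np.int64)
        self.k_active = np.array([layers[n].k_active for n in self.layer_names],
                                 dtype=np.int64)
        self.n_slots = n_slots
        self.block = [n_slots > 1 and _is_block_diagonal(p.mask, n_slots)
                      for p in projections]
        dense = [p for p, b in zip(projections, self.block) if not b]
        blocked = [p for p, b in zip(projections, self.block) if b]
        self.proj_names = [p.name for p in dense]
        self.bproj_names = [p.name for p in blocked]
        self.send = np.array([self.index[p.sender] for p in dense], np.int64)
        self.recv = np.array([self.index[p.receiver] for p in dense], np.int64)
        self.scale = np.array([p.scale for p in dense], np.float64)
        self.bsend = np.array([self.index[p.sender] for p in blocked], np.int64)
        self.brecv = np.array([self.index[p.receiver] for p in blocked], np.int64)
        self.bscale = np.array([p.scale for p in blocked], np.float64)
        self.Ws = None
        self.Bs = None

    def pack_weights(self, projections: list) -> None:
        self.Ws = NumbaList()
        self.Bs = NumbaList()
        for p, blk in zip(projections, self.block):
            eff = p.w * (p.scale / (p.sender_activity * p.fanin[None, :]))
            if blk:
                n_s, n_r = eff.shape
                sps, rps = n_s // self.n_slots, n_r // self.n_slots
                blocks = np.empty((self.n_slots, sps, rps))
                for sl in range(self.n_slots):
                    blocks[sl] = eff[sl * sps:(sl + 1) * sps,
                                     sl * rps:(sl + 1) * rps]
                self.Bs.append(np.ascontiguousarray(blocks))
            else:
                self.Ws.append(np.ascontiguousarray(eff))

    def run(self, layers: dict, gates: dict, params, n_steps: int) -> dict:
        y = np.concatenate([layers[n].y for n in self.layer_names])
        vm = np.concatenate([layers[n].vm for n in self.layer_names])
        clamped = np.array([layers[n].clamped for n in self.layer_names])
        popen = np.array([float(gates.get(n, 1.0)) for n in self.proj_names])
        bpopen = np.array([float(gates.get(n, 1.0)) for n in self.bproj_names])
        _settle_kernel(y, vm, n_steps, self.Ws, self.send, self.recv,
                       self.scale, popen,
                       self.Bs, self.bsend, self.brecv, self.bscale, bpopen,
                       self.offs, clamped,
                       self.n_pools, self.pool_size, self.k_active,
                       params.dt_vm, params.g_l, params.gain, params.threshold,
                       params.e_rev_exc, params.e_rev_inh, params.e_rev_leak,
                       params.kwta_pt)
        out = {}
        for i, n in enumerate(self.layer_names):
            a, b = self.offs[i], self.offs[i + 1]
            lay = layers[n]
            if not lay.clamped:
                lay.y = y[a:b].copy()
                lay.vm = vm[a:b].copy()
            out[n] = lay.y.copy()
        return out
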