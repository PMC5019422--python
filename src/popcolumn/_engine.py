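"""Compiled inner loop for the coupled population-density simulation.

The per-population one-step propagator exp(dt * (L + sum_s lambda_s S_s)) is
evaluated by a sub-stepped truncated Taylor series acting on the packed CSR
representation of the flux operators (identical math to
``solver.step_density(method="taylor")``; equivalence is covered by tests).

Per population the leak and the unit-rate synaptic operators are stored as
data rows aligned on one shared (union) sparsity pattern, so composing the
generator for the current input rates is a dense axpy over the pattern's
nonzeros.  Rates are events/ms throughout this module.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernel
OK = 0
NEGATIVE_MASS = 1
MASS_DRIFT = 2
SERIES_FAILURE = 3


@njit(cache=True)
def run_kernel(
    T,
    dt,
    indptr,        # (n_pops, n_bins+1) int64
    indices,       # (n_pops, max_nnz) int64
    nnz,           # (n_pops,) int64
    opdata,        # (n_pops, max_ops, max_nnz) float64; row 0 = leak
    fire,          # (n_pops, max_ops, n_bins) float64
    nops,          # (n_pops,) int64
    leak_maxdiag,  # (n_pops,) float64
    c_tgt, c_op, c_srckind, c_src,  # connection tables (int64)
    c_indeg, c_delay,               # float64 / int64
    ext,           # (n_ext, T) float64, events/ms
    P,             # (n_pops, n_bins) float64, modified in place
    rates,         # (n_pops, T) float64 out, events/ms
):
    n_pops, n_bins = P.shape
    max_ops = opdata.shape[1]
    n_conn = c_tgt.shape[0]

    lam = np.zeros((n_pops, max_ops))
    data = np.zeros(indices.shape[1])
    fvec = np.zeros(n_bins)
    term = np.zeros(n_bins)
    nxt = np.zeros(n_bins)
    acc = np.zeros(n_bins)

    for t in range(T):
        # gather delayed input rates per (population, weight-group)
        for p in range(n_pops):
            for o in range(max_ops):
                lam[p, o] = 0.0
            lam[p, 0] = 1.0  # leak enters at unit rate
        for c in range(n_conn):
            d = c_delay[c]
            if d < 1:
                d = 1  # zero-delay coupling resolves at one step lag
            if c_srckind[c] == 0:
                idx = t - d
                r = rates[c_src[c], idx] if idx >= 0 else 0.0
            else:
                idx = t - c_delay[c]
                if idx < 0:
                    idx = 0
                r = ext[c_src[c], idx]
            lam[c_tgt[c], c_op[c]] += c_indeg[c] * r

        # advance every population with rates frozen over the step (Jacobi)
        for p in range(n_pops):
            nz = nnz[p]
            no = nops[p]
            for q in range(nz):
                data[q] = opdata[p, 0, q]
            for i in range(n_bins):
                fvec[i] = 0.0
            lam_tot = 0.0
            for o in range(1, no):
                lo = lam[p, o]
                if lo == 0.0:
                    continue
                lam_tot += lo
                for q in range(nz):
                    data[q] += lo * opdata[p, o, q]
                for i in range(n_bins):
                    fvec[i] += lo * fire[p, o, i]

            max_out = leak_maxdiag[p] + lam_tot
            n_sub = 1 + int(dt * max_out / 2.0)
            h = dt / n_sub

            spiked = 0.0
            for _ in range(n_sub):
                dot_f = 0.0
                for i in range(n_bins):
                    term[i] = P[p, i]
                    acc[i] = P[p, i]
                    dot_f += fvec[i] * P[p, i]
                spiked += h * dot_f
                converged = False
                for kk in range(1, 80):
                    scale = h / kk
                    mx = 0.0
                    dot_f = 0.0
                    for i in range(n_bins):
                        s = 0.0
                        for q in range(indptr[p, i], indptr[p, i + 1]):
                            s += data[q] * term[indices[p, q]]
                        nxt[i] = scale * s
                    for i in range(n_bins):
                        term[i] = nxt[i]
                        acc[i] += nxt[i]
                        a = abs(nxt[i])
                        if a > mx:
                            mx = a
                        dot_f += fvec[i] * nxt[i]
                    spiked += (h / (kk + 1)) * dot_f
                    if mx < 1e-16:
                        converged = True
                        break
                if not converged:
                    return SERIES_FAILURE, t, p
                for i in range(n_bins):
                    P[p, i] = acc[i]

            total = 0.0
            mn = 0.0
            for i in range(n_bins):
                total += P[p, i]
                if P[p, i] < mn:
                    mn = P[p, i]
            if mn < -1e-12:
                return NEGATIVE_MASS, t, p
            if abs(total - 1.0) > 1e-9:
                return MASS_DRIFT, t, p
            rates[p, t] = spiked / dt

    return OK, -1, -1
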