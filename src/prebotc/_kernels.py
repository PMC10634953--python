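"""Numba kernel for fixed-step forward-Euler integration of neuron batches.

One kernel serves both uncoupled sweeps (``coupled=False``; every neuron an
independent cell, e.g. a (neuron x drive) grid flattened into a batch) and
the synaptically coupled network (CSR connectivity, depression, zero-delay
exponential synapses).

Gating nonlinearities are evaluated through linearly interpolated lookup
tables built by :func:`prebotc.biophysics.rate_tables` on a 0.05 mV grid;
membrane currents are computed in closed form.  The Euler relaxation factor
dt/tau can exceed 1 for the fastest gates near the spike peak, so gates are
clamped to [0, 1] after each step.

Status codes returned: 0 = ok, 1 = spike buffer full.
"""

import numba
import numpy as np

from .biophysics import SPIKE_THRESHOLD, TABLE_DV, TABLE_V_MIN

#: Post-spike detection lockout (ms); suppresses numerical double-crossings.
REFRACTORY = 1.0


@numba.njit(cache=True, fastmath=True)
def run_chunk(
    V, G, D, syn,                       # state: (n,), (n,10), (n,), (n,)
    gNa, gK, gSPK, gAHP, gNaP, gCa, gLeak, gTonic,   # (n,)
    tab,                                # (20, nV) rate tables
    C, ENa, EK, ELeak, ECa, Esyn,       # scalars
    dt, n_steps, step0,                 # step0: global index of first step
    coupled, syn_on,                    # flags
    indptr, indices, weights,           # outgoing CSR (per presynaptic row)
    syn_decay, d_rate, D0, alphaD,      # synapse scalars (d_rate = dt/tauD)
    fr_mNaP, fr_hNaP, fr_D,             # (n,) uint8 freeze flags
    last_spike,                         # (n,) ms
    sp_t, sp_i, sp_n,                   # spike buffers + fill count
    rec_stride,                         # 0 = no recording
    rec_idx, recV, rec_mean, rec_n,     # V-trace subset, mean-field trace
):
    n = V.shape[0]
    nv = tab.shape[1]
    inv_dv = 1.0 / TABLE_DV
    thresh = SPIKE_THRESHOLD
    status = 0
    step_sp = np.empty(n, dtype=np.int64)

    for s in range(n_steps):
        gstep = step0 + s
        t_now = gstep * dt

        # stop cleanly at a step boundary if the buffer may not hold a
        # worst-case step (every neuron spiking)
        if sp_t.shape[0] - sp_n < n:
            return sp_n, rec_n, 1, s

        if rec_stride > 0 and gstep % rec_stride == 0:
            for j in range(rec_idx.shape[0]):
                recV[rec_n, j] = V[rec_idx[j]]
            mv = 0.0
            mh = 0.0
            md = 0.0
            ms = 0.0
            for i in range(n):
                mv += V[i]
                mh += G[i, 7]
                md += D[i]
                ms += syn[i]
            rec_mean[rec_n, 0] = mv / n
            rec_mean[rec_n, 1] = mh / n
            rec_mean[rec_n, 2] = md / n
            rec_mean[rec_n, 3] = ms / n
            rec_n += 1

        n_step_sp = 0
        for i in range(n):
            v = V[i]

            # gate updates via table interpolation at the pre-step voltage
            x = (v - TABLE_V_MIN) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > nv - 2:
                x = float(nv - 2)
            i0 = int(x)
            f = x - i0
            for k in range(10):
                if k == 6 and fr_mNaP[i] != 0:
                    continue
                if k == 7 and fr_hNaP[i] != 0:
                    continue
                inf = tab[2 * k, i0] + f * (tab[2 * k, i0 + 1] - tab[2 * k, i0])
                r = tab[2 * k + 1, i0] + f * (tab[2 * k + 1, i0 + 1] - tab[2 * k + 1, i0])
                g = G[i, k] + r * (inf - G[i, k])
                if g < 0.0:
                    g = 0.0
                elif g > 1.0:
                    g = 1.0
                G[i, k] = g

            # membrane update from the freshly advanced gates (sequential
            # first-order Euler; tracks the exact trajectory more closely
            # than the fully simultaneous update at the same dt)
            ina = gNa[i] * G[i, 0] * G[i, 0] * G[i, 0] * G[i, 1] * (v - ENa)
            ik = gK[i] * G[i, 2] * G[i, 2] * G[i, 2] * G[i, 2] * (v - EK)
            ispk = gSPK[i] * G[i, 3] * G[i, 4] * (v - ENa)
            iahp = gAHP[i] * G[i, 5] * (v - EK)
            inap = gNaP[i] * G[i, 6] * G[i, 7] * (v - ENa)
            ica = gCa[i] * G[i, 8] * G[i, 9] * (v - ECa)
            ileak = gLeak[i] * (v - ELeak)
            gs = gTonic[i]
            if syn_on:
                gs += syn[i]
            isyn = gs * (v - Esyn)

            vnew = v + dt * (
                -(ina + ik + ispk + iahp + inap + ica + ileak + isyn) / C
            )
            V[i] = vnew

            # synaptic depression recovery
            if fr_D[i] == 0:
                dnew = D[i] + d_rate * (D0 - D[i])
                if dnew > D0:
                    dnew = D0
                D[i] = dnew

            # spike detection: upward crossing of threshold with lockout
            t_next = t_now + dt
            if vnew >= thresh and v < thresh and t_next - last_spike[i] >= REFRACTORY:
                last_spike[i] = t_next
                sp_t[sp_n] = t_next
                sp_i[sp_n] = i
                sp_n += 1
                step_sp[n_step_sp] = i
                n_step_sp += 1

        if syn_on:
            for i in range(n):
                syn[i] *= syn_decay
        if coupled and syn_on:
            # zero-delay transmission: each spike at the end of this step adds
            # W * D (presynaptic depression at spike time) to its targets,
            # then the presynaptic synapse depresses multiplicatively.
            for q in range(n_step_sp):
                j = step_sp[q]
                dj = D[j]
                for e in range(indptr[j], indptr[j + 1]):
                    syn[indices[e]] += weights[e] * dj
                if fr_D[j] == 0:
                    D[j] = dj * (1.0 - alphaD)

    return sp_n, rec_n, status, n_steps
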