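"""Numba core of the multicell Gillespie engine.

The kernel advances the coupled N-cell system between "barriers" (trajectory
sampling times, division times, interval end).  Divisions, binomial
partitioning and cell removal are handled by the Python driver in
:mod:`luxswitch.ssa`; the kernel only executes chemistry.

Per-cell species order:
    0 mRNA_luxR, 1 mRNA_luxIgfp, 2 luxR, 3 luxIgfp, 4 A, 5 C, 6 C2,
    7 DNA_free, 8 DNA_bound

Per-cell channel order (21 channels; the A_ext → cell diffusion channel is
pooled over cells and lives in the external group):
    0 basal tx luxR        1 basal tx luxI
    2 activated tx luxR    3 activated tx luxI
    4 translation luxR     5 translation luxI
    6 synthesis of A       7 R+A binding          8 C unbinding
    9 dimerization 2C→C2  10 C2 dissociation
   11 promoter binding    12 promoter unbinding
   13 A → A_ext (out)     14 deg A   15 deg mR   16 deg mI
   17 deg R   18 deg I    19 deg C   20 deg C2

External group:
    0 influx γ·cA*·f·Vtot, 1 efflux γ·n_Aext, 2 degradation dA·n_Aext,
    3 diffusion A_ext → cells, D·n_Aext·ΣVᵢ/(Vtot−ΣVᵢ) (receiving cell
      chosen proportionally to its volume).

Second-order propensities are evaluated with the cell volume at the moment
the cell's row was last refreshed (every event in the cell, and at every
barrier); the volume growth between refreshes is adiabatically slow compared
with the reaction dynamics.

Parameter packing (float64 vector, see ``pack_params`` in ssa.py):
    0 aR·kR  1 aI·kI  2 kR  3 kI  4 pR  5 pI  6 kA
    7 (k1−/Kd1)/f  8 k1−  9 (k2−/Kd2)/f  10 k2−  11 (klux−/Kdlux)/f  12 klux−
   13 D  14 dA  15 dmR  16 dmI  17 dR  18 dI  19 dC  20 dC2
   21 γ  22 γ·cA*·f·Vtot  23 Vtot  24 V0  25 f  26 ln2/τ (volume growth rate)
"""

import math

import numpy as np
from numba import njit

N_SPECIES = 9
N_CELL_CHANNELS = 21

LN2 = math.log(2.0)


@njit(cache=True, inline="always")
def _rnd(rs):
    """xoshiro256** next double in (0, 1]."""
    s0, s1, s2, s3 = rs[0], rs[1], rs[2], rs[3]
    x = s1 * np.uint64(5)
    result = ((x << np.uint64(7)) | (x >> np.uint64(57))) * np.uint64(9)
    t = s1 << np.uint64(17)
    s2 ^= s0
    s3 ^= s1
    s1 ^= s2
    s0 ^= s3
    s2 ^= t
    s3 = (s3 << np.uint64(45)) | (s3 >> np.uint64(19))
    rs[0], rs[1], rs[2], rs[3] = s0, s1, s2, s3
    return (np.float64(result >> np.uint64(11)) + 1.0) * (2.0 ** -53)


@njit(cache=True)
def seed_rng(seed):
    """Fill an xoshiro256** state from an integer seed via splitmix64."""
    rs = np.empty(4, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(4):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        rs[i] = w ^ (w >> np.uint64(31))
    return rs


@njit(cache=True, inline="always")
def _cell_volume(pk, birth, taui, i, t):
    return pk[24] * 2.0 ** ((t - birth[i]) / taui[i])


@njit(cache=True, inline="always")
def _refresh_cell(P, Scell, x, pk, i, V):
    invfV = 1.0 / V
    nmr = np.float64(x[i, 0]); nmi = np.float64(x[i, 1])
    nr = np.float64(x[i, 2]); ni = np.float64(x[i, 3])
    na = np.float64(x[i, 4]); nc = np.float64(x[i, 5])
    nc2 = np.float64(x[i, 6]); ndf = np.float64(x[i, 7]); ndb = np.float64(x[i, 8])
    P[i, 0] = pk[0] * ndf
    P[i, 1] = pk[1] * ndf
    P[i, 2] = pk[2] * ndb
    P[i, 3] = pk[3] * ndb
    P[i, 4] = pk[4] * nmr
    P[i, 5] = pk[5] * nmi
    P[i, 6] = pk[6] * ni
    P[i, 7] = pk[7] * invfV * nr * na
    P[i, 8] = pk[8] * nc
    P[i, 9] = pk[9] * invfV * 0.5 * nc * (nc - 1.0)
    P[i, 10] = pk[10] * nc2
    P[i, 11] = pk[11] * invfV * nc2 * ndf
    P[i, 12] = pk[12] * ndb
    P[i, 13] = pk[13] * na
    P[i, 14] = pk[14] * na
    P[i, 15] = pk[15] * nmr
    P[i, 16] = pk[16] * nmi
    P[i, 17] = pk[17] * nr
    P[i, 18] = pk[18] * ni
    P[i, 19] = pk[19] * nc
    P[i, 20] = pk[20] * nc2
    s = 0.0
    for k in range(N_CELL_CHANNELS):
        s += P[i, k]
    Scell[i] = s


@njit(cache=True, inline="always")
def _refresh_external(E, pk, aext, Vct, clamp, clamp_conc):
    if clamp:
        E[0] = 0.0
        E[1] = 0.0
        E[2] = 0.0
        E[3] = pk[13] * clamp_conc * pk[25] * Vct
    else:
        E[0] = pk[22]
        E[1] = pk[21] * aext
        E[2] = pk[14] * aext
        E[3] = pk[13] * aext * Vct / (pk[23] - Vct)


# stoichiometry table: per channel, up to three (species, delta) pairs
# encoded as arrays for speed
_STO_SPECIES = np.array([
    [0, -1, -1],   # 0 +mR
    [1, -1, -1],   # 1 +mI
    [0, -1, -1],   # 2 +mR
    [1, -1, -1],   # 3 +mI
    [2, -1, -1],   # 4 +R
    [3, -1, -1],   # 5 +I
    [4, -1, -1],   # 6 +A
    [2, 4, 5],     # 7 -R -A +C
    [2, 4, 5],     # 8 +R +A -C
    [5, 6, -1],    # 9 -2C +C2
    [5, 6, -1],    # 10 +2C -C2
    [6, 7, 8],     # 11 -C2 -DNAf +DNAb
    [6, 7, 8],     # 12 +C2 +DNAf -DNAb
    [4, -1, -1],   # 13 -A (to ext)
    [4, -1, -1],   # 14 -A
    [0, -1, -1],   # 15 -mR
    [1, -1, -1],   # 16 -mI
    [2, -1, -1],   # 17 -R
    [3, -1, -1],   # 18 -I
    [5, -1, -1],   # 19 -C
    [6, -1, -1],   # 20 -C2
], dtype=np.int64)

_STO_DELTA = np.array([
    [1, 0, 0],
    [1, 0, 0],
    [1, 0, 0],
    [1, 0, 0],
    [1, 0, 0],
    [1, 0, 0],
    [1, 0, 0],
    [-1, -1, 1],
    [1, 1, -1],
    [-2, 1, 0],
    [2, -1, 0],
    [-1, -1, 1],
    [1, 1, -1],
    [-1, 0, 0],
    [-1, 0, 0],
    [-1, 0, 0],
    [-1, 0, 0],
    [-1, 0, 0],
    [-1, 0, 0],
    [-1, 0, 0],
    [-1, 0, 0],
], dtype=np.int64)


@njit(cache=True)
def advance_interval(x, aext_box, birth, taui, t0, t1, pk, rs,
                     clamp, clamp_conc, stop_dir, stop_conc,
                     log_t, log_cell, log_ch, log_count, max_events):
    """Run the SSA from t0 to t1 (no divisions inside the interval).

    Returns (t_reached, n_events, stopped, negative_detected).
    ``stopped`` is 1 when the GFP concentration of cell 0 crossed
    ``stop_conc`` in the direction ``stop_dir`` (+1 up, −1 down).
    Events are appended to the log arrays while capacity remains
    (log_count[0] tracks usage; pass zero-length arrays to disable).
    """
    N = x.shape[0]
    P = np.empty((N, N_CELL_CHANNELS))
    Scell = np.empty(N)
    E = np.empty(4)
    V = np.empty(N)
    f = pk[25]
    Vct = 0.0
    for i in range(N):
        V[i] = _cell_volume(pk, birth, taui, i, t0)
        Vct += V[i]
        _refresh_cell(P, Scell, x, pk, i, V[i])
    aext = aext_box[0]
    _refresh_external(E, pk, aext, Vct, clamp, clamp_conc)
    t = t0
    n_ev = 0
    log_cap = log_t.shape[0]
    while n_ev < max_events:
        S = E[0] + E[1] + E[2] + E[3]
        for i in range(N):
            S += Scell[i]
        if S <= 0.0:
            t = t1
            break
        dt = -math.log(_rnd(rs)) / S
        if t + dt >= t1:
            t = t1
            break
        t = t + dt
        target = _rnd(rs) * S
        # ---- channel selection ----
        sel_cell = -1
        sel_ch = -1
        acc = 0.0
        for i in range(N):
            if acc + Scell[i] > target:
                rem = target - acc
                for k in range(N_CELL_CHANNELS):
                    rem -= P[i, k]
                    if rem < 0.0:
                        sel_cell = i
                        sel_ch = k
                        break
                if sel_ch < 0:
                    sel_cell = i
                    sel_ch = N_CELL_CHANNELS - 1
                break
            acc += Scell[i]
        if sel_cell < 0:
            # external group
            rem = target - acc
            ech = 3
            for k in range(4):
                rem -= E[k]
                if rem < 0.0:
                    ech = k
                    break
            if ech == 0:
                aext += 1.0
            elif ech == 1 or ech == 2:
                aext -= 1.0
            else:
                # diffusion into a cell, chosen proportionally to volume
                u = _rnd(rs) * Vct
                j = N - 1
                accv = 0.0
                for i in range(N):
                    accv += V[i]
                    if u < accv:
                        j = i
                        break
                x[j, 4] += 1
                if not clamp:
                    aext -= 1.0
                V[j] = _cell_volume(pk, birth, taui, j, t)
                _refresh_cell(P, Scell, x, pk, j, V[j])
            if not clamp:
                _refresh_external(E, pk, aext, Vct, clamp, clamp_conc)
            if log_count[0] < log_cap:
                log_t[log_count[0]] = t
                log_cell[log_count[0]] = -1
                log_ch[log_count[0]] = N_CELL_CHANNELS + ech
                log_count[0] += 1
            n_ev += 1
            continue
        # ---- per-cell channel ----
        i = sel_cell
        for s in range(3):
            sp = _STO_SPECIES[sel_ch, s]
            if sp < 0:
                break
            x[i, sp] += _STO_DELTA[sel_ch, s]
        if sel_ch == 13:  # A leaves the cell
            if not clamp:
                aext += 1.0
                _refresh_external(E, pk, aext, Vct, clamp, clamp_conc)
        V[i] = _cell_volume(pk, birth, taui, i, t)
        _refresh_cell(P, Scell, x, pk, i, V[i])
        if log_count[0] < log_cap:
            log_t[log_count[0]] = t
            log_cell[log_count[0]] = i
            log_ch[log_count[0]] = sel_ch
            log_count[0] += 1
        n_ev += 1
        # ---- optional stopping on the GFP level of cell 0 ----
        if stop_dir != 0 and i == 0 and (sel_ch == 5 or sel_ch == 18):
            conc = x[0, 3] / (f * V[0])
            if stop_dir > 0 and conc >= stop_conc:
                aext_box[0] = aext
                return t, n_ev, 1, 0
            if stop_dir < 0 and conc <= stop_conc:
                aext_box[0] = aext
                return t, n_ev, 1, 0
    # negative-count guard (should never trigger; diagnostic only)
    neg = 0
    for i in range(N):
        for s in range(N_SPECIES):
            if x[i, s] < 0:
                neg = 1
    aext_box[0] = aext
    return t, n_ev, 0, neg
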