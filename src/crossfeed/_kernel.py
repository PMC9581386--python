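"""Compiled event loop.

Molecule bookkeeping (per nutrient) uses a flat token array plus two
per-site counters.  ``mol`` lists one token (a flat site index) per
molecule ever placed and not yet confirmed removed; ``ct`` interleaves,
per site, the true molecule count (even slot) and the token count (odd
slot) so both land on one cache line.  Uptake just decrements the true
count (lazy deletion).  Diffusion draws a uniform token; if
the token's site carries more tokens than real molecules the drawn token is
retired with probability (tok-cnt)/tok and the draw repeats — tokens at one
site are exchangeable, so this reproduces exact uniform sampling over the
real molecules at O(1) amortized cost.  Excretion appends a token.

Cells never die, so each species is an append-only int32 array of flat
site indices, giving O(1) uniform cell choice.

Scalar state lives in small arrays so it survives between kernel calls:
``mst`` per nutrient = [n_molecules, n_tokens]; ``ist`` = [n1, n2];
``fst`` = [t].
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_REACHED = 0
STATUS_STASIS = 1
STATUS_GROW = 2
STATUS_BOUNDARY = 3

_NM, _NTOK = 0, 1

_INV53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _rand(st):
    """xorshift128+ double in (0, 1]; st is a 2-element uint64 state."""
    s1 = st[0]
    s0 = st[1]
    st[0] = s0
    s1 ^= s1 << np.uint64(23)
    st[1] = s1 ^ s0 ^ (s1 >> np.uint64(18)) ^ (s0 >> np.uint64(5))
    x = st[1] + s0
    return (np.float64(x >> np.uint64(11)) + 1.0) * _INV53


@njit(cache=True, inline="always")
def _randint(st, n):
    """Uniform integer in [0, n) via the 53-bit double (n << 2^53)."""
    u = _rand(st)
    i = np.int64(u * n)
    if i >= n:  # u == 1.0 edge
        i = n - 1
    return i


@njit(cache=True)
def _seed_state(seed):
    """splitmix64-expanded seed for the xorshift128+ state."""
    st = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        z += np.uint64(0x9E3779B97F4A7C15)
        w = z
        w = (w ^ (w >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        w = (w ^ (w >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        w = w ^ (w >> np.uint64(31))
        st[i] = w
    if st[0] == 0 and st[1] == 0:
        st[0] = np.uint64(1)
    # warm up past seeding correlations
    for _ in range(16):
        _rand(st)
    return st


@njit(cache=True)
def _fill_tokens(ct, mol, mst):
    """Populate the token array from the interleaved count grid."""
    k = 0
    for s in range(ct.shape[0] // 2):
        c = ct[2 * s]
        ct[2 * s + 1] = c
        for _ in range(c):
            mol[k] = s
            k += 1
    mst[_NM] = k
    mst[_NTOK] = k


@njit(cache=True, inline="always")
def _local_sum5(ct, s, N):
    x = s // N
    y = s % N
    total = np.int64(ct[2 * s])
    if x > 0:
        total += ct[2 * (s - N)]
    if x < N - 1:
        total += ct[2 * (s + N)]
    if y > 0:
        total += ct[2 * (s - 1)]
    if y < N - 1:
        total += ct[2 * (s + 1)]
    return total


@njit(cache=True)
def _advance(cell, N, cells1, cells2, ist,
             ctA, molA, mstA,
             ctB, molB, mstB,
             fst, ev, rs,
             lam1, lam2, gA, gB, DA, DB, YA, YB, KA, KB,
             thinning, uniform_empty, t_stop):
    t = fst[0]
    capC1 = cells1.shape[0]
    capC2 = cells2.shape[0]
    capA = molA.shape[0]
    capB = molB.shape[0]
    status = STATUS_REACHED
    while t < t_stop:
        n1 = ist[0]
        n2 = ist[1]
        nmA = mstA[_NM]
        nmB = mstB[_NM]
        # room for one more cell / token of each kind
        if (n1 + 1 >= capC1 or n2 + 1 >= capC2
                or mstA[_NTOK] + 1 >= capA or mstB[_NTOK] + 1 >= capB):
            status = STATUS_GROW
            break

        if thinning:
            fA = 1.0
            fB = 1.0
        else:
            fA = nmA / (nmA + KA) if nmA > 0 else 0.0
            fB = nmB / (nmB + KB) if nmB > 0 else 0.0
        k1 = lam1 * fA * n1
        k2 = gB * n1
        k3 = lam1 * fA / YA * n1
        k4 = lam2 * fB * n2
        k5 = gA * n2
        k6 = lam2 * fB / YB * n2
        k7 = DB * nmB
        k8 = DA * nmA
        k0 = k1 + k2 + k3 + k4 + k5 + k6 + k7 + k8
        if k0 <= 0.0:
            status = STATUS_STASIS
            break

        r1 = _rand(rs)
        while r1 == 0.0:
            r1 = _rand(rs)
        target = k0 * r1
        # channels ordered so the hot diffusion channels are found first
        cum = k7 + k8
        if target <= cum:
            j = 7 if target <= k7 else 8
        else:
            cum += k1
            if target <= cum:
                j = 1
            else:
                cum += k2
                if target <= cum:
                    j = 2
                else:
                    cum += k3
                    if target <= cum:
                        j = 3
                    else:
                        cum += k4
                        if target <= cum:
                            j = 4
                        else:
                            cum += k5
                            if target <= cum:
                                j = 5
                            else:
                                j = 6

        r2 = _rand(rs)
        while r2 == 0.0:
            r2 = _rand(rs)
        t -= np.log(r2) / k0

        executed = False
        if j == 7 or j == 8:
            # diffusion (7: B, 8: A); off-lattice hops reflect (null)
            if j == 7:
                ctN, molN, mstN = ctB, molB, mstB
            else:
                ctN, molN, mstN = ctA, molA, mstA
            while True:
                i = _randint(rs, mstN[_NTOK])
                s = molN[i]
                extra = ctN[2 * s + 1] - ctN[2 * s]
                if extra > 0 and _rand(rs) * ctN[2 * s + 1] < extra:
                    # retire a lazily-deleted token and redraw
                    last = mstN[_NTOK] - 1
                    molN[i] = molN[last]
                    mstN[_NTOK] = last
                    ctN[2 * s + 1] -= 1
                    continue
                break
            x = s // N
            y = s % N
            d = _randint(rs, 4)
            inside = True
            if d == 0:
                inside = x > 0
                s2 = s - N
            elif d == 1:
                inside = x < N - 1
                s2 = s + N
            elif d == 2:
                inside = y > 0
                s2 = s - 1
            else:
                inside = y < N - 1
                s2 = s + 1
            if inside:
                molN[i] = s2
                ctN[2 * s] -= 1
                ctN[2 * s + 1] -= 1
                ctN[2 * s2] += 1
                ctN[2 * s2 + 1] += 1
                executed = True
        elif j == 1 or j == 4:
            # division
            if j == 1:
                s = cells1[_randint(rs, n1)]
                ctN = ctA
                K = KA
            else:
                s = cells2[_randint(rs, n2)]
                ctN = ctB
                K = KB
            ok = True
            if thinning:
                S = _local_sum5(ctN, s, N)
                if S == 0:
                    ok = False
                elif _rand(rs) >= S / (S + K):
                    ok = False
            if ok:
                x = s // N
                y = s % N
                if uniform_empty:
                    c0 = -1
                    c1 = -1
                    c2 = -1
                    c3 = -1
                    ne = 0
                    if x > 0 and cell[s - N] == 0:
                        c0 = s - N
                        ne += 1
                    if x < N - 1 and cell[s + N] == 0:
                        c1 = s + N
                        ne += 1
                    if y > 0 and cell[s - 1] == 0:
                        c2 = s - 1
                        ne += 1
                    if y < N - 1 and cell[s + 1] == 0:
                        c3 = s + 1
                        ne += 1
                    if ne == 0:
                        ok = False
                        s2 = -1
                    else:
                        pick = _randint(rs, ne)
                        s2 = -1
                        for cc in (c0, c1, c2, c3):
                            if cc >= 0:
                                if pick == 0:
                                    s2 = cc
                                    break
                                pick -= 1
                else:
                    d = _randint(rs, 4)
                    if d == 0:
                        ok2 = x > 0
                        s2 = s - N
                    elif d == 1:
                        ok2 = x < N - 1
                        s2 = s + N
                    elif d == 2:
                        ok2 = y > 0
                        s2 = s - 1
                    else:
                        ok2 = y < N - 1
                        s2 = s + 1
                    if not ok2 or cell[s2] != 0:
                        ok = False
                if ok:
                    x2 = s2 // N
                    y2 = s2 % N
                    if x2 == 0 or x2 == N - 1 or y2 == 0 or y2 == N - 1:
                        status = STATUS_BOUNDARY
                        fst[0] = t
                        ev[j - 1, 1] += 1
                        return status
                    if j == 1:
                        cell[s2] = 1
                        cells1[n1] = s2
                        ist[0] = n1 + 1
                    else:
                        cell[s2] = 2
                        cells2[n2] = s2
                        ist[1] = n2 + 1
                    executed = True
        elif j == 2 or j == 5:
            # excretion: species 1 -> B, species 2 -> A
            if j == 2:
                s = cells1[_randint(rs, n1)]
            else:
                s = cells2[_randint(rs, n2)]
            x = s // N
            y = s % N
            c0 = -1
            c1 = -1
            c2 = -1
            c3 = -1
            ne = 0
            if x > 0:
                c0 = s - N
                ne += 1
            if x < N - 1:
                c1 = s + N
                ne += 1
            if y > 0:
                c2 = s - 1
                ne += 1
            if y < N - 1:
                c3 = s + 1
                ne += 1
            pick = _randint(rs, ne)
            tgt = -1
            for cc in (c0, c1, c2, c3):
                if cc >= 0:
                    if pick == 0:
                        tgt = cc
                        break
                    pick -= 1
            if j == 2:
                molB[mstB[_NTOK]] = tgt
                mstB[_NTOK] += 1
                mstB[_NM] += 1
                ctB[2 * tgt] += 1
                ctB[2 * tgt + 1] += 1
            else:
                molA[mstA[_NTOK]] = tgt
                mstA[_NTOK] += 1
                mstA[_NM] += 1
                ctA[2 * tgt] += 1
                ctA[2 * tgt + 1] += 1
            executed = True
        else:
            # uptake from the 4 n.n. sites (j == 3: A by sp.1, 6: B by sp.2)
            if j == 3:
                s = cells1[_randint(rs, n1)]
                ctN = ctA
                K = KA
            else:
                s = cells2[_randint(rs, n2)]
                ctN = ctB
                K = KB
            x = s // N
            y = s % N
            v0 = ctN[2 * (s - N)] if x > 0 else 0
            v1 = ctN[2 * (s + N)] if x < N - 1 else 0
            v2 = ctN[2 * (s - 1)] if y > 0 else 0
            v3 = ctN[2 * (s + 1)] if y < N - 1 else 0
            S = np.int64(v0) + v1 + v2 + v3
            ok = S > 0
            if ok and thinning and _rand(rs) >= S / (S + K):
                ok = False
            if ok:
                u = _randint(rs, S)
                if u < v0:
                    tgt = s - N
                elif u < v0 + v1:
                    tgt = s + N
                elif u < v0 + v1 + v2:
                    tgt = s - 1
                else:
                    tgt = s + 1
                # lazy deletion: drop the count now, retire a token later
                ctN[2 * tgt] -= 1
                if j == 3:
                    mstA[_NM] -= 1
                else:
                    mstB[_NM] -= 1
                executed = True

        if executed:
            ev[j - 1, 0] += 1
        else:
            ev[j - 1, 1] += 1

    fst[0] = t
    return status


class SimState:
    """Python-side owner of the kernel arrays for one run."""

    def __init__(self, N, params):
        self.N = int(N)
        self.params = params
        self.cell = np.zeros(self.N * self.N, dtype=np.int8)
        self.cells1 = np.zeros(1024, dtype=np.int32)
        self.cells2 = np.zeros(1024, dtype=np.int32)
        self.ist = np.zeros(2, dtype=np.int64)
        self.fst = np.zeros(1, dtype=np.float64)
        self.rs = _seed_state(params.seed)
        self.event_counts = np.zeros((8, 2), dtype=np.int64)
        self._mol = {}
        for nut in ("A", "B"):
            self._mol[nut] = {
                "ct": np.zeros(2 * self.N * self.N, dtype=np.int32),
                "mol": np.zeros(1024, dtype=np.int32),
                "mst": np.zeros(2, dtype=np.int64),
            }

    # -- construction -----------------------------------------------------

    @classmethod
    def from_colony(cls, state, params):
        N = state.shape[0]
        if state.shape[0] != state.shape[1]:
            raise ValueError("lattice must be square")
        sim = cls(N, params)
        sim.cell[:] = state.cell_grid.ravel()
        sim.fst[0] = state.t
        c1 = np.flatnonzero(sim.cell == 1).astype(np.int32)
        c2 = np.flatnonzero(sim.cell == 2).astype(np.int32)
        for arr, name, cnt_idx in ((c1, "cells1", 0), (c2, "cells2", 1)):
            cap = max(2 * len(arr) + 1024, 1024)
            buf = np.zeros(cap, dtype=np.int32)
            buf[:len(arr)] = arr
            setattr(sim, name, buf)
            sim.ist[cnt_idx] = len(arr)
        for nut, grid in (("A", state.nutrient_A), ("B", state.nutrient_B)):
            m = sim._mol[nut]
            total = int(grid.sum())
            m["mol"] = np.zeros(max(2 * total + 1024, 1024), dtype=np.int32)
            m["ct"][0::2] = grid.ravel()
            _fill_tokens(m["ct"], m["mol"], m["mst"])
        sim.rs = _seed_state(params.seed)
        return sim

    # -- properties -------------------------------------------------------

    @property
    def t(self):
        return float(self.fst[0])

    @property
    def n1(self):
        return int(self.ist[0])

    @property
    def n2(self):
        return int(self.ist[1])

    @property
    def nA(self):
        return int(self._mol["A"]["mst"][_NM])

    @property
    def nB(self):
        return int(self._mol["B"]["mst"][_NM])

    def cell_grid(self):
        return self.cell.reshape(self.N, self.N)

    def to_colony(self, t=None):
        from .model import ColonyState
        return ColonyState(
            self.cell_grid().copy(),
            self._mol["A"]["ct"][0::2].reshape(self.N, self.N).astype(np.int64),
            self._mol["B"]["ct"][0::2].reshape(self.N, self.N).astype(np.int64),
            self.t if t is None else t)

    # -- running ----------------------------------------------------------

    def _grow(self):
        for name, idx in (("cells1", 0), ("cells2", 1)):
            arr = getattr(self, name)
            if self.ist[idx] + 2 >= len(arr):
                setattr(self, name, np.concatenate(
                    [arr, np.zeros(len(arr), dtype=np.int32)]))
        for nut in ("A", "B"):
            m = self._mol[nut]
            nm, ntok = int(m["mst"][_NM]), int(m["mst"][_NTOK])
            if ntok + 2 >= len(m["mol"]):
                if ntok > 2 * nm + 1024:
                    # compact: rebuild tokens from the true counts
                    m["mol"] = np.zeros(max(2 * nm + 1024, 1024),
                                        dtype=np.int32)
                    _fill_tokens(m["ct"], m["mol"], m["mst"])
                else:
                    m["mol"] = np.concatenate(
                        [m["mol"], np.zeros(len(m["mol"]), dtype=np.int32)])

    def advance_to(self, t_stop):
        p = self.params
        while True:
            mA = self._mol["A"]
            mB = self._mol["B"]
            status = _advance(
                self.cell, self.N, self.cells1, self.cells2, self.ist,
                mA["ct"], mA["mol"], mA["mst"],
                mB["ct"], mB["mol"], mB["mst"],
                self.fst, self.event_counts, self.rs,
                float(p.lambda_max_1), float(p.lambda_max_2),
                float(p.gamma_A), float(p.gamma_B),
                float(p.D_A), float(p.D_B),
                float(p.Y_A), float(p.Y_B),
                float(p.K_A), float(p.K_B),
                p.propensity_mode == "thinning",
                p.division_site_rule == "uniform-empty",
                float(t_stop))
            if status == STATUS_GROW:
                self._grow()
                continue
            return status
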