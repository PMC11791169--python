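"""Exact SSA kernel (Gillespie direct method) with array-compiled channels.

A :class:`~spatialssa.network.ReactionSystem` is flattened into numpy arrays
(channel kinds, rate constants, reactant indices, sparse state changes and a
reverse dependency map) and advanced by a numba-compiled direct-method loop:

* waiting times are exponential with the total propensity,
* the firing channel is found by cumulative-sum search in declaration order,
* after each event only the propensities that read a changed state entry are
  recomputed; the running total is refreshed by full summation every 4096
  events to keep floating-point drift bounded,
* sampling is zero-order hold: each grid time records the last state at or
  before it; a zero total propensity freezes the state without busy-waiting.

One seeded generator drives each run, so a given (system, init, seed) is
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .network import ReactionSystem, SystemState, Trajectory

__all__ = ["ssa_run", "compile_program"]

_KIND = {"mass_action": 0, "qssa_sites": 1, "qssa_protein": 3}
_METHOD_OFFSET = {"slqssa": 0, "stqssa": 1}
# kinds: 0 mass action, 1 slQSSA sites, 2 stQSSA sites,
#        3 slQSSA protein, 4 stQSSA protein


@njit(cache=True)
def _slq(dt, pt, kd):
    if dt == 0:
        return 0.0
    if pt == 0:
        return float(dt)
    l = dt - pt
    if l < 0:
        l = 0
    w = 1.0
    den = w
    num = l * w
    while l < dt:
        w = w * kd * (dt - l) / ((l + 1.0) * (pt - dt + l + 1.0))
        l += 1
        den += w
        num += l * w
    return num / den


@njit(cache=True)
def _stq(dt, pt, kd):
    a = dt - pt - kd
    x = 0.5 * (a + np.sqrt(a * a + 4.0 * kd * dt))
    if x < 0.0:
        x = 0.0
    if x > dt:
        x = float(dt)
    return x


@njit(cache=True)
def _prop(c, kind, rate, r1, r2, qdt, qkd, state):
    k = kind[c]
    if k == 0:
        a = rate[c]
        if r1[c] >= 0:
            a *= state[r1[c]]
        if r2[c] >= 0:
            a *= state[r2[c]]
        return a
    pt = state[r1[c]]
    dt = qdt[c]
    if k == 1:
        return rate[c] * _slq(dt, pt, qkd[c])
    if k == 2:
        return rate[c] * _stq(float(dt), float(pt), qkd[c])
    if k == 3:
        pq = pt - (dt - _slq(dt, pt, qkd[c]))
    else:
        pq = pt - (dt - _stq(float(dt), float(pt), qkd[c]))
    if pq < 0.0:
        pq = 0.0
    return rate[c] * pq


@njit(cache=True)
def _ssa_core(
    kind, rate, r1, r2, qdt, qkd,
    sc_ptr, sc_idx, sc_val, dep_ptr, dep_idx,
    init, grid, t_max, seed,
):
    np.random.seed(seed)
    n_ch = kind.shape[0]
    state = init.copy()
    props = np.empty(n_ch)
    total = 0.0
    for c in range(n_ch):
        props[c] = _prop(c, kind, rate, r1, r2, qdt, qkd, state)
        total += props[c]
    n_grid = grid.shape[0]
    out = np.empty((n_grid, state.shape[0]), dtype=np.int64)
    gi = 0
    t = 0.0
    since_refresh = 0
    while gi < n_grid:
        if total <= 1e-300:
            t_next = t_max + 1.0  # frozen: jump past every remaining grid time
        else:
            u = 1.0 - np.random.random()
            t_next = t + (-np.log(u) / total)
        while gi < n_grid and grid[gi] < t_next:
            out[gi, :] = state
            gi += 1
        if gi >= n_grid or total <= 1e-300 or t_next > t_max:
            if gi < n_grid and total <= 1e-300:
                # unreachable in practice (grid <= t_max < t_next) but safe
                for g in range(gi, n_grid):
                    out[g, :] = state
                gi = n_grid
            if gi >= n_grid:
                break
            if t_next > t_max:
                for g in range(gi, n_grid):
                    out[g, :] = state
                break
        # select the firing channel (cumulative-sum, declaration order)
        u2 = np.random.random() * total
        acc = 0.0
        ch = -1
        for c in range(n_ch):
            acc += props[c]
            if u2 < acc:
                ch = c
                break
        if ch < 0 or props[ch] <= 0.0:
            # float drift past the end: take the last positive channel
            ch = n_ch - 1
            while ch >= 0 and props[ch] <= 0.0:
                ch -= 1
            if ch < 0:
                total = 0.0
                continue
        for k in range(sc_ptr[ch], sc_ptr[ch + 1]):
            state[sc_idx[k]] += sc_val[k]
        for k in range(sc_ptr[ch], sc_ptr[ch + 1]):
            si = sc_idx[k]
            for m in range(dep_ptr[si], dep_ptr[si + 1]):
                d = dep_idx[m]
                newp = _prop(d, kind, rate, r1, r2, qdt, qkd, state)
                total += newp - props[d]
                props[d] = newp
        t = t_next
        since_refresh += 1
        if since_refresh >= 4096:
            since_refresh = 0
            total = 0.0
            for c in range(n_ch):
                total += props[c]
    return out


class _Program:
    """Array form of a reaction system, cached on the system object."""

    __slots__ = (
        "kind", "rate", "r1", "r2", "qdt", "qkd",
        "sc_ptr", "sc_idx", "sc_val", "dep_ptr", "dep_idx", "n_state",
    )


def compile_program(system: ReactionSystem) -> _Program:
    ns = len(system.species)
    n_state = system.n_compartments * ns
    sidx = {sp: j for j, sp in enumerate(system.species)}

    n_ch = len(system.channels)
    kind = np.zeros(n_ch, dtype=np.int64)
    rate = np.zeros(n_ch)
    r1 = np.full(n_ch, -1, dtype=np.int64)
    r2 = np.full(n_ch, -1, dtype=np.int64)
    qdt = np.zeros(n_ch, dtype=np.int64)
    qkd = np.zeros(n_ch)
    sc_ptr = np.zeros(n_ch + 1, dtype=np.int64)
    sc_idx_l, sc_val_l = [], []
    reads: list[list[int]] = [[] for _ in range(n_state)]

    for c, ch in enumerate(system.channels):
        rate[c] = ch.rate
        flat = [comp * ns + sidx[sp] for comp, sp in ch.reactants]
        if ch.kind == "mass_action":
            kind[c] = 0
            if len(flat) >= 1:
                r1[c] = flat[0]
            if len(flat) == 2:
                r2[c] = flat[1]
        else:
            kind[c] = _KIND[ch.kind] + _METHOD_OFFSET[ch.qssa_method]
            r1[c] = flat[0]
            qdt[c] = ch.qssa_dtotal
            qkd[c] = ch.qssa_kd
        for f in flat:
            if c not in reads[f]:
                reads[f].append(c)
        for comp, sp, delta in ch.changes:
            sc_idx_l.append(comp * ns + sidx[sp])
            sc_val_l.append(delta)
        sc_ptr[c + 1] = len(sc_idx_l)

    dep_ptr = np.zeros(n_state + 1, dtype=np.int64)
    dep_idx_l = []
    for s in range(n_state):
        dep_idx_l.extend(reads[s])
        dep_ptr[s + 1] = len(dep_idx_l)

    prog = _Program()
    prog.kind = kind
    prog.rate = rate
    prog.r1 = r1
    prog.r2 = r2
    prog.qdt = qdt
    prog.qkd = qkd
    prog.sc_ptr = sc_ptr
    prog.sc_idx = np.asarray(sc_idx_l, dtype=np.int64)
    prog.sc_val = np.asarray(sc_val_l, dtype=np.int64)
    prog.dep_ptr = dep_ptr
    prog.dep_idx = np.asarray(dep_idx_l, dtype=np.int64)
    prog.n_state = n_state
    return prog


_PROGRAM_CACHE: dict[int, _Program] = {}


def _program_for(system: ReactionSystem) -> _Program:
    key = id(system)
    prog = _PROGRAM_CACHE.get(key)
    if prog is None:
        if len(_PROGRAM_CACHE) > 256:
            _PROGRAM_CACHE.clear()
        prog = compile_program(system)
        _PROGRAM_CACHE[key] = prog
    return prog


def ssa_run(
    system: ReactionSystem,
    init: SystemState,
    t_max: float,
    seed: int,
    sample_grid,
) -> Trajectory:
    """Run one exact SSA trajectory, sampled on ``sample_grid``.

    ``sample_grid`` must be sorted and contained in ``[0, t_max]``.  The
    value recorded at a grid time is the last state at or before it.
    """
    grid = np.asarray(sample_grid, dtype=np.float64)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("sample_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(grid) < 0) or grid[0] < 0 or grid[-1] > t_max:
        raise ValueError("sample_grid must be sorted within [0, t_max]")
    if init.counts.shape != (system.n_compartments, len(system.species)):
        raise ValueError(
            f"init shape {init.counts.shape} does not match system "
            f"({system.n_compartments}, {len(system.species)})"
        )
    prog = _program_for(system)
    flat_init = np.ascontiguousarray(init.counts.reshape(-1), dtype=np.int64)
    out = _ssa_core(
        prog.kind, prog.rate, prog.r1, prog.r2, prog.qdt, prog.qkd,
        prog.sc_ptr, prog.sc_idx, prog.sc_val, prog.dep_ptr, prog.dep_idx,
        flat_init, grid, float(t_max), int(seed) & 0x7FFFFFFF,
    )
    if np.any(out < 0):  # defensive: propensity/update inconsistency
        raise RuntimeError("negative copy number produced; channel set invalid")
    counts = out.reshape(len(grid), system.n_compartments, len(system.species))
    return Trajectory(
        times=grid, counts=counts, species=system.species, label=system.label
    )
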