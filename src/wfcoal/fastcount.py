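"""Accelerated lineage-count-only Hudson runs.

The large-sample experiments (lineage-count explosion, long-horizon
persistence above the haploid population size) need 1e7-1e9 events, far
beyond what the recording event loop can do interactively. This module
implements the identical single-population Hudson process — span-weighted
recombination, pairwise common-ancestor events with full overlap
bookkeeping and pruning of coalesced material, exponential growth by
closed-form time inversion — as a numba kernel over preallocated arrays,
recording only the lineage count at integer generations. It is
cross-validated against the recording engine on small configurations.

Data structures: segment lists are singly linked index arrays; lineage
spans sit in a Fenwick tree for O(log k) weighted sampling; the global
overlap-count step function is a linked list with bucket fingers for
near-O(1) positional search, compacted periodically.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["hudson_lineage_counts"]

_STATUS_OK = 0
_STATUS_SEG_OVERFLOW = 1
_STATUS_LIN_OVERFLOW = 2
_STATUS_CNT_OVERFLOW = 3


@njit(cache=True)
def _run(seed, n, axis_len, n0, alpha, end_time,
         scap, lcap, ccap, nbuckets):
    np.random.seed(seed)
    # --- segments ---
    seg_l = np.empty(scap, np.float64)
    seg_r = np.empty(scap, np.float64)
    seg_nxt = np.empty(scap, np.int64)
    seg_free = np.empty(scap, np.int64)
    for i in range(scap):
        seg_free[i] = scap - 1 - i
    n_free = scap

    # --- lineages ---
    lin_head = np.full(lcap, -1, np.int64)
    lin_tail = np.full(lcap, -1, np.int64)
    lin_left = np.zeros(lcap, np.float64)
    lin_right = np.zeros(lcap, np.float64)
    slots = np.empty(lcap, np.int64)       # dense active list
    slot_pos = np.full(lcap, -1, np.int64)
    lin_free = np.empty(lcap, np.int64)
    for i in range(lcap):
        lin_free[i] = lcap - 1 - i
    n_lin_free = lcap
    k = 0

    # --- Fenwick over lineage slots ---
    fen = np.zeros(lcap + 1, np.float64)
    fenv = np.zeros(lcap, np.float64)
    total_mass = 0.0
    fbits = 0
    while (1 << fbits) <= lcap:
        fbits += 1

    # --- overlap counter: linked list with bucket fingers ---
    cpos = np.empty(ccap, np.float64)
    cval = np.empty(ccap, np.int64)
    cnxt = np.empty(ccap, np.int64)
    cpos[0] = 0.0
    cval[0] = n
    cnxt[0] = 1
    cpos[1] = axis_len
    cval[1] = 0
    cnxt[1] = -1
    calloc = 2
    bwidth = axis_len / nbuckets
    fingers = np.zeros(nbuckets, np.int64)
    splits_since = 0

    trace_len = int(end_time) + 1
    trace = np.zeros(trace_len, np.int64)
    # diagnostics: recombinations, CA events, counter walk steps, segment
    # walk steps, compactions, finger rebuilds, counter allocs, total segs
    diag = np.zeros(8, np.int64)

    # initialise sample lineages
    for i in range(n):
        s = seg_free[n_free - 1]
        n_free -= 1
        seg_l[s] = 0.0
        seg_r[s] = axis_len
        seg_nxt[s] = -1
        slot = lin_free[n_lin_free - 1]
        n_lin_free -= 1
        lin_head[slot] = s
        lin_tail[slot] = s
        lin_left[slot] = 0.0
        lin_right[slot] = axis_len
        slot_pos[slot] = k
        slots[k] = slot
        k += 1
        # fenwick add
        delta = axis_len - fenv[slot]
        fenv[slot] = axis_len
        j = slot + 1
        while j <= lcap:
            fen[j] += delta
            j += j & (-j)
        total_mass += delta

    t = 0.0
    next_trace = 0.0
    status = _STATUS_OK

    while True:
        # trace recording up to current time
        while next_trace <= t and next_trace < trace_len:
            trace[int(next_trace)] = k
            next_trace += 1.0
        if k <= 1 or t >= end_time:
            break

        # waiting times
        t_rec = np.inf
        if total_mass > 1e-12:
            t_rec = t + np.random.exponential(1.0) / total_mass
        t_ca = np.inf
        if k >= 2:
            pairs = 0.5 * k * (k - 1.0)
            e = np.random.exponential(1.0)
            rate0 = pairs / (2.0 * n0 * np.exp(-alpha * t))
            if alpha == 0.0:
                t_ca = t + e / rate0
            else:
                arg = 1.0 + alpha * e / rate0
                if arg > 0.0:
                    t_ca = t + np.log(arg) / alpha
        t_event = t_rec if t_rec < t_ca else t_ca
        boundary = next_trace if next_trace < end_time else end_time
        if t_event >= boundary:
            t = boundary
            continue
        t = t_event

        if t_rec < t_ca:
            # ---- recombination ----
            diag[0] += 1
            u = np.random.random() * total_mass
            idx = 0
            bit = 1 << (fbits - 1)
            while bit > 0:
                nx = idx + bit
                if nx <= lcap and fen[nx] <= u:
                    u -= fen[nx]
                    idx = nx
                bit >>= 1
            slot = idx
            if slot >= lcap or lin_head[slot] < 0:
                continue
            span = lin_right[slot] - lin_left[slot]
            x = lin_left[slot] + np.random.random() * span
            if x <= lin_left[slot] or x >= lin_right[slot]:
                continue
            # walk segments to the split point
            s = lin_head[slot]
            prev = -1
            while s != -1 and seg_r[s] <= x:
                prev = s
                s = seg_nxt[s]
                diag[3] += 1
            if s == -1:
                continue
            orig_tail = lin_tail[slot]
            if seg_l[s] < x:
                # split inside segment s
                if n_free == 0:
                    status = _STATUS_SEG_OVERFLOW
                    break
                s2 = seg_free[n_free - 1]
                n_free -= 1
                seg_l[s2] = x
                seg_r[s2] = seg_r[s]
                seg_nxt[s2] = seg_nxt[s]
                seg_r[s] = x
                seg_nxt[s] = -1
                right_head = s2
                right_tail = s2 if orig_tail == s else orig_tail
                left_tail = s
                new_left_right = x
            else:
                # x falls in a trapped gap before segment s
                if prev == -1:
                    continue
                seg_nxt[prev] = -1
                right_head = s
                right_tail = orig_tail
                left_tail = prev
                new_left_right = seg_r[prev]
            if n_lin_free == 0:
                status = _STATUS_LIN_OVERFLOW
                break
            nslot = lin_free[n_lin_free - 1]
            n_lin_free -= 1
            lin_head[nslot] = right_head
            lin_tail[nslot] = right_tail
            lin_tail[slot] = left_tail
            lin_left[nslot] = seg_l[right_head]
            old_right = lin_right[slot]
            lin_right[nslot] = old_right
            lin_right[slot] = new_left_right
            slot_pos[nslot] = k
            slots[k] = nslot
            k += 1
            # fenwick updates
            v = lin_right[slot] - lin_left[slot]
            delta = v - fenv[slot]
            fenv[slot] = v
            j = slot + 1
            while j <= lcap:
                fen[j] += delta
                j += j & (-j)
            total_mass += delta
            v = old_right - seg_l[right_head]
            delta = v - fenv[nslot]
            fenv[nslot] = v
            j = nslot + 1
            while j <= lcap:
                fen[j] += delta
                j += j & (-j)
            total_mass += delta
        else:
            # ---- common ancestor ----
            diag[1] += 1
            i1 = np.random.randint(0, k)
            i2 = np.random.randint(0, k - 1)
            if i2 >= i1:
                i2 += 1
            sx = slots[i1]
            sy = slots[i2]
            # fast path: spans don't overlap -> concatenate lists in O(1)
            if lin_right[sx] <= lin_left[sy] or lin_right[sy] <= lin_left[sx]:
                if lin_right[sy] <= lin_left[sx]:
                    sx, sy = sy, sx
                seg_nxt[lin_tail[sx]] = lin_head[sy]
                lin_tail[sx] = lin_tail[sy]
                lin_right[sx] = lin_right[sy]
                # drop sy
                p2 = slot_pos[sy]
                last = slots[k - 1]
                slots[p2] = last
                slot_pos[last] = p2
                k -= 1
                slot_pos[sy] = -1
                lin_head[sy] = -1
                lin_tail[sy] = -1
                lin_free[n_lin_free] = sy
                n_lin_free += 1
                delta = -fenv[sy]
                fenv[sy] = 0.0
                j = sy + 1
                while j <= lcap:
                    fen[j] += delta
                    j += j & (-j)
                total_mass += delta
                v = lin_right[sx] - lin_left[sx]
                delta = v - fenv[sx]
                fenv[sx] = v
                j = sx + 1
                while j <= lcap:
                    fen[j] += delta
                    j += j & (-j)
                total_mass += delta
                continue
            x = lin_head[sx]
            y = lin_head[sy]
            out_head = -1
            out_tail = -1
            overflow = False
            while x != -1 or y != -1:
                take_plain = -1
                if x == -1:
                    take_plain = y
                    y = seg_nxt[y]
                elif y == -1:
                    take_plain = x
                    x = seg_nxt[x]
                elif seg_r[x] <= seg_l[y]:
                    take_plain = x
                    x = seg_nxt[x]
                elif seg_r[y] <= seg_l[x]:
                    take_plain = y
                    y = seg_nxt[y]
                else:
                    # overlap piece
                    a = seg_l[x] if seg_l[x] > seg_l[y] else seg_l[y]
                    b = seg_r[x] if seg_r[x] < seg_r[y] else seg_r[y]
                    # left non-overlap parts pass through
                    if seg_l[x] < a:
                        if n_free == 0:
                            overflow = True
                            break
                        sp = seg_free[n_free - 1]
                        n_free -= 1
                        seg_l[sp] = seg_l[x]
                        seg_r[sp] = a
                        seg_nxt[sp] = -1
                        if out_tail == -1:
                            out_head = sp
                        else:
                            if seg_r[out_tail] == seg_l[sp]:
                                seg_r[out_tail] = seg_r[sp]
                                seg_free[n_free] = sp
                                n_free += 1
                                sp = out_tail
                            else:
                                seg_nxt[out_tail] = sp
                        out_tail = sp
                        seg_l[x] = a
                    if seg_l[y] < a:
                        if n_free == 0:
                            overflow = True
                            break
                        sp = seg_free[n_free - 1]
                        n_free -= 1
                        seg_l[sp] = seg_l[y]
                        seg_r[sp] = a
                        seg_nxt[sp] = -1
                        if out_tail == -1:
                            out_head = sp
                        else:
                            if seg_r[out_tail] == seg_l[sp]:
                                seg_r[out_tail] = seg_r[sp]
                                seg_free[n_free] = sp
                                n_free += 1
                                sp = out_tail
                            else:
                                seg_nxt[out_tail] = sp
                        out_tail = sp
                        seg_l[y] = a
                    # --- counter: decrement [a, b) by 1, collect survivors
                    bidx = int(a / bwidth)
                    if bidx >= nbuckets:
                        bidx = nbuckets - 1
                    ci = fingers[bidx]
                    if cpos[ci] > a:
                        ci = 0
                    nx = cnxt[ci]
                    while nx != -1 and cpos[nx] <= a:
                        ci = nx
                        nx = cnxt[ci]
                        diag[2] += 1
                    # ci: last node with pos <= a. Tighten the finger: ci is
                    # a valid start for this bucket whenever it sits in an
                    # earlier bucket
                    if cpos[ci] < bidx * bwidth:
                        fingers[bidx] = ci
                    # split at a
                    if cpos[ci] < a:
                        if calloc >= ccap:
                            overflow = True
                            break
                        cj = calloc
                        calloc += 1
                        cpos[cj] = a
                        cval[cj] = cval[ci]
                        cnxt[cj] = cnxt[ci]
                        cnxt[ci] = cj
                        ci = cj
                        splits_since += 1
                    # walk pieces until b
                    while cpos[ci] < b:
                        nx = cnxt[ci]
                        pend = cpos[nx] if nx != -1 else axis_len
                        if pend > b:
                            # split at b
                            if calloc >= ccap:
                                overflow = True
                                break
                            cj = calloc
                            calloc += 1
                            cpos[cj] = b
                            cval[cj] = cval[ci]
                            cnxt[cj] = cnxt[ci]
                            cnxt[ci] = cj
                            pend = b
                            nx = cj
                            splits_since += 1
                        c = cval[ci]
                        if c - 1 <= 1:
                            cval[ci] = 0  # fully coalesced here
                        else:
                            cval[ci] = c - 1
                            # surviving piece [cpos[ci], pend)
                            if n_free == 0:
                                overflow = True
                                break
                            sp = seg_free[n_free - 1]
                            n_free -= 1
                            seg_l[sp] = cpos[ci]
                            seg_r[sp] = pend
                            seg_nxt[sp] = -1
                            if out_tail == -1:
                                out_head = sp
                            else:
                                if seg_r[out_tail] == seg_l[sp]:
                                    seg_r[out_tail] = seg_r[sp]
                                    seg_free[n_free] = sp
                                    n_free += 1
                                    sp = out_tail
                                else:
                                    seg_nxt[out_tail] = sp
                            out_tail = sp
                        if nx == -1:
                            break
                        ci = nx
                    if overflow:
                        break
                    # consume the overlapped parts
                    if seg_r[x] > b:
                        seg_l[x] = b
                    else:
                        ox = x
                        x = seg_nxt[x]
                        seg_free[n_free] = ox
                        n_free += 1
                    if seg_r[y] > b:
                        seg_l[y] = b
                    else:
                        oy = y
                        y = seg_nxt[y]
                        seg_free[n_free] = oy
                        n_free += 1
                    continue
                # plain pass-through of take_plain
                seg_nxt[take_plain] = -1
                if out_tail == -1:
                    out_head = take_plain
                    out_tail = take_plain
                else:
                    if seg_r[out_tail] == seg_l[take_plain]:
                        seg_r[out_tail] = seg_r[take_plain]
                        seg_free[n_free] = take_plain
                        n_free += 1
                    else:
                        seg_nxt[out_tail] = take_plain
                        out_tail = take_plain
            if overflow:
                status = _STATUS_CNT_OVERFLOW if calloc >= ccap else _STATUS_SEG_OVERFLOW
                break
            # remove sy from active set (keep sx as the merged lineage)
            p2 = slot_pos[sy]
            last = slots[k - 1]
            slots[p2] = last
            slot_pos[last] = p2
            k -= 1
            slot_pos[sy] = -1
            lin_head[sy] = -1
            lin_tail[sy] = -1
            lin_free[n_lin_free] = sy
            n_lin_free += 1
            delta = -fenv[sy]
            fenv[sy] = 0.0
            j = sy + 1
            while j <= lcap:
                fen[j] += delta
                j += j & (-j)
            total_mass += delta
            if out_head == -1:
                # merged lineage empty: remove sx too
                p1 = slot_pos[sx]
                last = slots[k - 1]
                slots[p1] = last
                slot_pos[last] = p1
                k -= 1
                slot_pos[sx] = -1
                lin_head[sx] = -1
                lin_tail[sx] = -1
                lin_free[n_lin_free] = sx
                n_lin_free += 1
                delta = -fenv[sx]
                fenv[sx] = 0.0
                j = sx + 1
                while j <= lcap:
                    fen[j] += delta
                    j += j & (-j)
                total_mass += delta
            else:
                lin_head[sx] = out_head
                lin_tail[sx] = out_tail
                lin_left[sx] = seg_l[out_head]
                lin_right[sx] = seg_r[out_tail]
                v = lin_right[sx] - lin_left[sx]
                delta = v - fenv[sx]
                fenv[sx] = v
                j = sx + 1
                while j <= lcap:
                    fen[j] += delta
                    j += j & (-j)
                total_mass += delta

        # cheap frequent finger rebuild (searches otherwise degrade to a
        # full list walk as inserts accumulate past stale fingers)
        if splits_since > 4096 + (calloc >> 5) and not (calloc > ccap - 8):
            diag[5] += 1
            splits_since = 0
            ci = 0
            for bi in range(nbuckets):
                target = bi * bwidth
                nx = cnxt[ci]
                while nx != -1 and cpos[nx] <= target:
                    ci = nx
                    nx = cnxt[ci]
                fingers[bi] = ci

        # periodic counter compaction + finger rebuild
        if calloc > ccap - 8 or splits_since > (ccap >> 2):
            diag[4] += 1
            # compact: copy live chain dropping redundant equal-value nodes
            np_pos = np.empty(ccap, np.float64)
            np_val = np.empty(ccap, np.int64)
            m = 0
            ci = 0
            lastval = -12345
            while ci != -1:
                if cval[ci] != lastval or ci == 0:
                    np_pos[m] = cpos[ci]
                    np_val[m] = cval[ci]
                    lastval = cval[ci]
                    m += 1
                ci = cnxt[ci]
            if m >= ccap - 8:
                status = _STATUS_CNT_OVERFLOW
                break
            for i2 in range(m):
                cpos[i2] = np_pos[i2]
                cval[i2] = np_val[i2]
                cnxt[i2] = i2 + 1
            cnxt[m - 1] = -1
            calloc = m
            splits_since = 0
            # rebuild fingers
            ci = 0
            for bi in range(nbuckets):
                target = bi * bwidth
                nx = cnxt[ci]
                while nx != -1 and cpos[nx] <= target:
                    ci = nx
                    nx = cnxt[ci]
                fingers[bi] = ci

    diag[6] = calloc
    diag[7] = k
    return status, trace, diag


def hudson_lineage_counts(seed: int, num_samples: int, axis_length: float,
                          n0: float, growth_rate: float, end_time: float,
                          seg_capacity: int = 1 << 22,
                          lineage_capacity: int = 1 << 18,
                          counter_capacity: int = 1 << 21,
                          buckets: int = 1 << 13) -> np.ndarray:
    """Lineage count at each integer generation 0..end_time under Hudson's
    coalescent for a single population of diploid size
    ``n0 * exp(-growth_rate * t)`` on a uniform axis of ``axis_length``
    Morgans (multi-chromosome maps enter via their spacered axis length).
    """
    status, trace, diag = _run(int(seed) & 0x7FFFFFFF, int(num_samples),
                               float(axis_length), float(n0), float(growth_rate),
                               float(end_time), seg_capacity, lineage_capacity,
                               counter_capacity, buckets)
    if status != _STATUS_OK:
        raise RuntimeError(f"fastcount capacity exceeded (status {status})")
    return trace
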