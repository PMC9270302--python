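"""Independent brute-force oracles for the core trace operations.

Everything here is written as plain loops over the grid, deliberately
avoiding the vectorised code paths of the package, so that agreement is a
meaningful check rather than a tautology.
"""

from __future__ import annotations

import math


def interp(xs, ys, x: float) -> float:
    """Piecewise-linear evaluation by explicit segment search."""
    if x <= xs[0]:
        return float(ys[0])
    if x >= xs[-1]:
        return float(ys[-1])
    for i in range(len(xs) - 1):
        if xs[i] <= x <= xs[i + 1]:
            w = (x - xs[i]) / (xs[i + 1] - xs[i])
            return float(ys[i] + w * (ys[i + 1] - ys[i]))
    raise AssertionError("unreachable")


def max_drop(xs, ys, window: float) -> tuple[float, float]:
    """Exhaustive window scan over every grid start position."""
    tvl = xs[-1]
    if tvl <= window:
        return float(ys[0] - ys[-1]), 0.0
    best_drop, best_start = -math.inf, None
    for i in range(len(xs)):
        s = xs[i]
        if s > tvl - window + 1e-9:
            break
        drop = ys[i] - interp(xs, ys, s + window)
        if drop > best_drop + 1e-15:
            best_drop, best_start = drop, s
    return float(best_drop), float(best_start)


def diseased_segments(xs, ys, slope_eps: float, merge_gap: float):
    """Per-cell thresholding followed by interval merging, cell by cell."""
    segs = []
    for i in range(len(xs) - 1):
        dx = xs[i + 1] - xs[i]
        if (ys[i] - ys[i + 1]) / dx > slope_eps:
            if segs and xs[i] - segs[-1][1] < merge_gap:
                segs[-1][1] = xs[i + 1]
            elif segs and abs(xs[i] - segs[-1][1]) < 1e-12:
                segs[-1][1] = xs[i + 1]
            else:
                segs.append([xs[i], xs[i + 1]])
    lfd = sum(e - s for s, e in segs)
    return float(lfd), [(float(s), float(e)) for s, e in segs]


def _has_plateau(xs, ys, lo, hi, sep, tol=0.01):
    if hi - lo < sep - 1e-9:
        return False
    starts = [x for x in xs if lo - 1e-9 <= x <= hi - sep + 1e-9] or [lo]
    for s in starts:
        if interp(xs, ys, s) - interp(xs, ys, s + sep) < tol:
            return True
    return False


def detect_events(
    xs,
    ys,
    focal_min_drop=0.05,
    focal_max_span=10.0,
    diffuse_min_len=15.0,
    diffuse_min_drop=0.05,
    separation=5.0,
    slope_eps=0.002,
    merge_gap=2.0,
    diffuse_merge_gap=6.0,
):
    """Exhaustive candidate enumeration + greedy selection, re-implemented
    with plain lists; returns (focal, diffuse) as lists of (start, end, drop)."""
    cands = []
    n = len(xs)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if xs[j] - xs[i] > focal_max_span + 1e-9:
                break
            d = ys[i] - ys[j]
            if d >= focal_min_drop - 1e-12:
                cands.append((float(xs[i]), float(xs[j]), float(d)))
    cands.sort(key=lambda c: (-c[2], c[1] - c[0], c[0]))
    chosen = []
    for s, e, d in cands:
        ok = True
        for fs, fe, _ in chosen:
            if not (e <= fs or s >= fe):
                ok = False
                break
            lo, hi = (e, fs) if e <= fs else (fe, s)
            if not _has_plateau(xs, ys, lo, hi, separation):
                ok = False
                break
        if ok:
            chosen.append((s, e, d))
    chosen.sort()

    _, segs = diseased_segments(xs, ys, slope_eps, merge_gap)
    pieces = []
    for s, e in segs:
        parts = [(s, e)]
        for hs, he, _ in chosen:
            nxt = []
            for ps, pe in parts:
                if he <= ps or hs >= pe:
                    nxt.append((ps, pe))
                else:
                    if ps < hs:
                        nxt.append((ps, hs))
                    if he < pe:
                        nxt.append((he, pe))
            parts = nxt
        pieces.extend(p for p in parts if p[1] - p[0] > 1e-9)
    pieces.sort()
    merged = []
    for s, e in pieces:
        if merged and s - merged[-1][1] < diffuse_merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    diffuse = []
    for s, e in merged:
        d = interp(xs, ys, s) - interp(xs, ys, e)
        if e - s >= diffuse_min_len - 1e-9 and d >= diffuse_min_drop - 1e-12:
            diffuse.append((float(s), float(e), float(d)))
    return chosen, diffuse


def roc_scan(scores, events, direction_low=True):
    """Exhaustive threshold enumeration for the max(sens+spec) cutoff and a
    Mann-Whitney AUC (with tie correction) — two routes independent of the
    package's trapezoid/midpoint implementation."""
    s = [float(v) for v in scores]
    y = [bool(v) for v in events]
    pos = [v for v, e in zip(s, y) if e]
    neg = [v for v, e in zip(s, y) if not e]
    # Mann-Whitney AUC: probability a random event scores on the event side
    wins = 0.0
    for a in pos:
        for b in neg:
            if (a < b if direction_low else a > b):
                wins += 1.0
            elif a == b:
                wins += 0.5
    auc = wins / (len(pos) * len(neg))

    distinct = sorted(set(s))
    cuts = [distinct[0] - 1.0]
    cuts += [(u + v) / 2 for u, v in zip(distinct[:-1], distinct[1:])]
    cuts += [distinct[-1] + 1.0]
    best = None
    for c in cuts:
        if direction_low:
            k = sum(1 for v in pos if v <= c)
            m = sum(1 for v in neg if v > c)
        else:
            k = sum(1 for v in pos if v >= c)
            m = sum(1 for v in neg if v < c)
        # youden index as an exact fraction: k/P + m/N = (k*N + m*P)/(P*N)
        key = (k * len(neg) + m * len(pos), -c)  # ties toward smaller threshold
        if best is None or key > best[0]:
            best = (key, c, k / len(pos), m / len(neg))
    _, cutoff, sens, spec = best
    return auc, cutoff, sens, spec


def fisher_enumerate_2xc(table):
    """Exact Fisher p for a 2×c table by full enumeration of tables with the
    observed margins; p = total probability of tables no more probable than
    the observed one."""
    rows = [sum(r) for r in table]
    cols = [table[0][j] + table[1][j] for j in range(len(table[0]))]
    n = sum(rows)

    def log_fact(k):
        return math.lgamma(k + 1)

    const = sum(log_fact(r) for r in rows) + sum(log_fact(c) for c in cols) - log_fact(n)

    def logp(first_row):
        lp = const
        for j, c in enumerate(cols):
            a = first_row[j]
            lp -= log_fact(a) + log_fact(c - a)
        return lp

    obs_lp = logp(table[0])
    total = 0.0
    c = len(cols)

    def rec(j, remaining, row):
        nonlocal total
        if j == c:
            if remaining == 0:
                lp = logp(row)
                if lp <= obs_lp + 1e-9:
                    total += math.exp(lp)
            return
        for a in range(0, min(cols[j], remaining) + 1):
            rec(j + 1, remaining - a, row + [a])

    rec(0, rows[0], [])
    return total
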