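"""Independent brute-force / exhaustive oracles used by the test suite.

Each oracle recomputes a statistic from its definition by enumeration or
linear programming, independently of the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog


def dip_lp(x) -> float:
    """Dip by exhaustive search over unimodal fits, via linear programming.

    For every candidate mode (each distinct data value, allowing an atom at
    the mode), the closest unimodal cdf is found as an LP over its values at
    the data points: piecewise-linear cdfs with kinks at data points are
    sup-norm optimal because the ECDF is constant between data points, and
    value-feasibility of a convex (concave) piece is equivalent to monotone
    chord slopes.  The dip is the smallest optimum over modes.
    """
    x = np.asarray(x, dtype=float)
    v, counts = np.unique(x, return_counts=True)
    c = np.cumsum(counts)
    n = c[-1]
    b = c / n          # ECDF value at v_i
    a = (c - counts) / n  # ECDF left limit at v_i
    K = len(v)
    if K == 1:
        return 0.0
    best = np.inf
    for j in range(K):
        # variables: g_0..g_{K-1} plus g_j split into (g_j^-, g_j^+) -> use
        # vars y_0..y_K where y_j = g_j^-, y_{j+1} = g_j^+, rest shifted.
        # positions of the variables on the x-axis:
        pos = np.concatenate([v[: j + 1], v[j:]])
        nvar = K + 1  # plus d as the last LP variable
        A_ub, b_ub = [], []

        def row(coefs: dict[int, float], rhs: float):
            r = [0.0] * (nvar + 1)
            for idx, cf in coefs.items():
                r[idx] = cf
            A_ub.append(r)
            b_ub.append(rhs)

        iminus, iplus = j, j + 1

        def var(i: int) -> int:  # index of g_i (right-piece copy for i > j)
            return i if i < j else i + 1

        # band constraints |g_i - b_i| <= d and |g_i - a_i| <= d
        for i in range(K):
            if i == j:
                # left-limit band on g_j^-, right-value band on g_j^+
                row({iminus: 1.0, nvar: -1.0}, a[i])
                row({iminus: -1.0, nvar: -1.0}, -a[i])
                row({iplus: 1.0, nvar: -1.0}, b[i])
                row({iplus: -1.0, nvar: -1.0}, -b[i])
            else:
                gi = var(i)
                row({gi: 1.0, nvar: -1.0}, a[i])
                row({gi: -1.0, nvar: -1.0}, -b[i])
                row({gi: 1.0, nvar: -1.0}, b[i])
                row({gi: -1.0, nvar: -1.0}, -a[i])
        # monotonicity over consecutive variables (includes g_j^- <= g_j^+)
        for t in range(nvar - 1):
            row({t: 1.0, t + 1: -1.0}, 0.0)
        # convex chords left of the mode: slopes nondecreasing up to g_j^-
        left_idx = list(range(0, j + 1))  # variables 0..j at pos v_0..v_j
        for t in range(len(left_idx) - 2):
            i0, i1, i2 = left_idx[t], left_idx[t + 1], left_idx[t + 2]
            d10 = pos[i1] - pos[i0]
            d21 = pos[i2] - pos[i1]
            # (g1-g0)/d10 <= (g2-g1)/d21
            row({i0: -d21, i1: (d21 + d10), i2: -d10}, 0.0)
        # concave chords right of the mode: slopes nonincreasing from g_j^+
        right_idx = list(range(j + 1, nvar))
        for t in range(len(right_idx) - 2):
            i0, i1, i2 = right_idx[t], right_idx[t + 1], right_idx[t + 2]
            d10 = pos[i1] - pos[i0]
            d21 = pos[i2] - pos[i1]
            # (g1-g0)/d10 >= (g2-g1)/d21
            row({i0: d21, i1: -(d21 + d10), i2: d10}, 0.0)
        cvec = [0.0] * nvar + [1.0]
        bounds = [(0.0, 1.0)] * nvar + [(0.0, 1.0)]
        res = linprog(cvec, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds)
        if res.status != 0:
            raise RuntimeError(f"LP failed at mode {j}: {res.message}")
        best = min(best, res.fun)
    return float(best)


def ks_enumeration(x, y) -> tuple[float, float]:
    """Exact two-sample K-S p by enumeration of all label assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    nx, ny = len(x), len(y)
    pooled = x + y

    def ks_stat(xs, ys):
        grid = sorted(set(xs) | set(ys))
        d = 0.0
        for g in grid:
            fx = sum(v <= g for v in xs) / len(xs)
            fy = sum(v <= g for v in ys) / len(ys)
            d = max(d, abs(fx - fy))
        return d

    obs = ks_stat(x, y)
    count = total = 0
    for idx in itertools.combinations(range(nx + ny), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(nx + ny) if i not in idx]
        total += 1
        if ks_stat(xs, ys) >= obs - 1e-12:
            count += 1
    return obs, count / total


def ranksum_enumeration(x, y) -> float:
    """Exact one-sided (x greater) rank-sum p by permutation enumeration."""
    x = list(map(float, x))
    y = list(map(float, y))
    nx = len(x)
    pooled = x + y

    def rank_sum_x(idx):
        order = sorted(range(len(pooled)), key=lambda i: pooled[i])
        # midranks
        ranks = [0.0] * len(pooled)
        i = 0
        while i < len(order):
            k = i
            while k + 1 < len(order) and pooled[order[k + 1]] == pooled[order[i]]:
                k += 1
            mid = (i + k) / 2 + 1
            for t in range(i, k + 1):
                ranks[order[t]] = mid
            i = k + 1
        return sum(ranks[i] for i in idx)

    obs = rank_sum_x(range(nx))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if rank_sum_x(idx) >= obs - 1e-12:
            count += 1
    return count / total


def fisher_two_sided(a: int, bq: int, c: int, d: int) -> float:
    """Two-sided exact p: sum of hypergeometric probabilities <= observed."""
    from scipy.stats import hypergeom

    n = a + bq + c + d
    row1 = a + bq
    col1 = a + c
    rv = hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def brute_force_overlaps(a_df, b_df, slop=0, min_overlap=1):
    """O(n*m) overlap flags for interval tracks."""
    flags = []
    for _, ra in a_df.iterrows():
        hit = False
        for _, rb in b_df.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            lo = max(ra["start"], rb["start"] - slop)
            hi = min(ra["end"], rb["end"] + slop)
            if hi - lo >= min_overlap:
                hit = True
                break
        flags.append(hit)
    return np.array(flags)


def brute_force_closest(a_df, b_df):
    dists = []
    for _, ra in a_df.iterrows():
        best = math.inf
        for _, rb in b_df.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            if min(ra["end"], rb["end"]) > max(ra["start"], rb["start"]):
                d = 0
            elif rb["end"] <= ra["start"]:
                d = ra["start"] - rb["end"]
            else:
                d = rb["start"] - ra["end"]
            best = min(best, d)
        dists.append(best)
    return np.array(dists, dtype=float)


def brute_force_tracts(segment: str, min_copies: float, min_tract_bp: int):
    """All maximal periodic runs by per-position extension, O(L^2)."""
    seq = segment.upper()
    n = len(seq)
    found = set()
    for m in range(1, 7):
        i = 0
        while i + 2 * m <= n:
            if seq[i + m] != seq[i]:
                i += 1
                continue
            # extend the run of s[k] == s[k+m] starting at i
            j = i
            while j + m < n and seq[j] == seq[j + m]:
                j += 1
            tract_len = (j - i) + m
            unit = seq[i : i + m]
            prim = unit
            for p in range(1, m):
                if m % p == 0 and unit == unit[:p] * (m // p):
                    prim = unit[:p]
                    break
            if prim == unit and tract_len / m >= min_copies and tract_len >= min_tract_bp:
                found.add((i, i + tract_len, m))
            i = j + 1  # next maximal run for this m
    return found


def brute_force_scan(seq: str, logodds: np.ndarray, threshold: float, both: bool):
    """Score every window of every strand explicitly."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    L = logodds.shape[1]
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    strands = ["+", "-"] if both else ["+"]
    for strand in strands:
        s = seq if strand == "+" else "".join(comp[c] for c in reversed(seq))
        for off in range(len(s) - L + 1):
            window = s[off : off + L]
            if any(c not in idx for c in window):
                continue
            score = sum(logodds[idx[c], p] for p, c in enumerate(window))
            if score >= threshold:
                pos = off if strand == "+" else len(seq) - L - off
                hits.append((pos, strand, round(score, 9)))
    return set(hits)
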