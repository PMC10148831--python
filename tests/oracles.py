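"""Naive reference implementations used only to cross-check the package.

Each oracle restates the defining rule as directly as possible (explicit
loops, exhaustive enumeration) and shares no code with the implementation
under test.
"""

import math

import numpy as np


def choi_wear_oracle(counts, window=90, artifact_max=2, flank=30):
    """Brute-force non-wear marking over the zero-run structure.

    Enumerates maximal zero(ish) runs, checks every junction between
    consecutive runs against the artifact rule, and marks every chained
    span whose total length reaches the window.  Missing epochs count as
    zeros and are non-wear regardless.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    zeroish = [bool(np.isnan(c) or c == 0) for c in counts]

    runs = []
    i = 0
    while i < n:
        if zeroish[i]:
            j = i
            while j < n and zeroish[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1

    nonwear = [False] * n
    for a in range(len(runs)):
        for b in range(a, len(runs)):
            ok = True
            for k in range(a, b):
                gap = runs[k + 1][0] - runs[k][1]
                left = runs[k][1] - runs[k][0]
                right = runs[k + 1][1] - runs[k + 1][0]
                if not (gap <= artifact_max and left >= flank and right >= flank):
                    ok = False
                    break
            if ok and runs[b][1] - runs[a][0] >= window:
                for e in range(runs[a][0], runs[b][1]):
                    nonwear[e] = True
    for e in range(n):
        if np.isnan(counts[e]):
            nonwear[e] = True
    return ~np.array(nonwear)


def window_mean_oracle(day, width, mode):
    """Exhaustive scan of every window start with python loops."""
    best_mean, best_start = None, None
    for start in range(len(day) - width + 1):
        vals = [v for v in day[start : start + width] if not math.isnan(v)]
        if len(vals) < 0.75 * width:
            continue
        mean = sum(vals) / len(vals)
        if best_mean is None:
            best_mean, best_start = mean, start
        elif (mode == "most" and mean > best_mean) or (
            mode == "least" and mean < best_mean
        ):
            best_mean, best_start = mean, start
    return best_mean, best_start


def iv_oracle(x):
    """Direct summation of the intradaily-variability definition."""
    x = list(np.asarray(x, dtype=float))
    obs = [v for v in x if not math.isnan(v)]
    n = len(obs)
    mean = sum(obs) / n
    num_terms = []
    for i in range(1, len(x)):
        if not math.isnan(x[i]) and not math.isnan(x[i - 1]):
            num_terms.append((x[i] - x[i - 1]) ** 2)
    msd = sum(num_terms) / len(num_terms)
    var = sum((v - mean) ** 2 for v in obs) / n
    return msd / var


def is_oracle(x, s=24):
    """Direct summation of the interdaily-stability definition."""
    x = list(np.asarray(x, dtype=float))
    obs = [(i, v) for i, v in enumerate(x) if not math.isnan(v)]
    n = len(obs)
    grand = sum(v for _, v in obs) / n
    between = 0.0
    s_realized = 0
    for h in range(s):
        vals = [v for i, v in obs if i % s == h]
        if vals:
            between += (sum(vals) / len(vals) - grand) ** 2
            s_realized += 1
    total = sum((v - grand) ** 2 for _, v in obs)
    return n * between / (s_realized * total)


def fisher_exact_oracle(table):
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def prob(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-12))


def spearman_oracle(x, y):
    """Rank correlation from midranks via the Pearson formula."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
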