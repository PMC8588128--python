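"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit Python loops and elementary
operations only, deliberately sharing no code with the package.
"""

import math


def vr_oracle(P):
    T = len(P)
    modes = []
    for row in P:
        best, best_j = -1.0, 0
        for j, p in enumerate(row):
            if p > best:
                best, best_j = p, j
        modes.append(best_j)
    counts = {}
    for c in modes:
        counts[c] = counts.get(c, 0) + 1
    f = max(counts.values())
    return 1.0 - f / T


def entropy_oracle(p):
    h = 0.0
    for pj in p:
        if pj > 0:
            h -= pj * math.log2(pj)
    return h


def mean_row_oracle(P):
    C = len(P[0])
    return [sum(row[j] for row in P) / len(P) for j in range(C)]


def mi_oracle(P):
    p_star = mean_row_oracle(P)
    mean_h = sum(entropy_oracle(row) for row in P) / len(P)
    return entropy_oracle(p_star) - mean_h


def vtot_oracle(P):
    p_star = mean_row_oracle(P)
    T, C = len(P), len(P[0])
    tot = 0.0
    for j in range(C):
        for row in P:
            tot += (row[j] - p_star[j]) ** 2
    return tot / T


def margin_oracle(P):
    p_star = mean_row_oracle(P)
    c, best = 0, -1.0
    for j, p in enumerate(p_star):
        if p > best:
            c, best = j, p
    d = []
    for row in P:
        runner = max(p for j, p in enumerate(row) if j != c)
        d.append(row[c] - runner)
    M = sum(d) / len(d)
    if len(d) > 1:
        mu = M
        sigma = math.sqrt(sum((x - mu) ** 2 for x in d) / (len(d) - 1))
    else:
        sigma = 0.0
    return M, sigma, d


def db_oracle(h1, h2):
    s = 0.0
    for a, b in zip(h1, h2):
        s += math.sqrt(a * b)
    return -math.log(s + 1e-12)


def standardize_oracle(trial, rest, decay=0.999, clip_mode="pre_update"):
    """Naively looped exponential moving standardization, one value at a time."""
    n_ch = len(trial)
    out = []
    for ch in range(n_ch):
        r = rest[ch]
        mu = sum(r) / len(r)
        var = sum((v - mu) ** 2 for v in r) / len(r)
        xs = []
        for x in trial[ch]:
            if clip_mode == "pre_update":
                lo, hi = mu - 6 * math.sqrt(var), mu + 6 * math.sqrt(var)
                x = min(max(x, lo), hi)
                mu = 0.001 * x + 0.999 * mu if decay == 0.999 else (1 - decay) * x + decay * mu
                var = (1 - decay) * (x - mu) ** 2 + decay * var
            else:
                mu = (1 - decay) * x + decay * mu
                var = (1 - decay) * (x - mu) ** 2 + decay * var
                lo, hi = mu - 6 * math.sqrt(var), mu + 6 * math.sqrt(var)
                x = min(max(x, lo), hi)
            xs.append((x - mu) / math.sqrt(var))
        out.append(xs)
    return out


def crop_count_oracle(window, crop, stride):
    """Enumerate valid crop start positions."""
    n = 0
    start = 0
    while start + crop <= window:
        n += 1
        start += stride
    return n
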