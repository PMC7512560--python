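"""Independent brute-force reference implementations.

Naive triple-loop estimators in pure Python, written directly from the
defining formulas with no shared code with the package. They are the
oracles the fast vectorised implementations are checked against.
"""

from __future__ import annotations

import math


def naive_templates(x, m):
    return [tuple(x[i:i + m]) for i in range(len(x) - m + 1)]


def naive_chebyshev(a, b):
    return max(abs(u - v) for u, v in zip(a, b))


def naive_range(a, b):
    """Normalised range distance; None for identical templates."""
    diffs = [abs(u - v) for u, v in zip(a, b)]
    hi, lo = max(diffs), min(diffs)
    if hi + lo == 0:
        return None
    return (hi - lo) / (hi + lo)


def _population_sd(x):
    n = len(x)
    mean = sum(x) / n
    return math.sqrt(sum((v - mean) ** 2 for v in x) / n)


def naive_apen(x, m, r, sd_correction=False):
    """Pincus ApEn: per-template mean log probabilities, self included."""
    if sd_correction:
        sd = _population_sd(x)
        x = [v / sd for v in x]
    phis = []
    for mm in (m, m + 1):
        temps = naive_templates(x, mm)
        n = len(temps)
        logs = []
        for a in temps:
            cnt = sum(1 for b in temps if naive_chebyshev(a, b) <= r)
            logs.append(math.log(cnt / n))
        phis.append(sum(logs) / n)
    return phis[0] - phis[1]


def naive_sampen(x, m, r, sd_correction=False):
    """Richman–Moorman SampEn; None when an aggregated count is zero."""
    if sd_correction:
        sd = _population_sd(x)
        x = [v / sd for v in x]
    temps_m = naive_templates(x, m)
    temps_m1 = naive_templates(x, m + 1)
    n2 = len(temps_m1)  # = N - m
    b = sum(
        1
        for i in range(n2)
        for j in range(n2)
        if i != j and naive_chebyshev(temps_m[i], temps_m[j]) <= r
    )
    a = sum(
        1
        for i in range(n2)
        for j in range(n2)
        if i != j and naive_chebyshev(temps_m1[i], temps_m1[j]) <= r
    )
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def naive_rangeen_a(x, m, r):
    """ApEn-style range entropy: self-pairs undefined (never match),
    probabilities normalised by the candidate count; None when any
    per-template count is zero."""
    phis = []
    for mm in (m, m + 1):
        temps = naive_templates(x, mm)
        n = len(temps)
        logs = []
        for i, a in enumerate(temps):
            cnt = 0
            for j, b in enumerate(temps):
                d = naive_range(a, b)
                if d is not None and d <= r:
                    cnt += 1
            if cnt == 0:
                return None
            logs.append(math.log(cnt / (n - 1)))
        phis.append(sum(logs) / n)
    return phis[0] - phis[1]


def naive_rangeen_b(x, m, r):
    """SampEn-style range entropy; undefined pairs never match."""
    temps_m = naive_templates(x, m)
    temps_m1 = naive_templates(x, m + 1)
    n2 = len(temps_m1)

    def agg(temps, size):
        total = 0
        for i in range(size):
            for j in range(size):
                if i == j:
                    continue
                d = naive_range(temps[i], temps[j])
                if d is not None and d <= r:
                    total += 1
        return total

    b = agg(temps_m, n2)
    a = agg(temps_m1, n2)
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def naive_rs_segment(seg):
    """R and S of one segment by the defining steps (hand computation)."""
    n = len(seg)
    mean = sum(seg) / n
    y = [v - mean for v in seg]
    z, acc = [], 0.0
    for v in y:
        acc += v
        z.append(acc)
    r = max(z) - min(z)
    s = math.sqrt(sum(v * v for v in y) / n)
    return r, s
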