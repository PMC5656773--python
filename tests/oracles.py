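"""Independent brute-force reimplementations used as test oracles.

Everything here is written from the definitions (sums, sorts, explicit
linear-interpolation quantiles, pairwise comparisons) without numpy
statistics helpers, so it stays independent of the implementation paths it
checks.
"""

from __future__ import annotations

import math


def naive_mean(xs) -> float:
    return sum(xs) / len(xs)


def naive_median(xs) -> float:
    s = sorted(xs)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def naive_quantile(xs, q: float) -> float:
    """Linear-interpolation quantile: position q * (n - 1) on sorted data."""
    s = sorted(xs)
    pos = q * (len(s) - 1)
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def naive_iqr(xs) -> float:
    return naive_quantile(xs, 0.75) - naive_quantile(xs, 0.25)


def naive_std(xs) -> float:
    mu = naive_mean(xs)
    return math.sqrt(sum((x - mu) ** 2 for x in xs) / len(xs))


def naive_skewness(xs) -> float:
    mu = naive_mean(xs)
    sd = naive_std(xs)
    if sd == 0:
        return 0.0
    return sum((x - mu) ** 3 for x in xs) / len(xs) / sd**3


def naive_excess_kurtosis(xs) -> float:
    mu = naive_mean(xs)
    var = sum((x - mu) ** 2 for x in xs) / len(xs)
    if var == 0:
        return 0.0
    return sum((x - mu) ** 4 for x in xs) / len(xs) / var**2 - 3.0


def naive_resultant(channels) -> list[float]:
    x, y, z = channels
    return [math.sqrt(a * a + b * b + c * c) for a, b, c in zip(x, y, z)]


def naive_derivative(xs, rate_hz: float) -> list[float]:
    return [(b - a) * rate_hz for a, b in zip(xs, xs[1:])]


def naive_sensor_block(channels, rate_hz: float) -> list[float]:
    """The 20 per-sensor features, computed from the definitions."""
    r = naive_resultant(channels)
    d = naive_derivative(r, rate_hz)
    block = [
        naive_mean(r),
        naive_median(r),
        naive_std(r),
        naive_skewness(r),
        naive_excess_kurtosis(r),
        naive_iqr(r),
        min(r),
        max(r),
        naive_iqr(d),
        min(d),
        max(d),
    ]
    for axis in channels:
        xs = list(axis)
        block += [max(xs), min(xs), naive_iqr(xs)]
    return block


def naive_feature_vector(clip, rate_hz: float = 50.0) -> list[float]:
    return naive_sensor_block(
        [list(row) for row in clip.accel], rate_hz
    ) + naive_sensor_block([list(row) for row in clip.gyro], rate_hz)


def naive_auc(labels, scores) -> float:
    """P(random positive outranks random negative), ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def naive_optimal_point(labels, scores):
    """Exhaustive scan over candidate thresholds (all distinct scores).

    Classify positive when score >= threshold; returns the (threshold,
    sensitivity, specificity) maximizing sens + spec, ties toward the
    lower threshold.
    """
    candidates = sorted(set(scores), reverse=True)
    candidates = [float("inf")] + candidates
    best = None
    for thr in candidates:
        tp = sum(1 for s, y in zip(scores, labels) if y == 1 and s >= thr)
        fn = sum(1 for s, y in zip(scores, labels) if y == 1 and s < thr)
        tn = sum(1 for s, y in zip(scores, labels) if y == 0 and s < thr)
        fp = sum(1 for s, y in zip(scores, labels) if y == 0 and s >= thr)
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if best is None or sens + spec >= best[1] + best[2] - 1e-12:
            if best is None or sens + spec > best[1] + best[2] + 1e-12 or thr < best[0]:
                best = (thr, sens, spec)
    return best


def naive_ranksum_exact_p(a, b) -> float:
    """Two-sided exact rank-sum p by full enumeration of rank assignments."""
    from itertools import combinations

    pooled = list(a) + list(b)
    # midranks
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    n1 = len(a)
    w_obs = sum(ranks[:n1])
    mu = n1 * (len(pooled) + 1) / 2.0
    count = total = 0
    for combo in combinations(range(len(pooled)), n1):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total
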