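"""Independent naive reference implementations used only as test oracles.

Everything here is deliberately written with plain loops and dictionaries,
sharing no code with the package, so agreement is evidence of correctness
rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def naive_lower_hull_baseline(x, y):
    """Rubber-band baseline by gift-wrapping the lower hull (O(n*h))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    hull = [0]
    while hull[-1] != n - 1:
        j = hull[-1]
        best, best_slope = None, None
        for k in range(j + 1, n):
            slope = (y[k] - y[j]) / (x[k] - x[j])
            if best is None or slope < best_slope - 1e-15:
                best, best_slope = k, slope
        hull.append(best)
    return np.interp(x, x[hull], y[hull])


def naive_detrended_sd(values, grid):
    values = np.asarray(values, float)
    grid = np.asarray(grid, float)
    n = len(values)
    xm, ym = grid.mean(), values.mean()
    slope = sum((grid[i] - xm) * (values[i] - ym) for i in range(n)) / sum(
        (grid[i] - xm) ** 2 for i in range(n)
    )
    resid = [values[i] - (ym + slope * (grid[i] - xm)) for i in range(n)]
    mean_r = sum(resid) / n
    return math.sqrt(sum((r - mean_r) ** 2 for r in resid) / (n - 1))


def naive_amide_snr(spectrum, grid, signal_window, noise_window, fallback_window):
    spectrum = np.asarray(spectrum, float)
    grid = np.asarray(grid, float)
    sm = (grid >= signal_window[0]) & (grid <= signal_window[1])
    corrected = spectrum[sm] - naive_lower_hull_baseline(grid[sm], spectrum[sm])
    num = max(corrected)
    for win in (noise_window, fallback_window):
        nm = (grid >= win[0]) & (grid <= win[1])
        if nm.sum() >= 3:
            sd = naive_detrended_sd(spectrum[nm], grid[nm])
            if sd >= 1e-12:
                return num / sd
    return float("inf")


def naive_spike_count(spectrum, grid, window, z_threshold=6.0):
    spectrum = np.asarray(spectrum, float)
    grid = np.asarray(grid, float)
    m = (grid >= window[0]) & (grid <= window[1])
    vals = spectrum[m]
    d = [vals[i + 1] - vals[i] for i in range(len(vals) - 1)]
    sd = sorted(d)
    med = (
        sd[len(sd) // 2]
        if len(sd) % 2
        else (sd[len(sd) // 2 - 1] + sd[len(sd) // 2]) / 2
    )
    dev = sorted(abs(v - med) for v in d)
    mad = (
        dev[len(dev) // 2]
        if len(dev) % 2
        else (dev[len(dev) // 2 - 1] + dev[len(dev) // 2]) / 2
    )
    if mad == 0:
        return 0
    flagged = [abs((v - med) / (1.4826 * mad)) > z_threshold for v in d]
    events, prev = 0, False
    for f in flagged:
        if f and not prev:
            events += 1
        prev = f
    return events


def naive_cosine_to_median(matrix, grid, window):
    matrix = np.asarray(matrix, float)
    grid = np.asarray(grid, float)
    m = (grid >= window[0]) & (grid <= window[1])
    sub = matrix[:, m]
    unit = []
    for row in sub:
        rn = math.sqrt(sum(v * v for v in row))
        unit.append([v / rn for v in row])
    ref = []
    for j in range(len(unit[0])):
        col = sorted(u[j] for u in unit)
        mid = len(col) // 2
        ref.append(col[mid] if len(col) % 2 else (col[mid - 1] + col[mid]) / 2)
    ref_n = math.sqrt(sum(v * v for v in ref))
    return np.array(
        [sum(a * b for a, b in zip(u, ref)) / ref_n for u in unit]
    )


def naive_trapezoid(y, x):
    return sum(
        (y[i] + y[i + 1]) / 2 * (x[i + 1] - x[i]) for i in range(len(y) - 1)
    )


def naive_baseline_fraction(spectrum, grid, window):
    spectrum = np.asarray(spectrum, float)
    grid = np.asarray(grid, float)
    m = (grid >= window[0]) & (grid <= window[1])
    vals, g = spectrum[m], grid[m]
    baseline = naive_lower_hull_baseline(g, vals)
    return 100.0 * naive_trapezoid(baseline, g) / naive_trapezoid(vals, g)


def pair_count_auc(scores, labels):
    """AUC by exhaustive positive/negative pair counting; ties count 1/2."""
    scores = list(np.asarray(scores, float))
    labels = list(np.asarray(labels, int))
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def naive_entropy(values):
    counts = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    n = len(values)
    return -sum(c / n * math.log2(c / n) for c in counts.values())


def naive_su(x, y):
    hx = naive_entropy(list(x))
    hy = naive_entropy(list(y))
    hxy = naive_entropy(list(zip(x, y)))
    if hx + hy == 0:
        return 0.0
    return 2.0 * (hx + hy - hxy) / (hx + hy)


def exhaustive_fcbf(codes, y, delta=0.0):
    """Predominance FCBF by direct definition, plain python throughout."""
    codes = np.asarray(codes)
    p = codes.shape[1]
    su_label = [naive_su(codes[:, j], y) for j in range(p)]
    order = sorted(
        (j for j in range(p) if su_label[j] > delta),
        key=lambda j: (-su_label[j], j),
    )
    selected = []
    for f in order:
        if any(
            naive_su(codes[:, f], codes[:, g]) >= su_label[f] for g in selected
        ):
            continue
        selected.append(f)
    return selected
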