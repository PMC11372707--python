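"""Independent brute-force reference implementations used only by tests.

These follow the defining algorithms literally with explicit Python loops
and share no code with the package's vectorized routines.
"""

import math

import numpy as np


def dfa_brute(x, windows, aggregation="mean_rms"):
    """Step-by-step DFA: integrate, split into non-overlapping forward
    windows, fit a line per window with polyfit, per-window RMS residual,
    F(m) = mean of the RMS values, slope of log F on log m."""
    x = np.asarray(x, dtype=float)
    profile = np.cumsum(x - np.mean(x))
    fluct = []
    for m in windows:
        k = len(profile) // m
        rms_values = []
        for i in range(k):
            seg = profile[i * m:(i + 1) * m]
            t = np.arange(m, dtype=float)
            slope, intercept = np.polyfit(t, seg, 1)
            resid = seg - (slope * t + intercept)
            rms_values.append(math.sqrt(np.mean(resid ** 2)))
        if aggregation == "mean_rms":
            fluct.append(float(np.mean(rms_values)))
        else:
            fluct.append(math.sqrt(np.mean([v ** 2 for v in rms_values])))
    alpha = np.polyfit(np.log(windows), np.log(fluct), 1)[0]
    return fluct, float(alpha)


def sampen_brute(x, m=2, r=0.25, norm="euclidean"):
    """Ordered-pair sample entropy by explicit double loop; both template
    lengths use the same len(x) - m starting positions, self-pairs skipped."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    nt = n - m
    cm = 0
    cm1 = 0
    for i in range(nt):
        for j in range(nt):
            if i == j:
                continue
            if _dist(x[i:i + m], x[j:j + m], norm) < r:
                cm += 1
            if _dist(x[i:i + m + 1], x[j:j + m + 1], norm) < r:
                cm1 += 1
    sen = math.log(cm / cm1) if cm1 > 0 else None
    return sen, cm, cm1


def _dist(a, b, norm):
    if norm == "euclidean":
        return math.sqrt(sum((u - v) ** 2 for u, v in zip(a, b)))
    return max(abs(u - v) for u, v in zip(a, b))


def periodogram_loglog_slope(x):
    """Least-squares slope of log power vs log frequency of the raw
    periodogram — an oracle for spectral synthesis independent of DFA."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1.0)
    keep = freqs > 0
    return float(np.polyfit(np.log(freqs[keep]), np.log(spec[keep]), 1)[0])
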