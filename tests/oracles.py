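"""Independent brute-force oracles used only by the test suite.

Each oracle reimplements a quantity from first principles, in a deliberately
naive style (explicit loops, no shared code with the package), so that
agreement with the production path is a meaningful check.
"""

from __future__ import annotations

import math


def apen_naive(series, m: int, tolerance_fraction: float = 0.2) -> float:
    """Naive O(N^2) double-loop approximate entropy.

    Chebyshev distance, tolerance = tolerance_fraction * population SD,
    self-matches included; ApEn = Phi^m - Phi^(m+1).
    """
    x = [float(v) for v in series]
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    if sd == 0:
        return 0.0
    d = tolerance_fraction * sd

    def phi(k: int) -> float:
        n_vec = n - k + 1
        vectors = [x[i : i + k] for i in range(n_vec)]
        total = 0.0
        for i in range(n_vec):
            count = 0
            vi = vectors[i]
            for j in range(n_vec):
                vj = vectors[j]
                dist = 0.0
                for a, b in zip(vi, vj):
                    diff = a - b if a >= b else b - a
                    if diff > dist:
                        dist = diff
                if dist <= d:
                    count += 1
            total += math.log(count / n_vec)
        return total / n_vec

    return phi(m) - phi(m + 1)


def window_variance_scan(series, window_samples: int) -> list[float]:
    """Exhaustive sliding-window unbiased sample variance, hop = 1 sample."""
    x = [float(v) for v in series]
    out = []
    for i in range(len(x) - window_samples + 1):
        w = x[i : i + window_samples]
        mean = sum(w) / len(w)
        out.append(sum((v - mean) ** 2 for v in w) / (len(w) - 1))
    return out


def cutpoint_bruteforce(values, labels, direction: str):
    """Scan every midpoint threshold; maximize sens + spec, ties -> higher sens.

    Returns (threshold, sensitivity, specificity) with the same tie-breaking
    as the production scan (first candidate in ascending order wins ties).
    """
    pairs = sorted(set(float(v) for v in values))
    candidates = [(a + b) / 2 for a, b in zip(pairs[:-1], pairs[1:])]
    labels = [bool(l) for l in labels]
    best = None
    for thr in candidates:
        tp = fn = tn = fp = 0
        for v, lab in zip(values, labels):
            pred = (float(v) <= thr) if direction == "<=" else (float(v) > thr)
            if pred and lab:
                tp += 1
            elif pred and not lab:
                fp += 1
            elif not pred and lab:
                fn += 1
            else:
                tn += 1
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        key = (sens + spec, sens)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    return best[1], best[2], best[3]
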