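"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible (pure Python, explicit
loops, direct probability-mass enumeration) and deliberately shares no code
with the package.
"""

import math


def convolve_direct(signal, taps):
    """Direct convolution sum, 'valid' mode, pure Python."""
    n, w = len(signal), len(taps)
    out = []
    for i in range(n - w + 1):
        acc = 0.0
        for j in range(w):
            # np.convolve flips the kernel; taps are symmetric in practice,
            # but flip here anyway so the oracle is exact for any kernel
            acc += signal[i + j] * taps[w - 1 - j]
        out.append(acc)
    return out


def pair_indices_reference(d, min_len=20, max_len=500):
    """Exhaustive ascend/descend pairing under the declared rules.

    Within a window the ascending anchor is the leftmost maximal positive
    difference (found by linear scan) and its partner the leftmost most
    negative difference after it within max_len (found by scanning all
    candidate pairs); accepted peaks split the window at their ends,
    discarded anchors split it at the anchor.
    """
    out = []
    stack = [(0, len(d))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        a = None
        for i in range(lo, hi):
            if a is None or d[i] > d[a]:
                a = i
        if a is None or d[a] <= 0:
            continue
        best = None
        for j in range(a + 1, min(hi, a + max_len)):
            if d[j] < 0 and (best is None or d[j] < d[best]):
                best = j
        if best is not None and (best + 1 - a) >= min_len:
            out.append((a, best))
            stack.append((lo, a))
            stack.append((best + 1, hi))
        else:
            stack.append((lo, a))
            stack.append((a + 1, hi))
    return sorted(out)


def poisson_pmf(j, lam):
    return math.exp(-lam + j * math.log(lam) - math.lgamma(j + 1))


def poisson_two_sided_reference(k, lam):
    """Minimum-likelihood two-sided Poisson p by direct mass enumeration."""
    if lam == 0:
        return 1.0 if k == 0 else 0.0
    cutoff = int(max(k, lam + 10 * math.sqrt(lam) + 50)) + 1
    d = poisson_pmf(k, lam) * (1 + 1e-7)
    total = 0.0
    for j in range(cutoff + 1):
        if poisson_pmf(j, lam) <= d:
            total += poisson_pmf(j, lam)
    return min(1.0, total)


def binom_pmf(k, n, p):
    return math.exp(
        math.lgamma(n + 1)
        - math.lgamma(k + 1)
        - math.lgamma(n - k + 1)
        + (k * math.log(p) if k else 0.0)
        + ((n - k) * math.log1p(-p) if n - k else 0.0)
    )


def binom_two_sided_reference(k, n, p):
    """Minimum-likelihood two-sided binomial p by direct mass enumeration."""
    d = binom_pmf(k, n, p) * (1 + 1e-7)
    total = 0.0
    for j in range(n + 1):
        if binom_pmf(j, n, p) <= d:
            total += binom_pmf(j, n, p)
    return min(1.0, total)
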