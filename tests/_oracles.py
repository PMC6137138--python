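"""Independent brute-force reference implementations used as test oracles.

Pure-Python, loop-based, written directly from the algorithm definitions;
they deliberately share no code with the package.
"""

from __future__ import annotations

import numpy as np


def minimum_threshold_oracle(histogram, max_iters: int = 10000) -> int:
    """Iterated 3-bin smoothing until bimodal, then the valley bin."""
    h = [float(v) for v in histogram]
    n = len(h)

    def maxima(seq):
        out = []
        for i in range(n):
            left = seq[i - 1] if i > 0 else float("-inf")
            right = seq[i + 1] if i < n - 1 else float("-inf")
            if seq[i] > left and seq[i] > right:
                out.append(i)
        return out

    iters = 0
    while len(maxima(h)) != 2:
        if len(maxima(h)) < 2 and iters > 0:
            raise RuntimeError("unimodal")
        if iters >= max_iters:
            raise RuntimeError("no convergence")
        h = [
            (h[i - 1 if i > 0 else 0] + h[i] + h[i + 1 if i < n - 1 else n - 1]) / 3.0
            for i in range(n)
        ]
        iters += 1
    p1, p2 = maxima(h)
    best = p1 + 1
    for i in range(p1 + 1, p2):
        if h[i] < h[best]:
            best = i
    return best


def random_bimodal_histogram(rng: np.random.Generator) -> np.ndarray:
    """A 256-bin histogram of two well-separated intensity populations."""
    m1 = rng.uniform(25, 85)
    m2 = rng.uniform(150, 225)
    s1, s2 = rng.uniform(4, 14, 2)
    n1, n2 = rng.integers(500, 5000, 2)
    samples = np.concatenate([
        rng.normal(m1, s1, n1),
        rng.normal(m2, s2, n2),
    ])
    samples = np.clip(np.round(samples), 0, 255).astype(int)
    return np.bincount(samples, minlength=256)


def alternation_oracle(seq):
    """Enumerate every window of 3 consecutive entries explicitly."""
    n = len(seq)
    if n < 3:
        return None
    distinct = 0
    for i in range(n - 2):
        a, b, c = seq[i], seq[i + 1], seq[i + 2]
        if a != b and b != c and a != c:
            distinct += 1
    return 100.0 * distinct / (n - 2)


def random_entry_sequence(rng: np.random.Generator, arms=("A", "B", "C")):
    """A random arm-entry sequence with no immediate repeats."""
    length = int(rng.integers(3, 25))
    seq = [arms[rng.integers(len(arms))]]
    while len(seq) < length:
        nxt = arms[rng.integers(len(arms))]
        if nxt != seq[-1]:
            seq.append(nxt)
    return seq
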