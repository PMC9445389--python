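"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the package's vectorised code paths (and scipy's
shortcuts): sample entropy is counted with an explicit double loop over
templates, and Kendall's tau-b from an explicit loop/outer-product over
pairs with the textbook tie terms.
"""

from __future__ import annotations

import math

import numpy as np


def brute_sample_entropy(x, m: int, r: float) -> float:
    """O(N^2) template counting: length-L templates at starts 0..N-L-1,
    Chebyshev tolerance r, self-matches excluded, unordered pairs."""
    x = [float(v) for v in x]
    n = len(x)

    def pair_count(length: int) -> int:
        templates = [tuple(x[i:i + length]) for i in range(n - length)]
        count = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if max(abs(a - b) for a, b in zip(templates[i], templates[j])) <= r:
                    count += 1
        return count

    b = pair_count(m)
    a = pair_count(m + 1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def brute_kendall_tau_b(x, y) -> float:
    """Pair-count tau-b: (C - D) / sqrt((n0 - n1)(n0 - n2)) with C/D the
    concordant/discordant pair counts and n1/n2 the tied-pair counts."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = dx[iu] * dy[iu]
    concordant = int((s > 0).sum())
    discordant = int((s < 0).sum())
    n0 = n * (n - 1) // 2
    n1 = int((dx[iu] == 0).sum())
    n2 = int((dy[iu] == 0).sum())
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    return (concordant - discordant) / denom if denom else float("nan")
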