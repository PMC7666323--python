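"""Independent brute-force oracles: term-by-term tail summation via lgamma.

Kept free of any dependence on the implementation under test.
"""

import math


def poisson_tail_oracle(x: int, mu: float) -> float:
    """P(Poisson(mu) >= x) by ascending term summation."""
    if x == 0:
        return 1.0
    if mu == 0:
        return 0.0

    def pmf(i: int) -> float:
        return math.exp(-mu + i * math.log(mu) - math.lgamma(i + 1))

    if x <= mu:
        # large tail: the complement of a short, accurate lower sum
        return min(1.0 - math.fsum(pmf(i) for i in range(x)), 1.0)
    total = 0.0
    i = x
    while True:
        term = pmf(i)
        total += term
        if term < total * 1e-18:
            break
        i += 1
    return min(total, 1.0)


def binom_tail_oracle(x: int, n: int, pi: float) -> float:
    """P(Binomial(n, pi) >= x) by ascending term summation."""
    if x == 0:
        return 1.0
    if pi == 0:
        return 0.0
    log_pi, log_q = math.log(pi), math.log1p(-pi)

    def pmf(i: int) -> float:
        # log of the exact integer binomial coefficient avoids the large
        # cancellation between lgamma(n+1) and lgamma(n-i+1)
        return math.exp(math.log(math.comb(n, i)) + i * log_pi + (n - i) * log_q)

    if x <= n * pi:
        return min(1.0 - math.fsum(pmf(i) for i in range(x)), 1.0)
    total = 0.0
    for i in range(x, n + 1):
        term = pmf(i)
        total += term
        if term < total * 1e-18:
            break
    return min(total, 1.0)
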