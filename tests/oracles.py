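"""Independent brute-force oracles used by the test suite.

Integer-exact (math.comb) enumeration, deliberately separate from the
scipy/log-gamma code paths under test.
"""

import itertools
from math import comb

import numpy as np


def fisher_2x2_oracle(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = comb(r1, x) * comb(r2, c1 - x)
        if p <= p_obs:
            total += p
    return total / denom


def fisher_2xc_oracle(table) -> float:
    """Freeman–Halton p for a 2 x C table by integer-exact enumeration."""
    table = np.asarray(table)
    col_sums = table.sum(axis=0)
    m1 = int(table[0].sum())

    def weight(cells):
        return int(np.prod([comb(int(cj), int(aj)) for cj, aj in zip(col_sums, cells)]))

    denom = comb(int(table.sum()), m1)
    w_obs = weight(table[0])
    total = 0
    for cells in itertools.product(*[range(int(c) + 1) for c in col_sums]):
        if sum(cells) != m1:
            continue
        w = weight(cells)
        if w <= w_obs:
            total += w
    return total / denom
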