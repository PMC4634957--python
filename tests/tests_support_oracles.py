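"""Independent numerical oracles used by the acceptance tests.

Kept free of any recgene import so they cannot share code paths with the
implementation they check.
"""

import math

import numpy as np
from scipy import integrate


def fisher_enum_int(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration with exact integers.

    All tables with the observed margins share the denominator C(n, c1), so
    tables are compared by integer numerators and the sum is exact.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    m_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        m = math.comb(r1, k) * math.comb(r2, c1 - k)
        if m <= m_obs:
            total += m
    return total / math.comb(n, c1)


def t_sf_quad(t, df):
    """P(T > t) for Student's t by numerical integration of the density
    written directly from its gamma-function definition."""
    const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def density(x):
        return const * (1 + x * x / df) ** (-(df + 1) / 2)

    val, _ = integrate.quad(density, t, np.inf)
    return val
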