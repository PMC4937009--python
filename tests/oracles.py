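"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they are used to check.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


def quadrant_class_oracle(qplogs: float, aex: float) -> str:
    """Direct ordered evaluation of the four class predicates."""
    rules = [
        ("A", qplogs > 0 and aex < 0),
        ("B", qplogs >= 0 and aex > 0),
        ("C", qplogs < 0 and aex >= 0),
        ("D", qplogs <= 0 and aex <= 0),
    ]
    for name, hit in rules:
        if hit:
            return name
    return "U"


def exact_mann_whitney_p(x, y) -> float:
    """Exact two-sided p by full enumeration of group assignments.

    p = P(|U - mu| >= |U_obs - mu|) over all C(n1+n2, n1) ways of
    splitting the combined sample, using midranks throughout.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    combined = np.array(x + y)
    ranks = rankdata(combined)
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    threshold = abs(u_obs - mu) - 1e-9
    hits = total = 0
    for subset in combinations(range(n1 + n2), n1):
        u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= threshold:
            hits += 1
        total += 1
    return hits / total
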