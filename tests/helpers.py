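"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def brute_force_variability(table, config):
    """Naive-loop re-implementation of the variable-gene caller.

    Returns (passing sets, divergence dicts, cutoff, call sets).  Uses plain
    Python loops, dicts and sorted(); shares no code with the package path.
    """
    passing: dict[str, set] = {}
    div: dict[str, dict] = {}
    pc = config.pseudocount
    for s in table.sample_labels:
        reps = table.replicates(s)
        assert len(reps) == 2
        p = set()
        d = {}
        for g in table.gene_ids:
            f1 = float(table.values.loc[g, (s, reps[0])])
            f2 = float(table.values.loc[g, (s, reps[1])])
            if f1 > config.fpkm_floor and f2 > config.fpkm_floor:
                p.add(g)
                d[g] = abs(math.log2(f1 + pc) - math.log2(f2 + pc))
        passing[s] = p
        div[s] = d
    ref = div[config.reference_sample]
    n = len(ref)
    k = math.ceil(config.reference_top_fraction * n)
    ordered = sorted(ref.values(), reverse=True)
    cutoff = float("-inf") if k >= n else ordered[k]
    calls = {s: {g for g, x in div[s].items() if x > cutoff} for s in div}
    return passing, div, cutoff, calls


def _u_statistic(a, b) -> int:
    # number of (i, j) pairs with a_i > b_j; assumes tie-free pooled data
    return sum(1 for x in a for y in b if x > y)


def mw_exact_u_and_p(a, b):
    """Exact Mann-Whitney by full enumeration of all pooled arrangements.

    For tie-free data: U = min(U_a, U_b) and the two-sided exact p-value is
    P(min(U_a, U_b) <= observed) over all C(n1+n2, n1) group assignments.
    """
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    pooled = a + b
    u_a = _u_statistic(a, b)
    u_obs = min(u_a, n1 * n2 - u_a)
    count = total = 0
    for idx in combinations(range(n1 + n2), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n1 + n2) if i not in idx]
        u = _u_statistic(ga, gb)
        if min(u, n1 * n2 - u) <= u_obs:
            count += 1
        total += 1
    return u_obs, count / total


def statsmodels_two_way(y, a, b):
    """Type-II two-way ANOVA via statsmodels (the independent route)."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"y": np.asarray(y, float),
                       "fa": np.asarray(a).astype(str),
                       "fb": np.asarray(b).astype(str)})
    fit = ols("y ~ C(fa) * C(fb)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    return {
        "F_a": float(tab.loc["C(fa)", "F"]),
        "F_b": float(tab.loc["C(fb)", "F"]),
        "F_int": float(tab.loc["C(fa):C(fb)", "F"]),
        "p_int": float(tab.loc["C(fa):C(fb)", "PR(>F)"]),
    }
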