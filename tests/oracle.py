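"""Independent brute-force oracles used to cross-check the estimators.

These deliberately avoid the package's difference-of-joint-entropies code
path: conditional entropies are evaluated directly from conditional
distributions with pure-Python loops.
"""

import itertools
import math
from collections import Counter, defaultdict


def entropy_oracle(probs):
    """Direct -sum p log2 p over an iterable of probabilities."""
    return -sum(p * math.log2(p) for p in probs if p > 0)


def cte_oracle_from_pmf(pmf_dict):
    """CTE from a dict (y_next, y_now, x, *z) -> probability.

    Computes H(Y+|Y,Z) - H(Y+|Y,X,Z) via explicit conditional distributions.
    """

    def cond_entropy(group_key):
        groups = defaultdict(dict)
        for key, p in pmf_dict.items():
            if p > 0:
                groups[group_key(key)][key[0]] = (
                    groups[group_key(key)].get(key[0], 0.0) + p
                )
        h = 0.0
        for cond in groups.values():
            total = sum(cond.values())
            h += total * entropy_oracle(v / total for v in cond.values())
        return h

    h_given_yz = cond_entropy(lambda k: (k[1],) + tuple(k[3:]))
    h_given_yxz = cond_entropy(lambda k: tuple(k[1:]))
    return h_given_yz - h_given_yxz


def cte_oracle_from_series(effect, cause, conds=()):
    """Plug-in CTE straight from symbol sequences, no shared code."""
    y = list(effect)
    x = list(cause)
    zs = [list(z) for z in conds]
    samples = [
        (y[t + 1], y[t], x[t], *(z[t] for z in zs)) for t in range(len(y) - 1)
    ]
    counts = Counter(samples)
    total = sum(counts.values())
    pmf = {k: v / total for k, v in counts.items()}
    return cte_oracle_from_pmf(pmf)


def kmeans2_oracle(values):
    """Best 2-partition among ALL subsets (not only threshold splits).

    Feasible for small n; returns a frozenset of indices of the
    higher-mean cluster.
    """
    n = len(values)
    best, best_wcss = None, float("inf")
    for r in range(1, n):
        for subset in itertools.combinations(range(n), r):
            a = [values[i] for i in subset]
            b = [values[i] for i in range(n) if i not in subset]
            ma = sum(a) / len(a)
            mb = sum(b) / len(b)
            wcss = sum((v - ma) ** 2 for v in a) + sum((v - mb) ** 2 for v in b)
            if wcss < best_wcss:
                best_wcss = wcss
                best = subset if ma > mb else tuple(
                    i for i in range(n) if i not in subset
                )
    return frozenset(best)
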