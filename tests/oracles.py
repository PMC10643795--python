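"""Hand-written brute-force oracles, independent of the package."""

import math


def brute_force_spearman(x, y):
    """Oracle: mid-ranks by sorting, then the Pearson formula by hand."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def brute_force_kruskal(samples):
    """Oracle: H with tie correction, ranks computed by hand."""
    pooled = [v for s in samples for v in s]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    n = len(pooled)
    h = 0.0
    pos = 0
    for s in samples:
        r_sum = sum(ranks[pos : pos + len(s)])
        h += r_sum**2 / len(s)
        pos += len(s)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    from collections import Counter

    ties = Counter(pooled)
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction
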