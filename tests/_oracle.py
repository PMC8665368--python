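"""Independent loop-based reference implementation of the agreement formulas.

Deliberately written with plain Python lists and explicit loops, sharing no
code with the vectorized implementation it cross-checks.
"""

from __future__ import annotations


def oracle_percent_agreement(rows: list[list[int]], w: list[list[float]]) -> float:
    per_item = []
    q = len(w)
    for row in rows:
        ri = sum(row)
        if ri < 2:
            continue
        s = 0.0
        for k in range(q):
            rstar = 0.0
            for l in range(q):
                rstar += w[k][l] * row[l]
            s += row[k] * (rstar - 1.0)
        per_item.append(s / (ri * (ri - 1.0)))
    if not per_item:
        raise ValueError("no item with >= 2 ratings")
    return sum(per_item) / len(per_item)


def oracle_chance_agreement(rows: list[list[int]], w: list[list[float]]) -> float:
    n = len(rows)
    q = len(w)
    t_w = sum(sum(r) for r in w)
    pi = [0.0] * q
    for row in rows:
        ri = sum(row)
        for k in range(q):
            pi[k] += row[k] / ri / n
    return t_w / (q * (q - 1)) * sum(p * (1.0 - p) for p in pi)


def oracle_gwet(rows: list[list[int]], w: list[list[float]]) -> tuple[float, float, float]:
    """Return (p_a, p_e, AC) for one table of per-item category counts."""
    pa = oracle_percent_agreement(rows, w)
    pe = oracle_chance_agreement(rows, w)
    return pa, pe, (pa - pe) / (1.0 - pe)


def oracle_quadratic_weights(values: list[float]) -> list[list[float]]:
    vmax, vmin = max(values), min(values)
    span2 = (vmax - vmin) ** 2
    return [
        [1.0 - (vk - vl) ** 2 / span2 for vl in values]
        for vk in values
    ]
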