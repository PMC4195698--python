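"""Independent direct-formula oracles used to cross-check the package.

Everything here is deliberately written from first principles with the
standard library (math/statistics) on plain dict-of-lists data, staying
independent of the implementation paths it checks.
"""

from __future__ import annotations

import math
import statistics


def pairwise_v(q: dict[str, list[float]], j: str, k: str) -> float:
    ratios = [math.log2(a / b) for a, b in zip(q[j], q[k])]
    return statistics.stdev(ratios)


def m_values(q: dict[str, list[float]]) -> dict[str, float]:
    return {
        j: sum(pairwise_v(q, j, k) for k in q if k != j) / (len(q) - 1)
        for j in q
    }


def stepwise_ranking(q: dict[str, list[float]], order: list[str]) -> tuple[list[str], list[str]]:
    """(ordered best-first, exclusion order); ties to the later position."""
    remaining = list(order)
    exclusion: list[str] = []
    while len(remaining) > 2:
        m = m_values({t: q[t] for t in remaining})
        worst = max(range(len(remaining)), key=lambda i: (m[remaining[i]], i))
        exclusion.append(remaining.pop(worst))
    return remaining + list(reversed(exclusion)), exclusion


def normalization_factor(q: dict[str, list[float]], targets: list[str], n: int, s: int) -> float:
    prod = 1.0
    for t in targets[:n]:
        prod *= q[t][s]
    return prod ** (1.0 / n)


def v_curve(q: dict[str, list[float]], ordered: list[str]) -> dict[int, float]:
    n_samples = len(next(iter(q.values())))
    out = {}
    for n in range(2, len(ordered)):
        xs = [
            math.log2(
                normalization_factor(q, ordered, n, s)
                / normalization_factor(q, ordered, n + 1, s)
            )
            for s in range(n_samples)
        ]
        out[n] = statistics.stdev(xs)
    return out
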