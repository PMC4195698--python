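"""geNorm expression-stability analysis.

Given a samples x targets matrix of relative quantities Q, the stability of
target j is measured through the pairwise variations

    V_jk = SD_s( log2(Q_{s,j} / Q_{s,k}) )        (n-1 denominator)

and the stability value M_j = mean_{k != j} V_jk. Stepwise exclusion of the
target with the highest M ranks the panel; the last two targets cannot be
separated (their M values coincide by construction) and are reported as a
tied top pair. The optimal number of reference targets comes from the
pairwise variation between sequential normalization factors,

    V_{n/n+1} = SD_s( log2(NF_n(s) / NF_{n+1}(s)) ),

where NF_n is the geometric mean of the n best-ranked targets; the smallest
n with V_{n/n+1} below the cut-off (default 0.15) suffices.

Numerical note: all log-ratio statistics are computed on within-sample (or
within-pair) quotients referenced to the first sample, which is
algebraically a no-op for an SD but makes the statistics *exactly*
invariant, in floating point, to per-sample and per-target power-of-two
rescaling of Q. V_{n/n+1} uses the identity
``log2(NF_n/NF_{n+1}) = (1/(n(n+1))) * sum_{i<=n} log2(Q_i/Q_{n+1})``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StabilityRanking",
    "VCurve",
    "pairwise_variation",
    "m_values",
    "rank_targets",
    "normalization_factors",
    "v_curve",
    "classify_stability",
    "GeNormError",
]

DEFAULT_V_CUTOFF = 0.15
CATEGORY_THRESHOLDS = (0.2, 0.5)  # very-high below, high below, else low


class GeNormError(ValueError):
    pass


def _check_matrix(q: pd.DataFrame, min_targets: int = 2) -> None:
    if q.shape[0] < 3:
        raise GeNormError("need >= 3 samples for a stable SD")
    if q.shape[1] < min_targets:
        raise GeNormError(f"need >= {min_targets} targets")
    if (q.to_numpy() <= 0).any() or not np.isfinite(q.to_numpy()).all():
        raise GeNormError("relative quantities must be finite and > 0")


def _ratio_sd(qj: np.ndarray, qk: np.ndarray) -> float:
    # SD over samples of log2(qj/qk); the division by the first sample's
    # ratio is a constant shift on the log scale (SD-invariant) that makes
    # per-sample and power-of-two per-target scalings cancel bit-exactly.
    r = qj / qk
    y = np.log2(r / r[0])
    return float(np.std(y, ddof=1))


def pairwise_variation(q: pd.DataFrame, j: str, k: str) -> float:
    """V_jk: SD across samples of the log2 ratio of two targets' quantities."""
    if j == k:
        raise GeNormError("pairwise variation requires two distinct targets")
    _check_matrix(q[[j, k]])
    return _ratio_sd(q[j].to_numpy(dtype=float), q[k].to_numpy(dtype=float))


def m_values(q: pd.DataFrame) -> pd.Series:
    """geNorm stability value M per target: mean pairwise variation.

    Requires >= 3 targets (with 2 the mean degenerates to a single V and
    both targets tie by construction).
    """
    _check_matrix(q, min_targets=3)
    cols = list(q.columns)
    arr = q.to_numpy(dtype=float)
    n = len(cols)
    v = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            v[a, b] = v[b, a] = _ratio_sd(arr[:, a], arr[:, b])
    m = v.sum(axis=1) / (n - 1)
    return pd.Series(m, index=cols, name="M")


@dataclass
class StabilityRanking:
    """Outcome of the stepwise-exclusion geNorm ranking.

    ``ordered_targets`` lists targets best-first; the first two form the
    tied top pair (geNorm cannot separate them). ``m_final`` is each
    target's M at its exclusion round (for the pair: their common pairwise
    variation). ``m_by_round`` holds the full M trajectory, one row per
    exclusion round over the targets still in play.
    """

    ordered_targets: list[str]
    exclusion_order: list[str]
    m_final: pd.Series
    m_by_round: pd.DataFrame
    categories: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.categories = self.m_final.map(classify_stability)

    @property
    def ranks(self) -> pd.Series:
        """1-based rank per target; the top pair shares rank 1."""
        r = {}
        for i, t in enumerate(self.ordered_targets):
            r[t] = 1 if i < 2 else i + 1
        return pd.Series(r, name="rank").reindex(self.ordered_targets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": self.ordered_targets,
                "M_final": self.m_final.reindex(self.ordered_targets).to_numpy(),
                "rank": self.ranks.to_numpy(),
                "category": self.categories.reindex(self.ordered_targets).to_numpy(),
            }
        )


def rank_targets(q: pd.DataFrame) -> StabilityRanking:
    """Rank targets by stepwise exclusion of the highest-M target.

    Ties in the argmax are broken toward the later column position
    (deterministic). The final two targets are returned tied, ordered by
    their input column order.
    """
    _check_matrix(q, min_targets=3)
    remaining = list(q.columns)
    exclusion: list[str] = []
    m_final: dict[str, float] = {}
    rounds: list[pd.Series] = []
    while len(remaining) > 2:
        m = m_values(q[remaining])
        rounds.append(m)
        # argmax with ties broken by later position in current order
        worst = max(range(len(remaining)), key=lambda i: (m.iloc[i], i))
        name = remaining[worst]
        m_final[name] = float(m.iloc[worst])
        exclusion.append(name)
        remaining.remove(name)
    pair_v = pairwise_variation(q, remaining[0], remaining[1])
    for t in remaining:
        m_final[t] = pair_v
    ordered = list(remaining) + list(reversed(exclusion))
    m_by_round = pd.DataFrame(rounds).reindex(columns=list(q.columns))
    m_by_round.index = pd.RangeIndex(len(rounds), name="round")
    return StabilityRanking(
        ordered_targets=ordered,
        exclusion_order=exclusion,
        m_final=pd.Series(m_final, name="M").reindex(list(q.columns)),
        m_by_round=m_by_round,
    )


def normalization_factors(q: pd.DataFrame, targets: list[str], n: int) -> pd.Series:
    """NF_n per sample: geometric mean of the n best-ranked targets.

    ``targets`` is an ordered (best-first) target list; the selected subset
    is canonicalized by name before averaging so the result is exactly
    invariant to ordering within the set.
    """
    if not (2 <= n <= len(targets)):
        raise GeNormError(f"n must be in [2, {len(targets)}]")
    chosen = sorted(targets[:n])
    sub = np.log2(q[chosen].to_numpy(dtype=float))
    nf = np.exp2(sub.mean(axis=1))
    return pd.Series(nf, index=q.index, name=f"NF{n}")


@dataclass
class VCurve:
    """Pairwise variations V_{n/n+1} between sequential normalization factors."""

    v: pd.Series  # index n (2..n_max-1), value V_{n/n+1}
    optimal_n: int
    cutoff: float
    cutoff_reached: bool


def v_curve(
    q: pd.DataFrame,
    ranking: StabilityRanking | list[str],
    cutoff: float = DEFAULT_V_CUTOFF,
) -> VCurve:
    """V_{n/n+1} for n = 2..n_max-1 and the optimal reference count.

    ``optimal_n`` is the smallest n with V_{n/n+1} < cutoff; when the curve
    never drops below the cut-off the full panel (n_max) is reported with
    ``cutoff_reached=False``.
    """
    ordered = ranking.ordered_targets if isinstance(ranking, StabilityRanking) else list(ranking)
    _check_matrix(q[ordered], min_targets=3)
    arr = q[ordered].to_numpy(dtype=float)
    n_max = len(ordered)
    vals = {}
    for n in range(2, n_max):
        # log2(NF_n/NF_{n+1}) = (1/(n(n+1))) * sum_{i<n} log2(Q_i / Q_{n})
        # (0-based col n is the (n+1)-th ranked target); each ratio is
        # additionally referenced to sample 0 — an SD-invariant shift.
        acc = np.zeros(arr.shape[0])
        denom_col = arr[:, n]
        for i in range(n):
            r = arr[:, i] / denom_col
            acc += np.log2(r / r[0])
        x = acc / (n * (n + 1))
        vals[n] = float(np.std(x, ddof=1))
    v = pd.Series(vals, name="V")
    v.index.name = "n"
    below = v[v < cutoff]
    if len(below):
        return VCurve(v=v, optimal_n=int(below.index[0]), cutoff=cutoff, cutoff_reached=True)
    return VCurve(v=v, optimal_n=n_max, cutoff=cutoff, cutoff_reached=False)


def classify_stability(m: float) -> str:
    """Stability category: M < 0.2 'very-high', < 0.5 'high', else 'low'."""
    if m < 0:
        raise GeNormError("M must be >= 0")
    very_high, high = CATEGORY_THRESHOLDS
    if m < very_high:
        return "very-high"
    if m < high:
        return "high"
    return "low"
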