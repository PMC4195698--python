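"""Cross-experiment rank aggregation.

Combines K ranked reference-target lists (one per experiment, each with
per-target stability weights, i.e. geNorm M-values) into one consensus
ordering. Two aggregators are provided:

* :func:`borda` — mean rank position across lists (voting-theory baseline);
* :func:`aggregate_ce` — cross-entropy Monte Carlo minimization of the
  summed weighted Spearman footrule distance to all lists, seeded from the
  Borda solution.

The weighted footrule between a candidate ordering ``delta`` and list
``L_i`` is ``d = sum_t w~_i(t) * |rank_delta(t) - rank_i(t)|`` where the
per-list weights ``w~`` are the min-max *inverted* M-values, so the most
stable target (lowest M) carries weight 1 and the least stable weight 0;
constant weight vectors reduce to the unweighted footrule.

:func:`brute_force_aggregate` exhaustively minimizes the same objective for
small universes and serves as the in-package oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankedLists",
    "AggregatedRanking",
    "borda",
    "ws_distance",
    "objective",
    "aggregate_ce",
    "brute_force_aggregate",
    "AggregationError",
]


class AggregationError(ValueError):
    pass


@dataclass(frozen=True)
class RankedLists:
    """K full ranked lists over a common universe, with per-list weights.

    ``weights[i][t]`` is the stability weight (M-value; lower = more
    stable) of target ``t`` in list ``i``. Weights may be omitted, in
    which case every list is unweighted. The universe order is the order
    of the first list.
    """

    lists: Sequence[Sequence[str]]
    weights: Sequence[Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if not self.lists:
            raise AggregationError("need at least one ranked list")
        universe = set(self.lists[0])
        for i, lst in enumerate(self.lists):
            if len(set(lst)) != len(lst) or set(lst) != universe:
                raise AggregationError(
                    f"list {i} is not a permutation of the common universe"
                )
        if self.weights is not None:
            if len(self.weights) != len(self.lists):
                raise AggregationError("need one weight vector per list")
            for i, w in enumerate(self.weights):
                if set(w) != universe:
                    raise AggregationError(f"weights {i} not aligned to the universe")
                if any(v < 0 for v in w.values()):
                    raise AggregationError(f"weights {i} must be >= 0")

    @property
    def universe(self) -> list[str]:
        return list(self.lists[0])

    def rank_matrix(self) -> np.ndarray:
        """(K, n) matrix of 1-based ranks, columns aligned to the universe."""
        uni = self.universe
        pos = {t: j for j, t in enumerate(uni)}
        out = np.empty((len(self.lists), len(uni)))
        for i, lst in enumerate(self.lists):
            for r, t in enumerate(lst, start=1):
                out[i, pos[t]] = r
        return out

    def weight_matrix(self) -> np.ndarray:
        """(K, n) matrix of normalized footrule weights w~ (low M -> 1)."""
        uni = self.universe
        k, n = len(self.lists), len(uni)
        if self.weights is None:
            return np.ones((k, n))
        out = np.empty((k, n))
        for i, w in enumerate(self.weights):
            raw = np.array([w[t] for t in uni], dtype=float)
            span = raw.max() - raw.min()
            out[i] = 1.0 if span == 0 else (raw.max() - raw) / span
        return out

    def mean_ranks(self) -> pd.Series:
        return pd.Series(self.rank_matrix().mean(axis=0), index=self.universe, name="mean_rank")

    def mean_weights(self) -> pd.Series:
        uni = self.universe
        if self.weights is None:
            return pd.Series(0.0, index=uni, name="mean_weight")
        arr = np.array([[w[t] for t in uni] for w in self.weights])
        return pd.Series(arr.mean(axis=0), index=uni, name="mean_weight")


@dataclass
class AggregatedRanking:
    """A consensus ordering with its objective value and provenance."""

    order: list[str]
    phi: float
    method: str
    trace: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["iteration", "best_phi"])
    )
    seed: int | None = None

    def to_frame(self, lists: RankedLists | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"target": self.order, "consensus_rank": np.arange(1, len(self.order) + 1)}
        )
        if lists is not None:
            df["mean_rank"] = lists.mean_ranks().reindex(self.order).to_numpy()
            if lists.weights is not None:
                uni = lists.universe
                arr = np.array([[w[t] for t in uni] for w in lists.weights])
                med = pd.Series(np.median(arr, axis=0), index=uni)
                df["median_M"] = med.reindex(self.order).to_numpy()
        return df


def _normalize_weights(weights: Mapping[str, float], universe: Sequence[str]) -> np.ndarray:
    raw = np.array([weights[t] for t in universe], dtype=float)
    span = raw.max() - raw.min()
    if span == 0:
        return np.ones_like(raw)
    return (raw.max() - raw) / span


def ws_distance(
    candidate: Sequence[str],
    reference: Sequence[str],
    weights: Mapping[str, float] | None = None,
    normalize: bool = True,
) -> float:
    """Weighted Spearman footrule distance between two orderings.

    ``weights`` are the reference list's raw M-values; with
    ``normalize=True`` (default) they are min-max inverted so low M gives
    weight 1. Pass ``normalize=False`` to supply footrule weights directly.
    Zero iff the orderings agree (or every weight vanishes).
    """
    if set(candidate) != set(reference) or len(set(candidate)) != len(candidate):
        raise AggregationError("candidate and reference must share one universe")
    uni = list(reference)
    if weights is None:
        w = np.ones(len(uni))
    elif normalize:
        w = _normalize_weights(weights, uni)
    else:
        w = np.array([weights[t] for t in uni], dtype=float)
    r_ref = {t: i + 1 for i, t in enumerate(reference)}
    r_cand = {t: i + 1 for i, t in enumerate(candidate)}
    return float(sum(wi * abs(r_cand[t] - r_ref[t]) for wi, t in zip(w, uni)))


def objective(candidate: Sequence[str], lists: RankedLists) -> float:
    """Phi(delta): summed weighted footrule distance to every input list."""
    if set(candidate) != set(lists.universe):
        raise AggregationError("candidate not over the lists' universe")
    uni = lists.universe
    pos = {t: j for j, t in enumerate(uni)}
    cand_ranks = np.empty(len(uni))
    for r, t in enumerate(candidate, start=1):
        cand_ranks[pos[t]] = r
    ranks = lists.rank_matrix()
    w = lists.weight_matrix()
    return float((w * np.abs(cand_ranks[None, :] - ranks)).sum())


def borda(lists: RankedLists) -> AggregatedRanking:
    """Borda-count consensus: ascending mean rank across lists.

    Ties are broken by ascending mean raw weight (more stable first), then
    by universe (first-list) order.
    """
    uni = lists.universe
    mean_rank = lists.mean_ranks().to_numpy()
    mean_w = lists.mean_weights().to_numpy()
    idx = sorted(range(len(uni)), key=lambda j: (mean_rank[j], mean_w[j], j))
    order = [uni[j] for j in idx]
    return AggregatedRanking(order=order, phi=objective(order, lists), method="borda")


def _phi_batch(perms: np.ndarray, ranks: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Phi for a (N, n) batch of permutations given (K, n) ranks/weights.

    ``perms[s, p]`` is the universe index of the item at position ``p``.
    """
    n = perms.shape[1]
    cand_ranks = np.empty_like(perms)
    rows = np.arange(perms.shape[0])[:, None]
    cand_ranks[rows, perms] = np.arange(1, n + 1)[None, :]
    # (N, K, n) broadcast: |cand - ref| * weight
    diff = np.abs(cand_ranks[:, None, :] - ranks[None, :, :])
    return (diff * w[None, :, :]).sum(axis=(1, 2))


def aggregate_ce(
    lists: RankedLists,
    n_samples: int | None = None,
    elite_frac: float = 0.1,
    smoothing: float = 0.1,
    max_iter: int = 100,
    patience: int = 10,
    seed: int = 0,
) -> AggregatedRanking:
    """Cross-entropy Monte Carlo minimization of the footrule objective.

    Maintains an item x position probability matrix, initialized as an
    equal blend of the uniform matrix and the Borda permutation. Each
    iteration samples ``n_samples`` permutations (default ``100 * n``) by
    sequential position sampling without replacement, scores Phi, and
    relaxes the matrix toward the elite fraction with smoothing
    ``smoothing``. The Borda solution (and thereafter the incumbent) is
    injected into every sample pool, so the result never scores worse than
    Borda. Deterministic given ``seed``; stops after ``patience``
    iterations without improvement.
    """
    if not (0.0 < elite_frac < 1.0):
        raise AggregationError("elite_frac must be in (0, 1)")
    if not (0.0 < smoothing <= 1.0):
        raise AggregationError("smoothing must be in (0, 1]")
    uni = lists.universe
    n = len(uni)
    if n == 1:
        return AggregatedRanking(order=list(uni), phi=0.0, method="cross-entropy", seed=seed)
    if n_samples is None:
        n_samples = 100 * n
    rng = np.random.default_rng(seed)
    ranks = lists.rank_matrix()
    w = lists.weight_matrix()
    pos_of = {t: j for j, t in enumerate(uni)}

    borda_res = borda(lists)
    borda_perm = np.array([pos_of[t] for t in borda_res.order])
    p = np.full((n, n), 1.0 / n)
    p = 0.5 * p + 0.5 * np.eye(n)[borda_perm].T  # p[item, position]

    best_perm = borda_perm.copy()
    best_phi = borda_res.phi
    trace_rows = [(0, best_phi)]
    stall = 0
    for it in range(1, max_iter + 1):
        perms = _sample_permutations(rng, p, n_samples)
        perms[0] = best_perm  # elitism: incumbent always in the pool
        phis = _phi_batch(perms, ranks, w)
        order_idx = np.argsort(phis, kind="stable")
        k_elite = max(1, math.ceil(elite_frac * n_samples))
        elite = perms[order_idx[:k_elite]]

        if phis[order_idx[0]] < best_phi:
            best_phi = float(phis[order_idx[0]])
            best_perm = perms[order_idx[0]].copy()
            stall = 0
        else:
            stall += 1
        trace_rows.append((it, best_phi))
        if stall >= patience:
            break

        freq = np.zeros((n, n))
        positions = np.arange(n)
        for e in elite:
            freq[e, positions] += 1.0
        freq /= k_elite
        p = (1.0 - smoothing) * p + smoothing * freq

    order = [uni[j] for j in best_perm]
    return AggregatedRanking(
        order=order,
        phi=best_phi,
        method="cross-entropy",
        trace=pd.DataFrame(trace_rows, columns=["iteration", "best_phi"]),
        seed=seed,
    )


def _sample_permutations(rng: np.random.Generator, p: np.ndarray, n_samples: int) -> np.ndarray:
    """Sample permutations by sequential position sampling without replacement."""
    n = p.shape[0]
    perms = np.empty((n_samples, n), dtype=np.int64)
    available = np.ones((n_samples, n), dtype=bool)
    rows = np.arange(n_samples)
    for pos in range(n):
        probs = p[:, pos][None, :] * available
        totals = probs.sum(axis=1, keepdims=True)
        dead = totals[:, 0] <= 0
        if dead.any():
            probs[dead] = available[dead].astype(float)
            totals = probs.sum(axis=1, keepdims=True)
        probs = probs / totals
        u = rng.random(n_samples)
        choice = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        choice = np.minimum(choice, n - 1)
        # guard against rounding landing on an already-used item
        bad = ~available[rows, choice]
        while bad.any():
            idx = np.flatnonzero(bad)
            for i in idx:
                choice[i] = np.flatnonzero(available[i])[0]
            bad = ~available[rows, choice]
        perms[:, pos] = choice
        available[rows, choice] = False
    return perms


def brute_force_aggregate(lists: RankedLists) -> AggregatedRanking:
    """Exhaustive minimization of Phi; refuses universes larger than 8.

    Ties resolve to the lexicographically smallest ordering (by target
    name), making the oracle fully deterministic.
    """
    uni = lists.universe
    if len(uni) > 8:
        raise AggregationError("brute force is limited to <= 8 targets")
    ranks = lists.rank_matrix()
    w = lists.weight_matrix()
    pos_of = {t: j for j, t in enumerate(uni)}
    best_order: tuple[str, ...] | None = None
    best_phi = math.inf
    for perm in itertools.permutations(sorted(uni)):
        cand = np.empty(len(uni))
        for r, t in enumerate(perm, start=1):
            cand[pos_of[t]] = r
        phi = float((w * np.abs(cand[None, :] - ranks)).sum())
        if phi < best_phi:
            best_phi = phi
            best_order = perm
    assert best_order is not None
    return AggregatedRanking(order=list(best_order), phi=best_phi, method="brute-force")
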