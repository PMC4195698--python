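"""Cq -> efficiency-corrected relative quantities; standard-curve efficiencies.

Relative quantities follow the classic multi-reference-gene convention:
replicate wells are averaged on the Cq scale, each target is referenced to
its own minimum Cq, and the linear-scale quantity is

    Q_{s,t} = F_t ** (min_s' Cq_{s',t} - Cq_{s,t})

with F_t the assay's amplification factor (2.0 at 100% efficiency), so
``Q`` lies in (0, 1] with at least one sample at 1 per target.

Amplification efficiencies come from standard dilution series: the
least-squares slope ``b`` of Cq against log10(input quantity) gives
``efficiency% = (10**(-1/b) - 1) * 100`` (slope -3.3219 = doubling = 100%).
Efficiency-corrected Cq values produced by per-well tools can be used
directly by treating them as Cq with F = 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EfficiencyFit",
    "collapse_replicates",
    "efficiency_from_dilution",
    "efficiency_table",
    "amplification_factors",
    "cq_to_relative_quantity",
    "sample_groups",
    "QuantificationError",
]

EFFICIENCY_RANGE = (90.0, 110.0)


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class EfficiencyFit:
    """Result of a standard-curve efficiency estimate for one assay."""

    target: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_percent: float
    amplification_factor: float
    in_range: bool
    source: str = "dilution-series"


def collapse_replicates(cq: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates per (sample, target) on the Cq scale.

    Returns one row per (sample, target) with the replicate mean in ``cq``,
    the replicate SD in ``cq_sd`` (NaN for singletons) and the replicate
    count in ``n_replicates``. Group labels and, when present, dilution
    quantities are carried through.
    """
    keys = ["sample", "group", "target"]
    extra = [c for c in ("quantity_ng",) if c in cq.columns]
    grouped = cq.groupby(keys + extra, sort=False)["cq"]
    out = grouped.mean().reset_index()
    out["cq_sd"] = grouped.std(ddof=1).to_numpy()
    out["n_replicates"] = grouped.size().to_numpy()
    return out


def efficiency_from_dilution(series: pd.DataFrame, target: str | None = None) -> EfficiencyFit:
    """Estimate amplification efficiency from a standard dilution series.

    ``series`` is a long Cq table with a ``quantity_ng`` column (as produced
    by :func:`erenorm.simulate.make_dilution_series`). Technical replicates
    are collapsed first. Raises on fewer than 3 distinct quantities or on a
    non-negative slope (a series that does not amplify).
    """
    if "quantity_ng" not in series.columns:
        raise QuantificationError("dilution series requires a quantity_ng column")
    df = series if target is None else series[series["target"] == target]
    if df.empty:
        raise QuantificationError(f"no rows for target {target!r}")
    name = str(df["target"].iloc[0])
    df = collapse_replicates(df)
    if df["cq"].isna().any():
        raise QuantificationError("dilution series contains missing Cq values")
    if df["quantity_ng"].nunique() < 3:
        raise QuantificationError("need >= 3 distinct input quantities")

    x = np.log10(df["quantity_ng"].to_numpy(dtype=float))
    y = df["cq"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise QuantificationError(
            f"non-amplifying series for {name!r}: slope {fit.slope:.3f} >= 0"
        )
    eff = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    lo, hi = EFFICIENCY_RANGE
    return EfficiencyFit(
        target=name,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency_percent=float(eff),
        amplification_factor=float(1.0 + eff / 100.0),
        in_range=bool(lo <= eff <= hi),
    )


def efficiency_table(fits: Iterable[EfficiencyFit]) -> pd.DataFrame:
    """Tabulate efficiency fits (columns: target, efficiency_percent, ...)."""
    rows = [
        (f.target, f.efficiency_percent, f.amplification_factor, f.slope, f.r_squared,
         f.in_range, f.source)
        for f in fits
    ]
    return pd.DataFrame(
        rows,
        columns=["target", "efficiency_percent", "amplification_factor", "slope",
                 "r2", "in_range", "source"],
    )


def amplification_factors(
    efficiencies: pd.DataFrame | Mapping[str, float] | float | None,
    targets: Iterable[str],
) -> dict[str, float]:
    """Resolve per-target amplification factors F_t.

    Accepts an efficiency table (with ``amplification_factor`` or
    ``efficiency_percent`` columns), a mapping target -> F, a single F for
    all targets, or ``None`` meaning perfect doubling (F = 2) — the
    convention for externally efficiency-corrected Cq values.
    """
    targets = list(targets)
    if efficiencies is None:
        return {t: 2.0 for t in targets}
    if isinstance(efficiencies, (int, float)):
        f = float(efficiencies)
        if f <= 1.0:
            raise QuantificationError("amplification factor must be > 1")
        return {t: f for t in targets}
    if isinstance(efficiencies, pd.DataFrame):
        df = efficiencies.set_index("target")
        if "amplification_factor" in df.columns:
            mapping = df["amplification_factor"].to_dict()
        elif "efficiency_percent" in df.columns:
            mapping = (1.0 + df["efficiency_percent"] / 100.0).to_dict()
        else:
            raise QuantificationError(
                "efficiency table needs amplification_factor or efficiency_percent"
            )
    else:
        mapping = dict(efficiencies)
    missing = [t for t in targets if t not in mapping]
    if missing:
        raise QuantificationError(f"no efficiency for targets: {missing}")
    bad = [t for t in targets if mapping[t] <= 1.0]
    if bad:
        raise QuantificationError(f"amplification factor must be > 1 for: {bad}")
    return {t: float(mapping[t]) for t in targets}


def cq_to_relative_quantity(
    cq: pd.DataFrame,
    efficiencies: pd.DataFrame | Mapping[str, float] | float | None = None,
    missing: str = "error",
) -> pd.DataFrame:
    """Convert a Cq table to a samples x targets relative-quantity matrix.

    Technical replicates are collapsed first; the result is the wide matrix
    Q_{s,t} = F_t**(min Cq_t - Cq_{s,t}) in (0, 1]. Sample group labels are
    preserved in ``result.attrs["groups"]``.

    ``missing`` controls incomplete matrices: ``"error"`` (default; the
    stability analysis requires a complete matrix) or ``"drop"`` (drop
    samples with any missing target).
    """
    if missing not in ("error", "drop"):
        raise QuantificationError("missing policy must be 'error' or 'drop'")
    flat = collapse_replicates(cq) if "replicate" in cq.columns else cq
    wide = flat.pivot(index="sample", columns="target", values="cq")
    # keep first-appearance order of samples and targets
    wide = wide.reindex(index=flat["sample"].unique(), columns=flat["target"].unique())
    if wide.isna().any().any():
        if missing == "error":
            gaps = [
                (s, t)
                for s in wide.index
                for t in wide.columns
                if pd.isna(wide.at[s, t])
            ]
            raise QuantificationError(f"missing Cq for (sample, target): {gaps[:10]}")
        wide = wide.dropna(axis=0, how="any")
        if wide.empty:
            raise QuantificationError("all samples dropped by missing-data policy")
    factors = amplification_factors(efficiencies, wide.columns)
    q = pd.DataFrame(index=wide.index, columns=wide.columns, dtype=float)
    for t in wide.columns:
        col = wide[t].to_numpy(dtype=float)
        q[t] = factors[t] ** (col.min() - col)
    group_map = flat.drop_duplicates("sample").set_index("sample")["group"]
    q.attrs["groups"] = group_map.reindex(q.index)
    return q


def sample_groups(cq: pd.DataFrame) -> pd.Series:
    """Sample -> group label mapping from a long Cq table."""
    return cq.drop_duplicates("sample").set_index("sample")["group"]
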