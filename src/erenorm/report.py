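"""Normalization-strategy comparison and run reporting.

Quantifies what the choice of reference set does to measured biology: the
fold change of a gene of interest between two sample groups after dividing
by the per-sample normalization factor (geometric mean of the reference
targets), and group-level stability statistics contrasting ERE reference
targets with classic protein-coding reference genes.

The central identity — on noiseless data the measured fold change equals
the true fold change of the gene divided by the geometric mean of the
reference targets' own fold changes — is what makes unstable references
dangerous: a reference set that itself changes 6.7-fold turns a 20-fold
biological difference into an apparent 3-fold one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import AggregatedRanking, RankedLists
from .genorm import StabilityRanking, VCurve

__all__ = [
    "FoldChangeResult",
    "GroupStabilityStats",
    "fold_change",
    "group_stability_test",
    "write_report",
    "ReportError",
]


class ReportError(ValueError):
    pass


@dataclass
class FoldChangeResult:
    """Fold change of one gene of interest under one reference set."""

    goi: str
    reference_set: list[str]
    group_a: str
    group_b: str
    fold_change: float
    normalized: pd.Series  # per-sample normalized quantities


def _geomean(x: np.ndarray) -> float:
    return float(np.exp2(np.mean(np.log2(x))))


def fold_change(
    q: pd.DataFrame,
    groups: pd.Series | Mapping[str, str],
    goi: str,
    refs: Iterable[str],
    group_a: str,
    group_b: str,
    summary: str = "geometric",
) -> FoldChangeResult:
    """Fold change of ``goi`` between ``group_a`` and ``group_b``.

    Per sample, NF(s) is the geometric mean of the reference targets'
    quantities and the normalized quantity is Q_{s,goi} / NF(s); the fold
    change is the ratio of the group summaries (geometric means by
    default; ``summary="arithmetic"`` averages normalized quantities on
    the linear scale instead).
    """
    refs = sorted(set(refs))
    if not refs:
        raise ReportError("reference set must be non-empty")
    if goi in refs:
        raise ReportError("gene of interest cannot be one of its references")
    if summary not in ("geometric", "arithmetic"):
        raise ReportError("summary must be 'geometric' or 'arithmetic'")
    missing = [t for t in [goi, *refs] if t not in q.columns]
    if missing:
        raise ReportError(f"targets absent from the quantity matrix: {missing}")
    groups = pd.Series(groups).reindex(q.index)
    a_idx = groups[groups == group_a].index
    b_idx = groups[groups == group_b].index
    if len(a_idx) == 0 or len(b_idx) == 0:
        raise ReportError(f"both groups need >= 1 sample ({group_a!r}, {group_b!r})")

    nf = np.exp2(np.log2(q[refs].to_numpy(dtype=float)).mean(axis=1))
    normalized = pd.Series(q[goi].to_numpy(dtype=float) / nf, index=q.index, name=goi)
    agg = _geomean if summary == "geometric" else np.mean
    fc = float(agg(normalized.loc[a_idx].to_numpy()) / agg(normalized.loc[b_idx].to_numpy()))
    return FoldChangeResult(
        goi=goi,
        reference_set=list(refs),
        group_a=group_a,
        group_b=group_b,
        fold_change=fc,
        normalized=normalized,
    )


@dataclass
class GroupStabilityStats:
    """Location and spread comparison of M-values between two target groups."""

    group_names: tuple[str, str]
    medians: dict[str, float]
    iqrs: dict[str, float]
    sds: dict[str, float]
    location_t: float
    location_p: float
    spread_t: float
    spread_p: float


def group_stability_test(
    m: Mapping[str, float], membership: Mapping[str, str]
) -> GroupStabilityStats:
    """Compare M-value distributions between two target groups.

    Location: two-sample equal-variance Student's t-test on the M-values.
    Spread: the same t-test applied to absolute deviations from each
    group's median (a Brown-Forsythe-style contrast). Requires >= 2
    targets per group.
    """
    labels = sorted(set(membership.values()))
    if len(labels) != 2:
        raise ReportError("membership must define exactly two groups")
    values: dict[str, np.ndarray] = {}
    for g in labels:
        vals = np.array([m[t] for t in m if membership.get(t) == g], dtype=float)
        if vals.size < 2:
            raise ReportError(f"group {g!r} needs >= 2 targets")
        values[g] = vals
    a, b = (values[g] for g in labels)
    loc = stats.ttest_ind(a, b, equal_var=True)
    dev_a = np.abs(a - np.median(a))
    dev_b = np.abs(b - np.median(b))
    spread = stats.ttest_ind(dev_a, dev_b, equal_var=True)
    return GroupStabilityStats(
        group_names=(labels[0], labels[1]),
        medians={g: float(np.median(values[g])) for g in labels},
        iqrs={g: float(np.subtract(*np.percentile(values[g], [75, 25]))) for g in labels},
        sds={g: float(np.std(values[g], ddof=1)) for g in labels},
        location_t=float(loc.statistic),
        location_p=float(loc.pvalue),
        spread_t=float(spread.statistic),
        spread_p=float(spread.pvalue),
    )


_FLOAT_FMT = "%.10g"


def write_report(
    outdir: str | Path,
    rankings: Mapping[str, StabilityRanking] | None = None,
    v_curves: Mapping[str, VCurve] | None = None,
    consensus: AggregatedRanking | None = None,
    ranked_lists: RankedLists | None = None,
    fold_changes: Iterable[FoldChangeResult] | None = None,
    stability_stats: GroupStabilityStats | None = None,
    metadata: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write the run's report tables and metadata; returns written paths.

    Produces per-experiment ranking and V-curve tables, the aggregated
    consensus (with its convergence trace), the fold-change comparison
    table and ``run_metadata.json``. Missing upstream artifacts degrade
    gracefully: the corresponding table is skipped and an explicit gap
    note is recorded in the metadata.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ReportError(f"cannot create report directory {outdir}: {exc}") from exc
    written: list[Path] = []
    gaps: list[str] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(path)

    if rankings:
        for exp in sorted(rankings):
            _write(rankings[exp].to_frame(), f"ranking_{exp}.tsv")
    else:
        gaps.append("no per-experiment rankings")
    if v_curves:
        for exp in sorted(v_curves):
            vc = v_curves[exp]
            df = vc.v.rename("V").reset_index()
            df["optimal_n"] = vc.optimal_n
            _write(df, f"vcurve_{exp}.tsv")
    if consensus is not None:
        _write(consensus.to_frame(ranked_lists), "consensus.tsv")
        if len(consensus.trace):
            _write(consensus.trace, "aggregation_trace.tsv")
    else:
        gaps.append("no aggregated consensus (rank aggregation input missing)")
    if fold_changes:
        rows = [
            {
                "goi": fc.goi,
                "references": ",".join(fc.reference_set),
                "group_a": fc.group_a,
                "group_b": fc.group_b,
                "fold_change": fc.fold_change,
            }
            for fc in fold_changes
        ]
        _write(pd.DataFrame(rows), "fold_changes.tsv")

    meta: dict[str, object] = dict(metadata or {})
    if stability_stats is not None:
        meta["group_stability"] = {
            "groups": list(stability_stats.group_names),
            "medians": stability_stats.medians,
            "iqrs": stability_stats.iqrs,
            "location_t": stability_stats.location_t,
            "location_p": stability_stats.location_p,
            "spread_t": stability_stats.spread_t,
            "spread_p": stability_stats.spread_p,
        }
    if gaps:
        meta["gaps"] = gaps
    meta["files"] = sorted(p.name for p in written)
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    written.append(meta_path)
    return written
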