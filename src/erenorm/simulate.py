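"""Synthetic RT-qPCR and repeat-sequence data with known ground truth.

Two generators drive the whole pipeline:

* :func:`generate_cq_dataset` draws quantification-cycle (Cq) matrices from
  an explicit generative model — per-target baseline Cq and amplification
  factor, a shared per-sample mRNA-content factor, target-specific
  biological variance (log-normal on the log2 scale) and technical
  replicate noise — so the downstream stability and fold-change machinery
  can be checked against designed truth.
* :func:`generate_repeat_sequences` builds a genome and a transcript set
  with planted, point-mutated copies of a repeat consensus at recorded
  coordinates, for exercising the discovery stage.

All generators are deterministic given their design's ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetSpec",
    "CqDesign",
    "TruthRecord",
    "SequenceDesign",
    "RepeatTruth",
    "generate_cq_dataset",
    "generate_repeat_sequences",
    "make_dilution_series",
    "DesignError",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class DesignError(ValueError):
    """A design field violates its contract; the message names the field."""


@dataclass(frozen=True)
class TargetSpec:
    """One qPCR assay in a simulated experiment.

    Parameters
    ----------
    name:
        Target identifier.
    amplification_factor:
        Per-cycle amplification gain ``F`` (2.0 = perfect doubling,
        i.e. 100% efficiency). Must exceed 1.
    baseline_cq:
        Cq observed for the reference quantity ``Q = 1`` (cycles).
    biological_sd:
        SD of the target's biological variability, in log2 units
        (equivalently cycles at 100% efficiency).
    group_fold_changes:
        Group label -> multiplicative expression change relative to the
        implicit baseline of 1. Groups not listed sit at 1.
    stable:
        Whether the target is a *designed* stable normalizer. ``None``
        infers it: stable iff ``biological_sd <= 0.25`` and all fold
        changes are 1.
    """

    name: str
    amplification_factor: float = 2.0
    baseline_cq: float = 25.0
    biological_sd: float = 0.0
    group_fold_changes: Mapping[str, float] = field(default_factory=dict)
    stable: bool | None = None

    def validate(self) -> None:
        if self.amplification_factor <= 1.0:
            raise DesignError(
                f"amplification_factor must be > 1 for target {self.name!r}"
            )
        if self.biological_sd < 0:
            raise DesignError(f"biological_sd must be >= 0 for target {self.name!r}")
        for group, fc in self.group_fold_changes.items():
            if fc <= 0:
                raise DesignError(
                    f"group_fold_changes[{group!r}] must be > 0 for target {self.name!r}"
                )

    def is_stable(self) -> bool:
        if self.stable is not None:
            return self.stable
        flat = all(fc == 1.0 for fc in self.group_fold_changes.values())
        return self.biological_sd <= 0.25 and flat


@dataclass(frozen=True)
class CqDesign:
    """Design of one simulated qPCR experiment (samples x targets x replicates)."""

    targets: Sequence[TargetSpec]
    groups: Sequence[str]
    n_samples: int
    sample_content_sd: float = 0.0
    technical_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise DesignError("n_samples must be >= 1")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")
        if self.sample_content_sd < 0:
            raise DesignError("sample_content_sd must be >= 0")
        if self.technical_sd < 0:
            raise DesignError("technical_sd must be >= 0")
        if not self.groups:
            raise DesignError("groups must be non-empty")
        if len(set(self.groups)) != len(self.groups):
            raise DesignError("groups must be unique")
        names = [t.name for t in self.targets]
        if len(set(names)) != len(names):
            raise DesignError("targets must have unique names")
        if not names:
            raise DesignError("targets must be non-empty")
        for t in self.targets:
            t.validate()


@dataclass
class TruthRecord:
    """Ground truth behind a generated Cq dataset.

    ``quantities`` holds the true per-sample linear-scale quantity Q for
    every target (samples x targets); geNorm and the fold-change machinery
    should recover functions of these up to per-target scale.
    """

    quantities: pd.DataFrame
    groups: pd.Series
    biological_sd: dict[str, float]
    fold_changes: dict[str, dict[str, float]]
    stable_targets: list[str]


def generate_cq_dataset(design: CqDesign) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw a Cq matrix from the generative model.

    The model: for sample ``s`` in group ``g`` and target ``t``,

        Q_{s,t} = FC_{g,t} * 2**u_s * 2**b_{s,t}
        Cq_{s,t,r} = c_t - log_{F_t}(Q_{s,t}) + eps_{s,t,r}

    with ``u_s ~ N(0, sample_content_sd)`` (shared mRNA-content factor a
    good normalizer must cancel), ``b_{s,t} ~ N(0, biological_sd_t)`` and
    ``eps ~ N(0, technical_sd)`` independent per replicate well.

    Returns the long-form Cq table (columns ``sample, group, target,
    replicate, cq``) and the :class:`TruthRecord`.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    sample_names: list[str] = []
    sample_groups: list[str] = []
    for g in design.groups:
        for i in range(design.n_samples):
            sample_names.append(f"{g}_s{i + 1}")
            sample_groups.append(g)
    n_s = len(sample_names)
    n_t = len(design.targets)

    u = rng.normal(0.0, design.sample_content_sd, size=n_s) if design.sample_content_sd > 0 else np.zeros(n_s)

    log2_q = np.empty((n_s, n_t))
    for j, t in enumerate(design.targets):
        b = rng.normal(0.0, t.biological_sd, size=n_s) if t.biological_sd > 0 else np.zeros(n_s)
        fc = np.array([t.group_fold_changes.get(g, 1.0) for g in sample_groups])
        log2_q[:, j] = np.log2(fc) + u + b
    q = np.exp2(log2_q)

    rows = []
    for j, t in enumerate(design.targets):
        log_f = np.log2(t.amplification_factor)
        base_cq = t.baseline_cq - log2_q[:, j] / log_f
        for r in range(design.n_replicates):
            eps = (
                rng.normal(0.0, design.technical_sd, size=n_s)
                if design.technical_sd > 0
                else np.zeros(n_s)
            )
            for s in range(n_s):
                rows.append(
                    (sample_names[s], sample_groups[s], t.name, r + 1, base_cq[s] + eps[s])
                )
    cq = pd.DataFrame(rows, columns=["sample", "group", "target", "replicate", "cq"])

    truth = TruthRecord(
        quantities=pd.DataFrame(q, index=sample_names, columns=[t.name for t in design.targets]),
        groups=pd.Series(sample_groups, index=sample_names, name="group"),
        biological_sd={t.name: t.biological_sd for t in design.targets},
        fold_changes={t.name: dict(t.group_fold_changes) for t in design.targets},
        stable_targets=[t.name for t in design.targets if t.is_stable()],
    )
    return cq, truth


# ---------------------------------------------------------------------------
# Sequence generation


@dataclass(frozen=True)
class SequenceDesign:
    """Design for a genome + transcriptome with planted repeat copies.

    ``substitution_rate`` is the per-base probability that a planted copy
    diverges from the consensus at that position (substitutions only, no
    indels). Transcript copies are inserted in the final third of the
    transcript, emulating repeat instances residing in 3' untranslated
    regions. Coordinates are 0-based half-open throughout.
    """

    genome_length: int = 100_000
    consensus_length: int = 300
    n_copies: int = 100
    substitution_rate: float = 0.05
    n_transcripts: int = 100
    transcript_length: int = 1_200
    fraction_with_repeat: float = 0.4
    reverse_strand_fraction: float = 0.5
    min_gap: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.substitution_rate < 0.5):
            raise DesignError("substitution_rate must be in [0, 0.5)")
        if self.consensus_length < 50:
            raise DesignError("consensus_length must be >= 50")
        if self.n_copies < 0:
            raise DesignError("n_copies must be >= 0")
        if not (0.0 <= self.fraction_with_repeat <= 1.0):
            raise DesignError("fraction_with_repeat must be in [0, 1]")
        if self.n_transcripts < 0:
            raise DesignError("n_transcripts must be >= 0")
        if self.transcript_length < 3 * self.consensus_length:
            raise DesignError(
                "transcript_length must be >= 3 * consensus_length to host a 3'-region copy"
            )
        if self.n_copies > 0:
            needed = self.n_copies * (self.consensus_length + self.min_gap)
            if self.genome_length < needed:
                raise DesignError(
                    f"genome_length {self.genome_length} too short for {self.n_copies} "
                    f"copies of {self.consensus_length} bp plus {self.min_gap} bp gaps "
                    f"(needs >= {needed})"
                )


@dataclass
class RepeatTruth:
    """Planted-copy ground truth for one generated sequence set."""

    consensus: str
    genome_copies: pd.DataFrame  # copy, subject, start, end, strand, identity
    transcript_copies: pd.DataFrame  # transcript, carries, start, end, identity


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, consensus: np.ndarray, rate: float) -> tuple[np.ndarray, float]:
    """Point-mutate a consensus copy; returns (sequence, percent identity)."""
    copy = consensus.copy()
    if rate > 0:
        hit = rng.random(copy.size) < rate
        n_mut = int(hit.sum())
        if n_mut:
            # substitute with a base different from the current one
            shift = rng.integers(1, 4, size=n_mut)
            idx = np.flatnonzero(hit)
            code_of = np.zeros(256, dtype=np.int64)
            for code, b in enumerate(_BASES):
                code_of[b] = code
            copy[idx] = _BASES[(code_of[copy[idx]] + shift) % 4]
        identity = 100.0 * (copy.size - n_mut) / copy.size
    else:
        identity = 100.0
    return copy, identity


def _revcomp_bytes(seq: np.ndarray) -> np.ndarray:
    table = np.zeros(256, dtype=np.uint8)
    table[ord("A")] = ord("T")
    table[ord("T")] = ord("A")
    table[ord("C")] = ord("G")
    table[ord("G")] = ord("C")
    table[ord("N")] = ord("N")
    return table[seq[::-1]]


def generate_repeat_sequences(
    design: SequenceDesign,
) -> tuple[dict[str, str], dict[str, str], RepeatTruth]:
    """Build a genome and transcript set with planted repeat copies.

    Returns ``(genome, transcripts, truth)`` where the sequence sets are
    ``{record id: sequence}`` mappings. The genome is a single record
    ``"chr1"``; transcripts are ``"tx0001"`` .... Each planted copy is an
    independently point-mutated consensus instance; roughly
    ``reverse_strand_fraction`` of genomic copies are inserted
    reverse-complemented. Transcript copies always sit in the final third
    of the transcript (3'-region policy).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)

    consensus = _random_dna(rng, design.consensus_length)
    genome = _random_dna(rng, design.genome_length)

    g_rows = []
    if design.n_copies > 0:
        slot = design.genome_length // design.n_copies
        span = design.consensus_length
        max_off = slot - span - design.min_gap
        for i in range(design.n_copies):
            off = int(rng.integers(0, max_off + 1)) if max_off > 0 else 0
            start = i * slot + off
            copy, identity = _mutate(rng, consensus, design.substitution_rate)
            strand = "-" if rng.random() < design.reverse_strand_fraction else "+"
            if strand == "-":
                copy = _revcomp_bytes(copy)
            genome[start : start + span] = copy
            g_rows.append((f"copy{i:04d}", "chr1", start, start + span, strand, identity))
    genome_copies = pd.DataFrame(
        g_rows, columns=["copy", "subject", "start", "end", "strand", "identity"]
    )

    transcripts: dict[str, str] = {}
    t_rows = []
    n_carrying = int(round(design.fraction_with_repeat * design.n_transcripts))
    for i in range(design.n_transcripts):
        name = f"tx{i + 1:04d}"
        seq = _random_dna(rng, design.transcript_length)
        carries = i < n_carrying
        if carries:
            lo = 2 * design.transcript_length // 3
            hi = design.transcript_length - design.consensus_length
            pos = int(rng.integers(lo, hi + 1))
            copy, identity = _mutate(rng, consensus, design.substitution_rate)
            seq[pos : pos + design.consensus_length] = copy
            t_rows.append((name, True, pos, pos + design.consensus_length, identity))
        else:
            t_rows.append((name, False, -1, -1, np.nan))
        transcripts[name] = seq.tobytes().decode("ascii")

    truth = RepeatTruth(
        consensus=consensus.tobytes().decode("ascii"),
        genome_copies=genome_copies,
        transcript_copies=pd.DataFrame(
            t_rows, columns=["transcript", "carries", "start", "end", "identity"]
        ),
    )
    return {"chr1": genome.tobytes().decode("ascii")}, transcripts, truth


# ---------------------------------------------------------------------------
# Dilution series

DEFAULT_DILUTION_LADDER = (16.0, 4.0, 1.0, 0.25, 0.0625)


def make_dilution_series(
    factor: float,
    top_cq: float = 20.0,
    quantities: Sequence[float] = DEFAULT_DILUTION_LADDER,
    technical_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    target: str = "assay",
) -> pd.DataFrame:
    """Simulate a standard dilution series for one assay.

    Cq(q) = top_cq - log_factor(q / max(q)) + noise. The default quantity
    ladder is the 16 ng -> 0.0625 ng four-fold series used for standard
    curves. Returns a long Cq table with an extra ``quantity_ng`` column,
    directly consumable by :func:`erenorm.quantify.efficiency_from_dilution`.
    """
    if factor <= 1.0:
        raise DesignError("factor must be > 1")
    q = np.asarray(quantities, dtype=float)
    if np.any(q <= 0):
        raise DesignError("quantities must be strictly positive")
    if len(np.unique(q)) < 3:
        raise DesignError("quantities must contain >= 3 distinct values")
    if n_replicates < 1:
        raise DesignError("n_replicates must be >= 1")

    rng = np.random.default_rng(seed)
    log_f = np.log2(factor)
    base = top_cq - np.log2(q / q.max()) / log_f
    rows = []
    for r in range(n_replicates):
        noise = rng.normal(0.0, technical_sd, size=q.size) if technical_sd > 0 else np.zeros(q.size)
        for i, qty in enumerate(q):
            rows.append((f"q{qty:g}", "standard", target, r + 1, base[i] + noise[i], qty))
    return pd.DataFrame(
        rows, columns=["sample", "group", "target", "replicate", "cq", "quantity_ng"]
    )
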