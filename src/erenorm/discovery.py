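"""Candidate expressed-repeat-element (ERE) discovery.

The workflow mirrors the classic repeat-library screen: for every repeat
consensus, count its genomic copies, count the transcripts that carry an
expressed instance, compute the mean conservation rate of those instances,
apply strict thresholds (copies > 100, combined expressed hits > 30, mean
conservation > 85%), and delineate the most frequently expressed, most
conserved window of the consensus as the primer-design template.

Sequence search is a self-contained k-mer seeded, ungapped diagonal
aligner (:func:`scan_sequences`): exact k-mer seeds define diagonals, each
diagonal's best-scoring ungapped segment (match +1 / mismatch -2) becomes
a hit, and hits failing identity or length floors are dropped. Overlapping
hits on one subject and strand are merged, keeping the best identity. An
adapter (:func:`hits_from_tabular`) ingests standard 12-column tabular
output from an external aligner for real-data use.

Coordinates are 0-based half-open; minus-strand hits report forward-strand
subject coordinates with ``strand == "-"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SequenceHit",
    "ScanParams",
    "Thresholds",
    "EreCandidate",
    "scan_sequences",
    "copy_number",
    "expressed_hits",
    "ExpressedHits",
    "conservation_rate",
    "filter_candidates",
    "conserved_region",
    "hits_from_tabular",
    "DiscoveryError",
]


class DiscoveryError(ValueError):
    pass


@dataclass(frozen=True)
class ScanParams:
    """Aligner parameters: seed length, identity floor (%), length floor (bp)."""

    k: int = 11
    min_identity: float = 70.0
    min_length: int = 50
    mismatch_penalty: float = 2.0

    def validate(self) -> None:
        if self.k < 8:
            raise DiscoveryError("seed length k must be >= 8")
        if not (50.0 <= self.min_identity <= 100.0):
            raise DiscoveryError("min_identity must be in [50, 100]")
        if self.min_length < 1:
            raise DiscoveryError("min_length must be >= 1")


@dataclass(frozen=True)
class SequenceHit:
    """One merged local match of a consensus against a subject sequence."""

    subject_id: str
    subject_start: int
    subject_end: int
    strand: str
    consensus_start: int
    consensus_end: int
    identity: float  # percent
    length: int


def _as_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


_RC = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC[_a] = _b


def _revcomp(arr: np.ndarray) -> np.ndarray:
    return _RC[arr[::-1]]


def _kmer_positions(seq: np.ndarray, k: int) -> dict[bytes, list[int]]:
    out: dict[bytes, list[int]] = {}
    data = seq.tobytes()
    for i in range(len(data) - k + 1):
        out.setdefault(data[i : i + k], []).append(i)
    return out


def _best_segment(match: np.ndarray, penalty: float) -> tuple[int, int] | None:
    """Max-scoring run under +1/match, -penalty/mismatch (Kadane)."""
    scores = np.where(match, 1.0, -penalty)
    best = 0.0
    best_range: tuple[int, int] | None = None
    cur = 0.0
    start = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = s
            start = i
        else:
            cur += s
        if cur > best:
            best = cur
            best_range = (start, i + 1)
    return best_range


def _normalize_subjects(subjects) -> list[tuple[str, str]]:
    if isinstance(subjects, Mapping):
        return [(str(k), str(v)) for k, v in subjects.items()]
    out = []
    for rec in subjects:
        if hasattr(rec, "seq"):  # Bio.SeqRecord
            out.append((str(rec.id), str(rec.seq)))
        else:
            sid, seq = rec
            out.append((str(sid), str(seq)))
    return out


def scan_sequences(
    consensus: str,
    subjects,
    params: ScanParams = ScanParams(),
) -> list[SequenceHit]:
    """Find local matches of ``consensus`` in ``subjects`` on both strands.

    ``subjects`` may be a mapping id -> sequence, an iterable of
    ``(id, sequence)`` pairs, or Bio.SeqRecord objects. Returns merged hits
    sorted by (subject, start).
    """
    params.validate()
    cons = _as_bytes(str(consensus))
    if cons.size < params.k:
        raise DiscoveryError("consensus shorter than the seed length")
    cons_kmers: dict[bytes, list[int]] = {}
    cdata = cons.tobytes()
    for i in range(cons.size - params.k + 1):
        cons_kmers.setdefault(cdata[i : i + params.k], []).append(i)

    hits: list[SequenceHit] = []
    for sid, seq in _normalize_subjects(subjects):
        fwd = _as_bytes(seq)
        ls = fwd.size
        if ls < params.k:
            continue
        for strand, subj in (("+", fwd), ("-", _revcomp(fwd))):
            diagonals: set[int] = set()
            data = subj.tobytes()
            for sp in range(ls - params.k + 1):
                kmer = data[sp : sp + params.k]
                cps = cons_kmers.get(kmer)
                if cps:
                    for cp in cps:
                        diagonals.add(sp - cp)
            for d in diagonals:
                c_lo = max(0, -d)
                c_hi = min(cons.size, ls - d)
                if c_hi - c_lo < params.min_length:
                    continue
                match = cons[c_lo:c_hi] == subj[c_lo + d : c_hi + d]
                seg = _best_segment(match, params.mismatch_penalty)
                if seg is None:
                    continue
                a, b = seg
                length = b - a
                if length < params.min_length:
                    continue
                identity = 100.0 * float(match[a:b].sum()) / length
                if identity < params.min_identity:
                    continue
                cs, ce = c_lo + a, c_lo + b
                ss, se = cs + d, ce + d
                if strand == "-":
                    ss, se = ls - se, ls - ss
                hits.append(
                    SequenceHit(
                        subject_id=sid,
                        subject_start=int(ss),
                        subject_end=int(se),
                        strand=strand,
                        consensus_start=int(cs),
                        consensus_end=int(ce),
                        identity=identity,
                        length=int(length),
                    )
                )
    return _merge_hits(hits)


def _merge_hits(hits: list[SequenceHit]) -> list[SequenceHit]:
    """Drop hits overlapping a better hit by > 50% of the shorter one.

    Applies per subject and strand; the survivor is the higher-identity
    (then longer) hit.
    """
    kept: list[SequenceHit] = []
    by_key: dict[tuple[str, str], list[SequenceHit]] = {}
    for h in sorted(hits, key=lambda h: (-h.identity, -h.length, h.subject_start)):
        key = (h.subject_id, h.strand)
        clash = False
        for other in by_key.get(key, []):
            ov = min(h.subject_end, other.subject_end) - max(h.subject_start, other.subject_start)
            if ov > 0.5 * min(h.length, other.length):
                clash = True
                break
        if not clash:
            by_key.setdefault(key, []).append(h)
            kept.append(h)
    return sorted(kept, key=lambda h: (h.subject_id, h.subject_start, h.strand))


def copy_number(consensus: str, genome, params: ScanParams = ScanParams()) -> int:
    """Number of merged genomic copies of a repeat consensus."""
    subjects = _normalize_subjects(genome)
    if not subjects:
        raise DiscoveryError("genome must be non-empty")
    return len(scan_sequences(consensus, subjects, params))


@dataclass
class ExpressedHits:
    """Per-collection expressed-transcript counts for one repeat."""

    per_collection: dict[str, int]
    combined: int
    hits: dict[str, list[SequenceHit]]


def expressed_hits(
    consensus: str,
    collections: Mapping[str, object],
    params: ScanParams = ScanParams(),
) -> ExpressedHits:
    """Count transcripts carrying >= 1 hit, per named collection.

    A transcript with several hit segments counts once; the combined count
    sums over collections (e.g. RefSeq + non-RefSeq).
    """
    if not collections:
        raise DiscoveryError("need >= 1 transcript collection")
    per: dict[str, int] = {}
    all_hits: dict[str, list[SequenceHit]] = {}
    for name, seqs in collections.items():
        hits = scan_sequences(consensus, seqs, params)
        per[name] = len({h.subject_id for h in hits})
        all_hits[name] = hits
    return ExpressedHits(per_collection=per, combined=sum(per.values()), hits=all_hits)


def conservation_rate(hits: Iterable[SequenceHit]) -> float:
    """Mean percent identity over hits; undefined (error) for no hits."""
    idents = [h.identity for h in hits]
    if not idents:
        raise DiscoveryError("conservation rate undefined for an empty hit list")
    return float(np.mean(idents))


@dataclass(frozen=True)
class Thresholds:
    """Strict candidate filters: copies > 100, hits > 30, conservation > 85%."""

    min_copies: int = 100
    min_combined_hits: int = 30
    min_conservation: float = 85.0

    def validate(self) -> None:
        if self.min_copies <= 0 or self.min_combined_hits <= 0 or self.min_conservation <= 0:
            raise DiscoveryError("thresholds must be positive")


@dataclass
class EreCandidate:
    """Per-repeat filter outcome and conserved-region template."""

    repeat_id: str
    copy_count: int
    hits_per_collection: dict[str, int]
    combined_hits: int
    conservation: float  # percent; NaN when no hits support it
    conservation_source: str
    passes: dict[str, bool]
    passed: bool
    region: tuple[int, int] | None


def filter_candidates(
    library: Mapping[str, str],
    genome,
    collections: Mapping[str, object],
    thresholds: Thresholds = Thresholds(),
    params: ScanParams = ScanParams(),
    conservation_source: str = "transcripts",
    region_window: int = 150,
) -> list[EreCandidate]:
    """Run the full discovery screen over a repeat consensus library.

    All three filters are evaluated for every repeat (strict inequalities)
    and retained for reporting; ``passed`` requires all three. The
    conserved region is delineated for every repeat with expressed hits.
    ``conservation_source`` selects whether the conservation rate is
    recomputed from transcript hits (default) or genomic hits.
    """
    thresholds.validate()
    if conservation_source not in ("transcripts", "genome"):
        raise DiscoveryError("conservation_source must be 'transcripts' or 'genome'")
    out: list[EreCandidate] = []
    for rid, consensus in library.items():
        genomic = scan_sequences(consensus, genome, params)
        copies = len(genomic)
        expr = expressed_hits(consensus, collections, params)
        tx_hits = [h for hs in expr.hits.values() for h in hs]
        cons_hits = tx_hits if conservation_source == "transcripts" else genomic
        conservation = conservation_rate(cons_hits) if cons_hits else float("nan")
        passes = {
            "copy_number": copies > thresholds.min_copies,
            "expressed_hits": expr.combined > thresholds.min_combined_hits,
            "conservation": bool(conservation > thresholds.min_conservation),
        }
        window = min(region_window, len(consensus))
        region = conserved_region(tx_hits, len(consensus), window) if tx_hits else None
        out.append(
            EreCandidate(
                repeat_id=rid,
                copy_count=copies,
                hits_per_collection=dict(expr.per_collection),
                combined_hits=expr.combined,
                conservation=conservation,
                conservation_source=conservation_source,
                passes=passes,
                passed=all(passes.values()),
                region=region,
            )
        )
    return out


def candidates_frame(candidates: list[EreCandidate]) -> pd.DataFrame:
    """Flatten candidates into the report table."""
    rows = []
    for c in candidates:
        row: dict[str, object] = {"repeat": c.repeat_id, "copies": c.copy_count}
        for name, count in c.hits_per_collection.items():
            row[f"hits_{name}"] = count
        row.update(
            hits_combined=c.combined_hits,
            conservation=c.conservation,
            conservation_source=c.conservation_source,
            pass_copy_number=c.passes["copy_number"],
            pass_expressed_hits=c.passes["expressed_hits"],
            pass_conservation=c.passes["conservation"],
            passed=c.passed,
            region_start=c.region[0] if c.region else -1,
            region_end=c.region[1] if c.region else -1,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def conserved_region(
    hits: Iterable[SequenceHit], consensus_length: int, window: int
) -> tuple[int, int]:
    """Fixed-length consensus window maximizing coverage x identity.

    The per-position score is the sum over covering hits of their fractional
    identity (equivalently coverage times mean identity); ties resolve to
    the earliest window.
    """
    hits = list(hits)
    if not hits:
        raise DiscoveryError("conserved region requires >= 1 hit")
    if window > consensus_length:
        raise DiscoveryError("window exceeds the consensus length")
    score = np.zeros(consensus_length)
    for h in hits:
        score[h.consensus_start : h.consensus_end] += h.identity / 100.0
    csum = np.concatenate(([0.0], np.cumsum(score)))
    window_sums = csum[window:] - csum[:-window]
    start = int(np.argmax(window_sums))  # argmax takes the earliest maximum
    return start, start + window


TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def hits_from_tabular(source) -> list[SequenceHit]:
    """Ingest 12-column tabular hits from an external aligner.

    Accepts a path or a DataFrame in the standard tabular layout (query =
    repeat consensus, 1-based inclusive coordinates; minus-strand hits have
    subject start > end). Coordinates are converted to 0-based half-open.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        if list(df.columns[: len(TABULAR_COLUMNS)]) != TABULAR_COLUMNS:
            df.columns = TABULAR_COLUMNS[: len(df.columns)]
    else:
        df = pd.read_csv(source, sep="\t", header=None, names=TABULAR_COLUMNS)
    hits = []
    for row in df.itertuples(index=False):
        ss, se = int(row.sstart), int(row.send)
        strand = "+" if ss <= se else "-"
        if strand == "-":
            ss, se = se, ss
        hits.append(
            SequenceHit(
                subject_id=str(row.sseqid),
                subject_start=ss - 1,
                subject_end=se,
                strand=strand,
                consensus_start=int(row.qstart) - 1,
                consensus_end=int(row.qend),
                identity=float(row.pident),
                length=int(row.length),
            )
        )
    return _merge_hits(hits)
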