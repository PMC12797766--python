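"""Artifact QC: TSO-concatemer detection and strand-invasion profiling.

Concatemers are flagged by exact occurrence of junction literals (both
orientations are passed as separate literals; no implicit
reverse-complementing).  Strand invasion is scored by fuzzy-matching each
deduplicated 5' UMI-read's UMI+spacer+GGG pattern against the reference
window immediately upstream of its alignment start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .design import DEFAULT_SPACER

CONCATEMER_LITERALS = ("ATATGGGCTAC", "GTAGCCCATAT")
CONCATEMER_K = 11
EXTRACTION_LITERAL = "ATTGCGCAATG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MethodConfig:
    """Per-protocol strand-invasion scoring parameters.

    ``spacer=None`` marks a variable WW spacer: the last two bases of the
    extracted UMI field are re-annotated as the observed spacer.
    """

    name: str
    umi_len: int
    spacer: str | None
    window: int = 23
    max_mismatch: int = 3
    ww_spacer_len: int = 2

    @property
    def pattern_len(self) -> int:
        if self.spacer is None:
            return self.umi_len + 3  # observed WW is part of the extracted field
        return self.umi_len + len(self.spacer) + 3


METHOD_CONFIGS = {
    "ss3x": MethodConfig(name="SS3X", umi_len=10, spacer=None),
    "pb10x": MethodConfig(name="PB10X_5p", umi_len=9, spacer=DEFAULT_SPACER),
    "tenx": MethodConfig(name="TENX_5p", umi_len=10, spacer=DEFAULT_SPACER),
}


@dataclass
class AlignedReadRecord:
    """Minimal alignment facts needed to score one 5' UMI-read."""

    cell_id: str
    umi: str
    reference: str
    start: int
    strand: str = "+"
    upstream_context: str = ""


@dataclass
class InvasionReport:
    n_dedup_reads: int
    n_flagged: int
    percent_flagged: float
    mismatch_histogram: dict[int, int]

    def as_dict(self) -> dict:
        return {
            "n_dedup_reads": self.n_dedup_reads,
            "n_flagged": self.n_flagged,
            "percent_flagged": self.percent_flagged,
            "mismatch_histogram": dict(self.mismatch_histogram),
        }


def detect_concatemers(
    r2_sequences: Iterable[str],
    literals: Sequence[str] = CONCATEMER_LITERALS,
    k: int = CONCATEMER_K,
) -> tuple[list[bool], float]:
    """Exact-substring junction-literal scan; returns per-read flags and the
    flagged fraction."""
    if k < 1:
        raise ValueError("k must be >= 1")
    for lit in literals:
        if len(lit) != k:
            raise ValueError(f"literal {lit!r} length != k={k}")
    flags = [any(lit in seq for lit in literals) for seq in r2_sequences]
    fraction = sum(flags) / len(flags) if flags else 0.0
    return flags, fraction


def _contains_within_hamming(seq: str, literal: str, hdist: int) -> bool:
    L = len(literal)
    for off in range(len(seq) - L + 1):
        mism = 0
        for a, b in zip(seq[off : off + L], literal):
            if a != b:
                mism += 1
                if mism > hdist:
                    break
        else:
            return True
    return False


def extract_5p_umi_reads(
    r1_records: Sequence[tuple[str, str]],
    literal: str = EXTRACTION_LITERAL,
    hdist: int = 1,
) -> list[tuple[str, str]]:
    """Keep read pairs whose R1 contains ``literal`` within Hamming <= hdist."""
    if hdist < 0:
        raise ValueError("hdist must be >= 0")
    return [
        (rid, seq)
        for rid, seq in r1_records
        if _contains_within_hamming(seq, literal, hdist)
    ]


def dedup_5p_reads(records: Sequence[AlignedReadRecord]) -> list[AlignedReadRecord]:
    """One record per (cell, UMI, reference, start, strand); first wins."""
    seen: set[tuple] = set()
    out = []
    for rec in records:
        key = (rec.cell_id, rec.umi, rec.reference, rec.start, rec.strand)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def invasion_pattern(record: AlignedReadRecord, config: MethodConfig) -> str:
    """UMI + spacer + GGG pattern for one record.

    For the variable-WW protocol the extracted 10-mer splits into an 8-nt
    UMI plus the observed 2-nt spacer; for fixed-spacer protocols the full
    constant spacer is appended.
    """
    if len(record.umi) != config.umi_len:
        raise ValueError(
            f"UMI length {len(record.umi)} != configured {config.umi_len}"
        )
    if config.spacer is None:
        umi = record.umi[: -config.ww_spacer_len]
        ww = record.umi[-config.ww_spacer_len :]
        return umi + ww + "GGG"
    return record.umi + config.spacer + "GGG"


def _best_anchored_mismatches(window: str, pattern: str) -> int | None:
    """Minimum substitution count over all anchored offsets of pattern in
    window; None when the window is shorter than the pattern."""
    L = len(pattern)
    if len(window) < L:
        return None
    best = None
    for off in range(len(window) - L + 1):
        mism = sum(a != b for a, b in zip(window[off : off + L], pattern))
        if best is None or mism < best:
            best = mism
    return best


def _edit_distance_substring(window: str, pattern: str) -> int:
    """agrep-style best edit distance of pattern against any window substring."""
    prev = [0] * (len(window) + 1)  # free leading gap in the window
    for ca in pattern:
        cur = [prev[0] + 1]
        for j, cb in enumerate(window, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return min(prev)  # free trailing gap


def flag_strand_invasion(
    record: AlignedReadRecord,
    config: MethodConfig,
    semantics: str = "hamming",
) -> tuple[bool, int | None]:
    """Score one deduplicated read's upstream window against its pattern.

    Default semantics count substitutions at anchored offsets; ``edit``
    allows indels (agrep-style).  Windows shorter than the pattern (contig
    edges) are never flagged.
    """
    pattern = invasion_pattern(record, config)
    window = record.upstream_context[-config.window :] if record.upstream_context else ""
    if len(window) < len(pattern):
        return False, None
    if semantics == "hamming":
        best = _best_anchored_mismatches(window, pattern)
    elif semantics == "edit":
        best = _edit_distance_substring(window, pattern)
    else:
        raise ValueError(f"unknown semantics {semantics!r}")
    if best is not None and best <= config.max_mismatch:
        return True, best
    return False, None


def extract_upstream_context(
    reference: dict[str, str],
    ref_name: str,
    start: int,
    strand: str = "+",
    window: int = 23,
) -> str:
    """Reference bases immediately 5' of the alignment start, read-oriented.

    Plus strand: ``window`` bases ending at ``start`` (0-based).  Minus
    strand: ``start`` is the alignment *end* coordinate (exclusive) and the
    following bases are reverse-complemented.  Truncated at contig edges.
    """
    seq = reference[ref_name]
    if strand == "+":
        lo = max(0, start - window)
        return seq[lo:start]
    chunk = seq[start : start + window]
    return revcomp(chunk)


def attach_contexts(
    records: Sequence[AlignedReadRecord],
    reference: dict[str, str],
    window: int = 23,
) -> list[AlignedReadRecord]:
    for rec in records:
        rec.upstream_context = extract_upstream_context(
            reference, rec.reference, rec.start, rec.strand, window
        )
    return list(records)


def records_from_tags(tags: pd.DataFrame) -> list[AlignedReadRecord]:
    """Build records from a tag table (cell_id, umi, reference, start, strand)."""
    return [
        AlignedReadRecord(
            cell_id=row.cell_id,
            umi=row.umi,
            reference=row.reference,
            start=int(row.start),
            strand=row.strand,
        )
        for row in tags.itertuples(index=False)
    ]


def strand_invasion_report(
    records: Sequence[AlignedReadRecord],
    reference: dict[str, str] | None,
    config: MethodConfig,
    semantics: str = "hamming",
    deduplicate: bool = True,
) -> InvasionReport:
    """Percentage of deduplicated 5' UMI-reads whose upstream window matches
    their UMI+spacer+GGG pattern at <= max_mismatch substitutions."""
    if deduplicate:
        records = dedup_5p_reads(records)
    if not records:
        raise ValueError("no records to score")
    if reference is not None:
        attach_contexts(records, reference, config.window)
    hist = {m: 0 for m in range(config.max_mismatch + 1)}
    n_flagged = 0
    for rec in records:
        flagged, best = flag_strand_invasion(rec, config, semantics)
        if flagged:
            n_flagged += 1
            hist[best] += 1
    return InvasionReport(
        n_dedup_reads=len(records),
        n_flagged=n_flagged,
        percent_flagged=100.0 * n_flagged / len(records),
        mismatch_histogram=hist,
    )
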