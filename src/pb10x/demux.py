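"""Read-1 parsing, whitelist barcode correction and per-cell read counting.

R1 layout is positional: bases [0,16) are the well barcode, [16,25) the UMI
and base 25 the first (constant) spacer base.  The spacer base is validated
warn-only: a mismatch is counted but the read is kept, since the base is
constant and carries no information.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Sequence

import pandas as pd

from .design import BarcodeSet, TSODesign
from .plate import PlateLayout, Well


@dataclass(frozen=True)
class ParsedR1:
    barcode_raw: str
    umi: str
    spacer_base: str
    barcode_corrected: str | None = None


def parse_read1(seq: str, design: TSODesign | None = None) -> ParsedR1:
    """Slice R1 into barcode / UMI / first spacer base."""
    design = design or TSODesign()
    need = design.barcode_len + design.umi_len + 1
    if len(seq) < need:
        raise ValueError(f"read 1 shorter than {need} nt: {len(seq)}")
    b, u = design.barcode_len, design.umi_len
    return ParsedR1(
        barcode_raw=seq[:b],
        umi=seq[b : b + u],
        spacer_base=seq[b + u : b + u + 1],
    )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def correct_barcode(
    raw: str, whitelist: BarcodeSet | Sequence[str], max_mismatch: int = 1
) -> str | None:
    """Unique whitelist barcode within Hamming <= max_mismatch, else None.

    Exact membership short-circuits; ties at the minimum distance are
    dropped (None) rather than guessed.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    barcodes = list(whitelist)
    if raw in set(barcodes):
        return raw
    best: str | None = None
    best_d = max_mismatch + 1
    tie = False
    for bc in barcodes:
        if len(bc) != len(raw):
            continue
        d = hamming(raw, bc)
        if d < best_d:
            best, best_d, tie = bc, d, False
        elif d == best_d:
            tie = True
    if best is None or tie or best_d > max_mismatch:
        return None
    return best


def assign_pools(wells: Sequence[Well], pool_size: int) -> PlateLayout:
    """Group consecutive wells into pools of ``pool_size``; ceil(n/size) pools."""
    layout = PlateLayout(wells=list(wells), pool_size=pool_size)
    assert layout.n_pools == ceil(len(wells) / pool_size)
    return layout


def demux_reads(
    r1_records: Iterable[tuple[str, str]],
    whitelist: BarcodeSet | Sequence[str],
    barcode_to_cell: dict[str, str] | None = None,
    design: TSODesign | None = None,
    max_mismatch: int = 1,
    pool_id: str = "pool1",
) -> pd.DataFrame:
    """Tag table for one pool: read_id, cell_id, umi, pool_id, status.

    ``status`` is ``exact``, ``corrected`` or ``unassigned``; every input
    read lands in exactly one row.
    """
    design = design or TSODesign()
    wl = set(whitelist)
    rows = []
    spacer_base = design.spacer[0]
    n_spacer_mismatch = 0
    for read_id, seq in r1_records:
        parsed = parse_read1(seq, design)
        if parsed.spacer_base != spacer_base:
            n_spacer_mismatch += 1
        if parsed.barcode_raw in wl:
            corrected, status = parsed.barcode_raw, "exact"
        else:
            corrected = correct_barcode(parsed.barcode_raw, list(wl), max_mismatch)
            status = "corrected" if corrected else "unassigned"
        cell = None
        if corrected is not None:
            cell = (
                barcode_to_cell.get(corrected) if barcode_to_cell else corrected
            )
        rows.append((read_id, cell, parsed.umi, pool_id, status))
    df = pd.DataFrame(rows, columns=["read_id", "cell_id", "umi", "pool_id", "status"])
    df.attrs["n_spacer_mismatch"] = n_spacer_mismatch
    return df


def reads_per_cell(tag_table: pd.DataFrame) -> pd.DataFrame:
    """Read counts per assigned cell; unassigned reads kept as one row with
    cell_id NaN so counts always sum to the input size."""
    assigned = tag_table["cell_id"].notna()
    counts = (
        tag_table.loc[assigned]
        .groupby("cell_id", sort=True)
        .size()
        .rename("n_reads")
        .reset_index()
    )
    n_unassigned = int((~assigned).sum())
    if n_unassigned:
        counts = pd.concat(
            [counts, pd.DataFrame({"cell_id": [None], "n_reads": [n_unassigned]})],
            ignore_index=True,
        )
    return counts
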