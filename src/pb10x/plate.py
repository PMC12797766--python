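"""Plate layout: wells, per-well cell/barcode assignment, and pooling."""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Sequence


@dataclass
class Well:
    well_id: str
    cell_id: str
    barcode: str


@dataclass
class PlateLayout:
    """Ordered occupied wells plus their grouping into pools.

    Pools are consecutive groups of ``pool_size`` wells in well order; each
    barcode must be unique within its pool (it identifies the well after
    pooling).
    """

    wells: list[Well]
    pool_size: int
    pools: dict[str, list[Well]] = field(init=False)

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        self.pools = {}
        for i in range(0, len(self.wells), self.pool_size):
            pool_id = f"pool{i // self.pool_size + 1}"
            group = self.wells[i : i + self.pool_size]
            seen: set[str] = set()
            for w in group:
                if w.barcode in seen:
                    raise ValueError(
                        f"duplicate barcode {w.barcode} within {pool_id}"
                    )
                seen.add(w.barcode)
            self.pools[pool_id] = group

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_cells(self) -> int:
        return len(self.wells)

    def pool_of(self, well: Well) -> str:
        idx = self.wells.index(well)
        return f"pool{idx // self.pool_size + 1}"

    def barcode_to_cell(self, pool_id: str) -> dict[str, str]:
        """Within-pool barcode -> cell_id map (valid only per pool)."""
        return {w.barcode: w.cell_id for w in self.pools[pool_id]}


def well_name(index: int, n_cols: int = 12) -> str:
    """Row-major plate coordinates: 0 -> A1, 12 -> B1 (96-well default)."""
    row, col = divmod(index, n_cols)
    if row < 26:
        return f"{chr(ord('A') + row)}{col + 1}"
    return f"W{index + 1}"


def make_layout(barcodes: Sequence[str], n_cells: int, pool_size: int) -> PlateLayout:
    """Lay out ``n_cells`` occupied wells, cycling barcodes pool by pool.

    Requires ``pool_size <= len(barcodes)`` so barcodes stay unique within
    each pool; the same barcode set is reused across pools (the pools are
    sequenced as separate libraries).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if pool_size > len(barcodes):
        raise ValueError(
            f"pool_size {pool_size} exceeds available barcodes ({len(barcodes)})"
        )
    wells = [
        Well(
            well_id=well_name(i),
            cell_id=f"cell_{i + 1:03d}",
            barcode=barcodes[i % pool_size],
        )
        for i in range(n_cells)
    ]
    layout = PlateLayout(wells=wells, pool_size=pool_size)
    expected = ceil(n_cells / pool_size)
    assert layout.n_pools == expected
    return layout
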