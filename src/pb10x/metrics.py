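"""Benchmarking statistics: subsampling, saturation curves, dropout ratios,
per-cell QC and paired-TCR recovery."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .io import xopen


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals for reported percentages."""
    return float(Decimal(str(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CountMatrix:
    """Gene x cell count matrix with a mitochondrial flag per gene."""

    counts: pd.DataFrame  # genes x cells, non-negative ints
    is_mito: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.is_mito is None:
            self.is_mito = pd.Series(
                [str(g).upper().startswith("MT-") for g in self.counts.index],
                index=self.counts.index,
            )
        else:
            self.is_mito = self.is_mito.reindex(self.counts.index, fill_value=False)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cells(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_mtx(cls, mtx_dir: str | Path) -> "CountMatrix":
        """Read a MatrixMarket triplet directory (matrix.mtx, features.tsv,
        barcodes.tsv; Cell Ranger dialect, gzip-transparent)."""
        mtx_dir = Path(mtx_dir)

        def find(stem: str) -> Path:
            for name in (f"{stem}.tsv", f"{stem}.tsv.gz", f"{stem}.mtx", f"{stem}.mtx.gz"):
                p = mtx_dir / name
                if p.exists():
                    return p
            raise FileNotFoundError(f"no {stem} file in {mtx_dir}")

        with xopen(find("matrix")) as fh:
            mat = scipy.io.mmread(fh).tocsr()
        with xopen(find("features")) as fh:
            genes = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        with xopen(find("barcodes")) as fh:
            cells = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
        counts = pd.DataFrame(mat.toarray().astype(int), index=genes, columns=cells)
        return cls(counts=counts)

    def to_mtx(self, mtx_dir: str | Path) -> None:
        mtx_dir = Path(mtx_dir)
        mtx_dir.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(self.counts.to_numpy())
        scipy.io.mmwrite(str(mtx_dir / "matrix.mtx"), sparse, field="integer")
        (mtx_dir / "features.tsv").write_text(
            "".join(f"{g}\t{g}\tGene Expression\n" for g in self.genes)
        )
        (mtx_dir / "barcodes.tsv").write_text("".join(f"{c}\n" for c in self.cells))

    @classmethod
    def from_dense_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df.astype(int))

    def to_dense_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t")


# --- subsampling and saturation -------------------------------------------


def subsample_reads(read_ids: Sequence, n_target: int, seed: int = 100) -> list:
    """Uniform sample without replacement, input order preserved."""
    total = len(read_ids)
    if not 0 <= n_target <= total:
        raise ValueError(f"n_target {n_target} outside [0, {total}]")
    if n_target == total:
        return list(read_ids)
    rng = np.random.default_rng(seed)
    keep = rng.choice(total, size=n_target, replace=False)
    keep_mask = np.zeros(total, dtype=bool)
    keep_mask[keep] = True
    return [r for r, k in zip(read_ids, keep_mask) if k]


def saturation(total_reads: int, unique_counts: int) -> float:
    """1 - unique/total: the fraction of reads that are duplicates."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if not 0 <= unique_counts <= total_reads:
        raise ValueError("unique_counts outside [0, total_reads]")
    return 1.0 - unique_counts / total_reads


@dataclass
class SaturationPoint:
    depth: int  # target reads per cell
    total_reads: int
    mean_genes_per_cell: float
    mean_umis_per_cell: float
    saturation: float


def saturation_curve(
    tagged: pd.DataFrame,
    depth_grid: Sequence[int],
    seed: int = 100,
    n_cells: int | None = None,
) -> list[SaturationPoint]:
    """Subsample gene-assigned reads to each target depth and report means.

    ``tagged`` needs cell_id / gene_id / umi columns; the unique-molecule
    key is the (cell, gene, UMI) triple.  Subsampling is global at
    n_cells x depth reads.  Grid points beyond the available depth are
    dropped with a warning.
    """
    if sorted(depth_grid) != list(depth_grid):
        raise ValueError("depth grid must be sorted ascending")
    df = tagged.dropna(subset=["gene_id"])
    df = df[df["gene_id"] != ""]
    cells = df["cell_id"].unique()
    n_cells = n_cells or len(cells)
    total = len(df)
    points = []
    for depth in depth_grid:
        n_target = depth * n_cells
        if n_target > total:
            warnings.warn(
                f"grid point {depth} reads/cell exceeds available depth; dropped"
            )
            continue
        idx = subsample_reads(range(total), n_target, seed=seed)
        sub = df.iloc[idx]
        triples = sub[["cell_id", "gene_id", "umi"]].drop_duplicates()
        per_cell_umis = triples.groupby("cell_id").size()
        per_cell_genes = triples.drop_duplicates(["cell_id", "gene_id"]).groupby("cell_id").size()
        points.append(
            SaturationPoint(
                depth=depth,
                total_reads=n_target,
                mean_genes_per_cell=float(per_cell_genes.reindex(cells, fill_value=0).mean()),
                mean_umis_per_cell=float(per_cell_umis.reindex(cells, fill_value=0).mean()),
                saturation=saturation(n_target, len(triples)),
            )
        )
    return points


def saturation_table(points: Sequence[SaturationPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "depth": p.depth,
                "total_reads": p.total_reads,
                "mean_genes_per_cell": p.mean_genes_per_cell,
                "mean_umis_per_cell": p.mean_umis_per_cell,
                "saturation": p.saturation,
            }
            for p in points
        ]
    )


# --- matrix summaries ------------------------------------------------------


def dropout_ratio(matrix: CountMatrix) -> pd.Series:
    """Per gene: fraction of cells with a zero count (1 = never detected)."""
    counts = matrix.counts
    if counts.shape[1] == 0 or counts.shape[0] == 0:
        raise ValueError("empty matrix")
    return (counts == 0).sum(axis=1) / counts.shape[1]


def per_cell_qc(matrix: CountMatrix) -> pd.DataFrame:
    """Per cell: genes detected, total UMIs, percent mitochondrial counts.

    percent_mito is NaN for cells with zero total counts.
    """
    counts = matrix.counts
    if counts.shape[1] == 0:
        raise ValueError("empty matrix")
    totals = counts.sum(axis=0)
    genes_detected = (counts > 0).sum(axis=0)
    mito_totals = counts.loc[matrix.is_mito].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(totals > 0, 100.0 * mito_totals / totals, np.nan)
    return pd.DataFrame(
        {
            "cell_id": counts.columns,
            "genes_detected": genes_detected.to_numpy(),
            "total_umis": totals.to_numpy(),
            "percent_mito": pct,
        }
    )


# --- TCR recovery ----------------------------------------------------------

_TRUTHY = {"T", "TRUE", "True", "true", "1", True}


def _as_bool(v) -> bool:
    return v in _TRUTHY


def read_airr(path: str | Path) -> pd.DataFrame:
    """Tolerant AIRR TSV reader; maps T/True/TRUE strings to booleans."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return df


def tcr_recovery(
    airr: pd.DataFrame,
    cell_universe: Sequence[str],
) -> dict:
    """Percent of cells with a qualifying TRA, TRB, and both.

    A chain qualifies iff productive and complete (V, J and CDR3 all
    identified).  The denominator is every assayed cell, rows or not.
    Percentages are half-up rounded to 2 decimals.
    """
    cells = list(dict.fromkeys(cell_universe))
    if not cells:
        raise ValueError("empty cell universe")
    qual_tra: set[str] = set()
    qual_trb: set[str] = set()
    for row in airr.itertuples(index=False):
        productive = _as_bool(getattr(row, "productive", "F"))
        if hasattr(row, "complete_vdj"):
            complete = _as_bool(row.complete_vdj)
            has_v = has_j = complete
        else:
            has_v = bool(getattr(row, "v_call", ""))
            has_j = bool(getattr(row, "j_call", ""))
        cdr3 = getattr(row, "junction_aa", "")
        has_cdr3 = bool(cdr3) and cdr3 != "None"
        if not (productive and has_v and has_j and has_cdr3):
            continue
        locus = getattr(row, "locus", None) or str(getattr(row, "v_call", ""))[:3]
        if locus == "TRA":
            qual_tra.add(row.cell_id)
        elif locus == "TRB":
            qual_trb.add(row.cell_id)
    universe = set(cells)
    tra = qual_tra & universe
    trb = qual_trb & universe
    n = len(cells)
    return {
        "pct_TRA": _round2(100.0 * len(tra) / n),
        "pct_TRB": _round2(100.0 * len(trb) / n),
        "pct_paired": _round2(100.0 * len(tra & trb) / n),
        "n_cells": n,
    }
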