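"""Synthetic data with ground truth: toy transcriptome, expression counts,
read pairs in the plate-based 5' geometry, and toy AIRR contig tables.

Read 1 is always barcode(16) + UMI(9) + the first spacer base = 26 nt; read 2
is a fixed 90 nt.  Two artifact classes can be injected per read:

``concatemer``
    R2 is a chain of TSO copies, so it contains the spacer/GGG/handle
    junction motif ``ATATGGGCTAC``.

``strand_invasion``
    R2 starts at an internal transcript position whose upstream reference
    context carries the read's own UMI + spacer + GGG pattern (optionally
    mutated); the pattern is written into the reference, so ground truth is
    exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import TSODesign
from .io import write_fasta, write_fastq, write_gtf, write_tsv
from .plate import PlateLayout

R1_LENGTH = 26
R2_LENGTH = 90
QUAL_CHAR = "I"  # constant Q40; qualities are never consumed downstream

CONCATEMER_MOTIF = "ATATGGGCTAC"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class Transcript:
    gene_id: str
    sequence: str
    is_mito: bool


@dataclass
class ToyTranscriptome:
    transcripts: list[Transcript]

    @property
    def gene_ids(self) -> list[str]:
        return [t.gene_id for t in self.transcripts]

    def as_dict(self) -> dict[str, str]:
        return {t.gene_id: t.sequence for t in self.transcripts}

    def write(self, fasta_path: str | Path, gtf_path: str | Path | None = None) -> None:
        write_fasta(self.as_dict(), fasta_path)
        if gtf_path is not None:
            rows = [
                {
                    "seqname": t.gene_id,
                    "feature": "exon",
                    "start": 0,
                    "end": len(t.sequence),
                    "strand": "+",
                    "attributes": {"gene_id": t.gene_id, "gene_type": "Mt_tRNA" if t.is_mito else "protein_coding"},
                }
                for t in self.transcripts
            ]
            write_gtf(rows, gtf_path)


@dataclass
class ExpressionTruth:
    counts: pd.DataFrame  # genes x cells
    mean: float
    dispersion: float
    seed: int


@dataclass
class SimulatedReads:
    """Paths plus the in-memory truth/tag tables for one simulation."""

    r1_paths: dict[str, Path]
    r2_paths: dict[str, Path]
    truth: pd.DataFrame  # read_id, cell_id, gene_id, umi, artifact_class, pool_id
    tags: pd.DataFrame  # read_id, cell_id, umi, reference, start, strand
    reference: dict[str, str]  # post-injection transcript sequences


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_transcriptome(
    n_genes: int,
    mito_fraction: float = 0.0,
    length_range: tuple[int, int] = (400, 1500),
    seed: int = 0,
    mito_length_range: tuple[int, int] = (70, 199),
) -> ToyTranscriptome:
    """Random transcriptome; mito genes are drawn short (< 200 nt)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= mito_fraction <= 1:
        raise ValueError("mito_fraction must be in [0, 1]")
    lo, hi = length_range
    if lo >= hi or lo < R2_LENGTH:
        raise ValueError(f"degenerate length range {length_range}")
    rng = np.random.default_rng(seed)
    n_mito = int(round(n_genes * mito_fraction))
    transcripts = []
    for i in range(n_genes):
        is_mito = i < n_mito
        a, b = mito_length_range if is_mito else length_range
        length = int(rng.integers(a, b + 1))
        gene_id = f"MT-G{i + 1}" if is_mito else f"GENE{i + 1}"
        transcripts.append(Transcript(gene_id, _random_dna(rng, length), is_mito))
    return ToyTranscriptome(transcripts)


def simulate_expression(
    layout: PlateLayout,
    transcriptome: ToyTranscriptome,
    mean: float = 5.0,
    dispersion: float = 2.0,
    seed: int = 0,
) -> ExpressionTruth:
    """Negative-binomial counts per gene x cell (var = m + m^2/dispersion)."""
    if mean < 0 or dispersion <= 0:
        raise ValueError("mean must be >= 0 and dispersion > 0")
    rng = np.random.default_rng(seed)
    genes = transcriptome.gene_ids
    cells = [w.cell_id for w in layout.wells]
    if mean == 0:
        mat = np.zeros((len(genes), len(cells)), dtype=int)
    else:
        p = dispersion / (dispersion + mean)
        mat = rng.negative_binomial(dispersion, p, size=(len(genes), len(cells)))
    counts = pd.DataFrame(mat, index=genes, columns=cells)
    return ExpressionTruth(counts=counts, mean=mean, dispersion=dispersion, seed=seed)


class _InvasionSiteAllocator:
    """Hands out non-overlapping internal positions for pattern injection.

    Sites within one transcript are spaced so a later write never clobbers
    an earlier read's upstream context.
    """

    def __init__(self, sequences: dict[str, str], pattern_len: int, window: int = 23):
        self.pattern_len = pattern_len
        # earliest usable start leaves a full window upstream
        self.cursors = {g: window for g in sequences}
        self.limits = {g: len(s) - 1 for g, s in sequences.items()}
        self.order = list(sequences)
        self.next_idx = 0

    def take(self, preferred_gene: str) -> tuple[str, int]:
        candidates = [preferred_gene] + self.order
        for _ in range(len(self.order) + 1):
            gene = candidates[0] if candidates else None
            if candidates:
                gene = candidates.pop(0)
            if gene is None:
                break
            start = self.cursors[gene]
            if start <= self.limits[gene]:
                self.cursors[gene] = start + self.pattern_len
                return gene, start
        raise RuntimeError(
            "transcriptome too small to host the requested number of "
            "strand-invasion sites; use more or longer transcripts"
        )


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        alt = [b for b in _BASES if b != arr[i]]
        arr[i] = alt[int(rng.integers(3))]
    return arr.tobytes().decode()


def _concatemer_r2(barcode: str, design: TSODesign, rng: np.random.Generator) -> str:
    unit = design.spacer + design.tail + design.handle
    seq = design.handle + barcode + (unit * 4)
    return seq[:R2_LENGTH]


def simulate_reads(
    truth: ExpressionTruth,
    layout: PlateLayout,
    design: TSODesign | None = None,
    depth_per_cell: int = 100,
    concatemer_rate: float = 0.0,
    invasion_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    transcriptome: ToyTranscriptome | None = None,
    invasion_mismatches: int = 0,
) -> SimulatedReads:
    """Emit ``depth_per_cell`` read pairs per occupied well, with artifacts.

    Each read independently becomes a concatemer (prob ``concatemer_rate``),
    a strand-invasion read (prob ``invasion_rate``) or a normal 5'-proximal
    read.  One R1/R2 FASTQ pair is written per pool (plain ``R1.fastq.gz``
    when there is a single pool).  Only mappable reads (normal + invasion)
    appear in the alignment tag table.
    """
    design = design or TSODesign()
    if depth_per_cell < 1:
        raise ValueError("depth_per_cell must be >= 1")
    if not layout.wells:
        raise ValueError("empty layout")
    for rate in (concatemer_rate, invasion_rate, error_rate):
        if not 0 <= rate <= 1:
            raise ValueError("rates must be in [0, 1]")
    if concatemer_rate + invasion_rate > 1:
        raise ValueError("concatemer_rate + invasion_rate must be <= 1")
    if transcriptome is None:
        raise ValueError("a ToyTranscriptome is required")
    if not 0 <= invasion_mismatches <= 3:
        raise ValueError("invasion_mismatches must be in [0, 3]")

    rng = np.random.default_rng(seed)
    # `reference` receives the invasion-pattern writes and is what gets
    # written to reference.fasta; R2 content is always sliced from the
    # pristine transcript sequences so injected patterns never leak into
    # other reads' sequences.
    pristine = {t.gene_id: t.sequence for t in transcriptome.transcripts}
    reference = dict(pristine)
    genes = list(reference)
    pattern_len = design.umi_len + len(design.spacer) + len(design.tail)
    allocator = _InvasionSiteAllocator(reference, pattern_len)

    counts = truth.counts
    truth_rows: list[tuple] = []
    tag_rows: list[tuple] = []
    pool_records: dict[str, tuple[list, list]] = {p: ([], []) for p in layout.pools}

    read_no = 0
    for pool_id, wells in layout.pools.items():
        r1_recs, r2_recs = pool_records[pool_id]
        for well in wells:
            col = counts[well.cell_id].to_numpy()
            total = col.sum()
            probs = col / total if total > 0 else None
            for _ in range(depth_per_cell):
                read_no += 1
                read_id = f"read_{read_no:08d}"
                umi = _random_dna(rng, design.umi_len)
                u = rng.random()
                if u < concatemer_rate:
                    artifact = "concatemer"
                    gene = ""
                    r2 = _concatemer_r2(well.barcode, design, rng)
                else:
                    gene = (
                        genes[int(rng.choice(len(genes), p=probs))]
                        if probs is not None
                        else genes[int(rng.integers(len(genes)))]
                    )
                    if u < concatemer_rate + invasion_rate:
                        artifact = "strand_invasion"
                        gene, start = allocator.take(gene)
                        pattern = umi + design.spacer + design.tail
                        if invasion_mismatches:
                            pat = list(pattern)
                            pos = rng.choice(pattern_len, size=invasion_mismatches, replace=False)
                            for p_i in pos:
                                alt = [c for c in "ACGT" if c != pat[p_i]]
                                pat[p_i] = alt[int(rng.integers(3))]
                            pattern = "".join(pat)
                        seq = reference[gene]
                        reference[gene] = seq[: start - pattern_len] + pattern + seq[start:]
                        r2 = None  # sliced after all injections
                        tag_rows.append((read_id, well.cell_id, umi, gene, start, "+"))
                    else:
                        artifact = "normal"
                        start = 0
                        r2 = None
                        tag_rows.append((read_id, well.cell_id, umi, gene, 0, "+"))
                r1 = well.barcode + umi + design.spacer[0]
                truth_rows.append((read_id, well.cell_id, gene, umi, artifact, pool_id, start if artifact != "concatemer" else -1))
                r1_recs.append([read_id, r1])
                r2_recs.append([read_id, r2])

    # slice R2 for mappable reads from the pristine sequences
    start_by_read = {r[0]: r[6] for r in truth_rows}
    gene_by_read = {r[0]: r[2] for r in truth_rows}
    for pool_id, (r1_recs, r2_recs) in pool_records.items():
        for rec in r2_recs:
            if rec[1] is None:
                seq = pristine[gene_by_read[rec[0]]]
                start = start_by_read[rec[0]]
                chunk = seq[start : start + R2_LENGTH]
                rec[1] = chunk + "A" * (R2_LENGTH - len(chunk))

    # sequencing errors, applied uniformly to both mates
    for pool_id, (r1_recs, r2_recs) in pool_records.items():
        for rec in r1_recs:
            rec[1] = _apply_errors(rec[1], rng, error_rate)
        for rec in r2_recs:
            rec[1] = _apply_errors(rec[1], rng, error_rate)

    truth_df = pd.DataFrame(
        truth_rows,
        columns=["read_id", "cell_id", "gene_id", "umi", "artifact_class", "pool_id", "start"],
    ).drop(columns=["start"])
    tags_df = pd.DataFrame(
        tag_rows, columns=["read_id", "cell_id", "umi", "reference", "start", "strand"]
    )

    r1_paths: dict[str, Path] = {}
    r2_paths: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        single = len(pool_records) == 1
        for pool_id, (r1_recs, r2_recs) in pool_records.items():
            tag = "" if single else f".{pool_id}"
            r1_paths[pool_id] = out_dir / f"R1{tag}.fastq.gz"
            r2_paths[pool_id] = out_dir / f"R2{tag}.fastq.gz"
            write_fastq(((i, s, QUAL_CHAR * len(s)) for i, s in r1_recs), r1_paths[pool_id])
            write_fastq(((i, s, QUAL_CHAR * len(s)) for i, s in r2_recs), r2_paths[pool_id])
        write_tsv(truth_df, out_dir / "truth.tsv")
        write_tsv(tags_df, out_dir / "tags.tsv")
        write_fasta(reference, out_dir / "reference.fasta")
    result = SimulatedReads(
        r1_paths=r1_paths, r2_paths=r2_paths, truth=truth_df, tags=tags_df, reference=reference
    )
    # keep raw sequences reachable for in-memory pipelines
    result.r1_records = {p: [(i, s) for i, s in recs[0]] for p, recs in pool_records.items()}  # type: ignore[attr-defined]
    result.r2_records = {p: [(i, s) for i, s in recs[1]] for p, recs in pool_records.items()}  # type: ignore[attr-defined]
    return result


# --- toy AIRR tables -------------------------------------------------------

_TRA = {"v_call": "TRAV8-4", "j_call": "TRAJ3", "junction_aa": "CAVSDLEPNSSASKIIF"}
_TRB = {"v_call": "TRBV12-3", "j_call": "TRBJ1-2", "junction_aa": "CASSFSTCSANYGYTF"}

AIRR_CATEGORIES = ("paired", "alpha_only", "beta_only", "unproductive", "none")


def simulate_airr(
    layout: PlateLayout,
    pair_rate: float = 0.8,
    alpha_only_rate: float = 0.05,
    beta_only_rate: float = 0.05,
    unproductive_rate: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Toy AIRR contig table + per-cell category truth.

    Each cell is assigned one category: a productive TRA+TRB pair, a single
    productive chain, unproductive-only contigs, or no contigs at all.
    """
    rates = (pair_rate, alpha_only_rate, beta_only_rate, unproductive_rate)
    if any(not 0 <= r <= 1 for r in rates) or sum(rates) > 1 + 1e-12:
        raise ValueError("rates must be in [0, 1] and sum to <= 1")
    rng = np.random.default_rng(seed)
    probs = list(rates) + [1.0 - sum(rates)]
    rows = []
    truth_rows = []
    for well in layout.wells:
        cat = AIRR_CATEGORIES[int(rng.choice(5, p=probs))]
        truth_rows.append((well.cell_id, cat))
        chains = {
            "paired": [("TRA", True), ("TRB", True)],
            "alpha_only": [("TRA", True)],
            "beta_only": [("TRB", True)],
            "unproductive": [("TRA", False), ("TRB", False)],
            "none": [],
        }[cat]
        for locus, productive in chains:
            info = _TRA if locus == "TRA" else _TRB
            rows.append(
                {
                    "cell_id": well.cell_id,
                    "locus": locus,
                    "v_call": info["v_call"],
                    "j_call": info["j_call"],
                    "junction_aa": info["junction_aa"],
                    "productive": "T" if productive else "F",
                    "complete_vdj": "T",
                }
            )
    airr = pd.DataFrame(
        rows,
        columns=["cell_id", "locus", "v_call", "j_call", "junction_aa", "productive", "complete_vdj"],
    )
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "category"])
    return airr, truth
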