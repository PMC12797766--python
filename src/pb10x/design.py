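"""Well-specific barcode selection and barcoded-TSO assembly.

The template-switching oligo (TSO) used here carries, 5' to 3': a read-1
PCR handle, a 16-nt well-specific barcode, a 9-nt UMI, a constant spacer
and three riboguanines (represented as ``GGG`` in the DNA alphabet).
Barcodes are drawn from a vendor whitelist under a minimum pairwise
Levenshtein-distance constraint so that well identity survives synthesis
and sequencing errors.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")

#: read-1 PCR handle (22 nt) used by the default design
DEFAULT_HANDLE = "CTACACGACGCTCTTCCGATCT"
#: constant spacer between the UMI and the riboguanine tail
DEFAULT_SPACER = "TTTCTTATAT"


class BarcodeSelectionError(RuntimeError):
    """Raised when no subset of the requested size satisfies the distance bound."""

    def __init__(self, requested: int, found: Sequence[str], d_min: int):
        self.requested = requested
        self.found = list(found)
        self.d_min = d_min
        super().__init__(
            f"could not select {requested} barcodes at pairwise Levenshtein >= "
            f"{d_min}; largest set found has {len(found)} barcodes"
        )


@dataclass(frozen=True)
class TSODesign:
    """Segment template of the barcoded TSO."""

    handle: str = DEFAULT_HANDLE
    barcode_len: int = 16
    umi_len: int = 9
    spacer: str = DEFAULT_SPACER
    tail: str = "GGG"
    blocked_5p: bool = True

    def __post_init__(self) -> None:
        for name in ("handle", "spacer", "tail"):
            seq = getattr(self, name)
            if not seq or not set(seq) <= DNA_ALPHABET:
                raise ValueError(f"{name} must be a non-empty A/C/G/T string: {seq!r}")
        if self.barcode_len < 1 or self.umi_len < 1:
            raise ValueError("barcode_len and umi_len must be positive")

    @property
    def oligo_length(self) -> int:
        return len(self.handle) + self.barcode_len + self.umi_len + len(self.spacer) + len(self.tail)


@dataclass(frozen=True)
class Oligo:
    name: str
    sequence: str
    modifications: tuple[str, ...] = ()


@dataclass
class BarcodeSet:
    """Barcodes with a verified minimum pairwise Levenshtein distance."""

    barcodes: list[str]
    d_min: int

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise ValueError("barcodes must all have the same length")
        bad = min_pairwise_distance(self.barcodes)
        if bad is not None and bad < self.d_min:
            raise ValueError(
                f"pairwise Levenshtein distance {bad} violates d_min={self.d_min}"
            )

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    def __contains__(self, item: str) -> bool:
        return item in set(self.barcodes)


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion).

    Accepts sequences over ``{A,C,G,T,N}``; ``N`` matches only itself.
    Empty strings are allowed.
    """
    for s in (a, b):
        if not set(s) <= DNA_ALPHABET_N:
            raise ValueError(f"sequence contains non-ACGTN characters: {s!r}")
    if len(a) < len(b):
        a, b = b, a
    # one-row DP over the shorter string
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, start=1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (ca != cb),
            )
        prev = cur
    return prev[-1]


def min_pairwise_distance(barcodes: Sequence[str]) -> int | None:
    """Minimum Levenshtein distance over all pairs; None for < 2 barcodes."""
    if len(barcodes) < 2:
        return None
    return min(levenshtein(a, b) for a, b in combinations(barcodes, 2))


def select_barcodes(
    whitelist: Sequence[str],
    n: int,
    d_min: int,
    order: str = "greedy",
) -> BarcodeSet:
    """Select ``n`` whitelist barcodes with pairwise Levenshtein >= ``d_min``.

    The default ``greedy`` policy walks the whitelist in its given order and
    accepts a candidate iff it is at distance >= ``d_min`` from every barcode
    accepted so far.  This is deterministic and reproduces any published set
    when the whitelist is seeded with that set.  The ``exhaustive`` policy
    enumerates subsets on the pairwise-distance graph and is only feasible
    for toy whitelists (<= ~20 entries).

    Raises :class:`BarcodeSelectionError` when the policy cannot reach ``n``;
    the error carries the largest set found.
    """
    if not whitelist:
        raise ValueError("empty whitelist")
    if n < 1:
        raise ValueError("n must be >= 1")
    if d_min < 0:
        raise ValueError("d_min must be >= 0")
    lengths = {len(b) for b in whitelist}
    if len(lengths) > 1:
        raise ValueError("whitelist entries have inconsistent lengths")
    for bc in whitelist:
        if not set(bc) <= DNA_ALPHABET:
            raise ValueError(f"whitelist barcode contains non-ACGT characters: {bc!r}")

    if order == "greedy":
        accepted: list[str] = []
        for cand in whitelist:
            if cand in accepted:
                continue
            if all(levenshtein(cand, kept) >= d_min for kept in accepted):
                accepted.append(cand)
                if len(accepted) == n:
                    return BarcodeSet(accepted, d_min)
        raise BarcodeSelectionError(n, accepted, d_min)

    if order == "exhaustive":
        best = _max_clique(list(dict.fromkeys(whitelist)), d_min)
        if len(best) >= n:
            return BarcodeSet(best[:n], d_min)
        raise BarcodeSelectionError(n, best, d_min)

    raise ValueError(f"unknown selection policy: {order!r}")


def _max_clique(items: list[str], d_min: int) -> list[str]:
    """Largest subset with all pairwise distances >= d_min (branch and bound)."""
    n = len(items)
    ok = [[levenshtein(items[i], items[j]) >= d_min for j in range(n)] for i in range(n)]
    best: list[int] = []

    def extend(clique: list[int], candidates: list[int]) -> None:
        nonlocal best
        if len(clique) + len(candidates) <= len(best):
            return
        if not candidates:
            if len(clique) > len(best):
                best = clique[:]
            return
        for idx, v in enumerate(candidates):
            extend(clique + [v], [u for u in candidates[idx + 1 :] if ok[v][u]])

    extend([], list(range(n)))
    return [items[i] for i in best]


def assemble_tso(barcode: str, design: TSODesign | None = None, name: str | None = None) -> Oligo:
    """Assemble the full TSO for one well barcode (UMI positions as ``N``)."""
    design = design or TSODesign()
    if len(barcode) != design.barcode_len:
        raise ValueError(
            f"barcode length {len(barcode)} != design barcode_len {design.barcode_len}"
        )
    if not set(barcode) <= DNA_ALPHABET:
        raise ValueError(f"barcode contains non-ACGT characters: {barcode!r}")
    seq = design.handle + barcode + "N" * design.umi_len + design.spacer + design.tail
    mods = ("5' biotin",) if design.blocked_5p else ()
    return Oligo(name=name or f"TSO_{barcode}", sequence=seq, modifications=mods)


def read_whitelist(path: str | Path) -> list[str]:
    """Read a barcode whitelist: one uppercase barcode per line, gzip-transparent."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    for bc in barcodes:
        if not set(bc) <= DNA_ALPHABET:
            raise ValueError(f"whitelist barcode contains non-ACGT characters: {bc!r}")
    return barcodes


def write_order_sheet(oligos: Iterable[Oligo], prefix: str | Path) -> tuple[Path, Path]:
    """Write a TSV (name, sequence, modifications) and a FASTA mirror.

    Returns (tsv_path, fasta_path).
    """
    oligos = list(oligos)
    if not oligos:
        raise ValueError("no oligos to write")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = prefix.with_suffix(".tsv")
    fasta_path = prefix.with_suffix(".fasta")
    with open(tsv_path, "w") as tsv:
        tsv.write("name\tsequence\tmodifications\n")
        for o in oligos:
            tsv.write(f"{o.name}\t{o.sequence}\t{';'.join(o.modifications)}\n")
    with open(fasta_path, "w") as fa:
        for o in oligos:
            fa.write(f">{o.name}\n{o.sequence}\n")
    return tsv_path, fasta_path


def read_order_sheet(tsv_path: str | Path) -> list[Oligo]:
    oligos = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["name", "sequence"]:
            raise ValueError("not an order sheet TSV")
        for line in fh:
            name, seq, mods = (line.rstrip("\n").split("\t") + [""])[:3]
            oligos.append(Oligo(name, seq, tuple(m for m in mods.split(";") if m)))
    return oligos
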