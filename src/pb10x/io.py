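"""Gzip-transparent readers and writers for the formats the toolkit touches."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd


def xopen(path: str | Path, mode: str = "rt") -> IO:
    """Open plain or gzipped text transparently, by suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA as an ordered {id: sequence} dict."""
    records: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with xopen(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    items = records.items() if isinstance(records, dict) else records
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with xopen(path, "wt") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a FASTQ file."""
    with xopen(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            qual = fh.readline().rstrip("\n")
            yield header.rstrip("\n")[1:].split()[0], seq, qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write (read_id, sequence, quality) triples; returns the record count."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = 0
    with xopen(path, "wt") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_gtf(rows: Iterable[dict], path: str | Path) -> None:
    """Minimal GTF writer; rows carry seqname/source/feature/start/end/strand/attributes.

    Starts are expected 0-based half-open and converted to GTF's 1-based
    inclusive convention here.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with xopen(path, "wt") as fh:
        for r in rows:
            attrs = "; ".join(f'{k} "{v}"' for k, v in r.get("attributes", {}).items())
            fh.write(
                "\t".join(
                    [
                        r["seqname"],
                        r.get("source", "pb10x"),
                        r.get("feature", "exon"),
                        str(r["start"] + 1),
                        str(r["end"]),
                        ".",
                        r.get("strand", "+"),
                        ".",
                        attrs + ";",
                    ]
                )
                + "\n"
            )
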