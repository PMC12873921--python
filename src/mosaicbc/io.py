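"""File formats: FASTQ(.gz), count/abundance TSV, sample sheets, tallies."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, List, Sequence, Tuple, Union

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .extract import SampleSheet, SequencingRead
from .stats import TwoColorTally

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: PathLike) -> Iterator[SequencingRead]:
    """Iterate FASTQ (optionally gzip-compressed) as SequencingRead objects."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield SequencingRead(
                read_id=title.split()[0], sequence=seq.upper(), quality=qual
            )


def write_fastq(
    records: Iterable[Tuple[str, str, str]], path: PathLike
) -> int:
    """Write (id, sequence, quality) triples as FASTQ; returns record count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for read_id, seq, qual in records:
            handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_count_table(path: PathLike) -> pd.DataFrame:
    """Barcode x sample integer count table from TSV (first column = barcode)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index.name = "barcode"
    return table.astype("int64")


def write_count_table(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index_label="barcode")


def read_sample_sheet(path: PathLike, max_mismatch: int = 1) -> SampleSheet:
    """Two-column TSV (sample_id, barcode), no header required."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["sample_id", "barcode"], dtype=str
    )
    if df["sample_id"].iloc[0].lower() in ("sample", "sample_id"):
        df = df.iloc[1:]
    return SampleSheet(
        entries=dict(zip(df["sample_id"], df["barcode"].str.upper())),
        max_mismatch=max_mismatch,
    )


def write_sample_sheet(sheet: SampleSheet, path: PathLike) -> None:
    with open(path, "w") as handle:
        for sample_id, barcode in sheet.entries.items():
            handle.write(f"{sample_id}\t{barcode}\n")


def write_truth_table(fish_truths, path: PathLike) -> None:
    """Ground-truth TSV: fish_id, barcode, clone_size."""
    with open(path, "w") as handle:
        handle.write("fish_id\tbarcode\tclone_size\n")
        for truth in fish_truths:
            for barcode, cells in sorted(truth.barcode_to_cells.items()):
                handle.write(f"{truth.fish_id}\t{barcode}\t{cells}\n")


def read_truth_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"clone_size": "int64"})


def read_tally_table(path: PathLike) -> List[TwoColorTally]:
    """TSV with columns fish, green_only, red_only, double_positive."""
    df = pd.read_csv(path, sep="\t")
    return [
        TwoColorTally(
            green_only=int(row.green_only),
            red_only=int(row.red_only),
            double_positive=int(row.double_positive),
            label=str(row.fish),
        )
        for row in df.itertuples()
    ]


def write_tally_table(tallies: Sequence[TwoColorTally], path: PathLike) -> None:
    with open(path, "w") as handle:
        handle.write("fish\tgreen_only\tred_only\tdouble_positive\n")
        for t in tallies:
            handle.write(f"{t.label}\t{t.green_only}\t{t.red_only}\t{t.double_positive}\n")
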