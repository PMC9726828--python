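"""Genomic interval and gene-annotation containers plus the flat-file formats
the pipeline consumes.

All coordinates are 0-based half-open (BED convention). Chromosome names are
matched as exact strings; no "chr" normalization is attempted, so an
annotation/peak naming mismatch yields zero overlap (the scoring stage warns
when that happens).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        # distance computations measure from here to the TSS
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """The binding regions of one transcription factor (or one evidence track).

    An empty interval list is legal: a TF with no binding regions simply
    scores zero everywhere.
    """

    tf_name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}


class GeneAnnotation:
    """Gene identifiers with chromosome, TSS coordinate and strand.

    This is the coordinate frame for every distance computation downstream.
    Backed by a DataFrame indexed by gene_id with columns chrom/tss/strand.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"gene_id", "chrom", "tss", "strand"}
        if not required.issubset(df.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene_id: {dup.iloc[0]!r}")
        if (df["tss"] < 0).any():
            bad = df.loc[df["tss"] < 0, "gene_id"].iloc[0]
            raise ValueError(f"negative TSS for gene {bad!r}")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError(
                f"invalid strand for gene {df.loc[bad_strand, 'gene_id'].iloc[0]!r}"
            )
        self._df = (
            df[["gene_id", "chrom", "tss", "strand"]]
            .astype({"gene_id": str, "chrom": str, "tss": int, "strand": str})
            .set_index("gene_id", drop=False)
        )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, int, str]]
    ) -> "GeneAnnotation":
        df = pd.DataFrame(records, columns=["gene_id", "chrom", "tss", "strand"])
        return cls(df)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def gene_ids(self) -> list[str]:
        return list(self._df.index)

    def chroms(self) -> set[str]:
        return set(self._df["chrom"])

    def tss(self, gene_id: str) -> int:
        return int(self._df.at[gene_id, "tss"])

    def chrom(self, gene_id: str) -> str:
        return str(self._df.at[gene_id, "chrom"])

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._df.index

    def to_tsv(self, path: str | Path) -> None:
        self._df.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path: str | Path, format: str = "tsv") -> GeneAnnotation:
    """Read a gene annotation from TSV (gene_id/chrom/tss/strand header) or BED6.

    For BED6 input the TSS is derived from the strand: start for '+' genes,
    end − 1 for '−' genes (the last covered base of a half-open interval).
    """
    path = Path(path)
    if format == "tsv":
        records = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["gene_id", "chrom", "tss", "strand"]:
                raise ValueError(
                    f"{path}: expected header gene_id/chrom/tss/strand, got {header}"
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
                gene_id, chrom, tss, strand = parts
                try:
                    tss_i = int(tss)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer tss {tss!r}") from None
                records.append((gene_id, chrom, tss_i, strand))
    elif format == "bed":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 6:
                    raise ValueError(f"{path}:{lineno}: BED6 required (got {len(parts)} fields)")
                chrom, start, end, name, _score, strand = parts[:6]
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
                if strand not in ("+", "-"):
                    raise ValueError(f"{path}:{lineno}: gene strand must be + or -")
                tss_i = start_i if strand == "+" else end_i - 1
                records.append((name, chrom, tss_i, strand))
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return GeneAnnotation.from_records(records)


def read_peaks(path: str | Path, tf_name: str) -> PeakSet:
    """Read a BED3+ file into a PeakSet, preserving file order.

    Coordinates are kept 0-based half-open, unchanged. A row with
    start >= end is a hard error reported with its line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 fields")
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start_i >= end_i:
                raise ValueError(
                    f"{path}:{lineno}: start {start_i} >= end {end_i}"
                )
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] != ".":
                try:
                    score = float(parts[4])
                except ValueError:
                    score = None
            strand = parts[5] if len(parts) > 5 and parts[5] in _STRANDS else "."
            intervals.append(
                GenomicInterval(chrom, start_i, end_i, name=name, score=score, strand=strand)
            )
    return PeakSet(tf_name=tf_name, intervals=intervals)


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6. Round-trips chrom/start/end/name through read_peaks."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            if isinstance(score, float) and score.is_integer():
                score = int(score)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def warn_if_disjoint(annotation: GeneAnnotation, peaks: PeakSet) -> bool:
    """Log a warning when a non-empty PeakSet shares no chromosome with the
    annotation (usually a naming-convention bug); returns True when disjoint."""
    if len(peaks) and not (peaks.chroms() & annotation.chroms()):
        logger.warning(
            "PeakSet %r shares no chromosome names with the annotation "
            "(e.g. peaks on %s); scores will be all zero",
            peaks.tf_name,
            sorted(peaks.chroms())[:3],
        )
        return True
    return False
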