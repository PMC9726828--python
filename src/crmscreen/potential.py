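"""Distance-decayed regulatory potential, empirical p-values and the binary
TF–target matrix.

The regulatory potential of a TF on a gene sums, over the TF's binding
regions whose midpoints lie within ``window_bp`` of the gene's TSS on the
same chromosome, the kernel

    exp(-(alpha + beta * d / window_bp))

where d is the absolute midpoint-to-TSS distance in bp. The kernel decreases
monotonically with distance and is additive over binding regions; peaks
beyond the window (or on other chromosomes) contribute nothing.

Scores become per-TF empirical p-values: p(g) is the fraction of genes whose
score is >= gene g's score, so the unique top gene gets 1/N and ties share a
p-value. Thresholding p <= cutoff gives the binary target matrix used by the
regulator screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import GeneAnnotation, PeakSet, warn_if_disjoint


@dataclass(frozen=True)
class DecayParams:
    """Kernel parameters: scoring window half-width, offset and slope."""

    window_bp: int = 100_000
    alpha: float = 0.5
    beta: float = 4.0

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


@dataclass
class TargetMatrix:
    """Binary genes x TFs matrix with the p-value cutoff that produced it."""

    values: pd.DataFrame  # int {0,1}, index gene_id, columns tf
    cutoff: float

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tfs(self) -> list[str]:
        return list(self.values.columns)


def regulatory_potential(
    peaks: PeakSet, chrom: str, tss: int, params: DecayParams = DecayParams()
) -> float:
    """Regulatory potential of one TF on one gene (chromosome + TSS)."""
    if not peaks.intervals:
        return 0.0
    mids = np.array(
        [iv.midpoint for iv in peaks.intervals if iv.chrom == chrom], dtype=float
    )
    if mids.size == 0:
        return 0.0
    d = np.abs(mids - tss)
    d = d[d <= params.window_bp]
    if d.size == 0:
        return 0.0
    return float(np.exp(-(params.alpha + params.beta * d / params.window_bp)).sum())


def score_matrix(
    annotation: GeneAnnotation,
    peaksets: list[PeakSet],
    params: DecayParams = DecayParams(),
) -> pd.DataFrame:
    """Genes x TFs regulatory-potential matrix.

    Genes with no nearby peaks keep all-zero rows: they shape the empirical
    null used for the p-values.
    """
    if len(annotation) < 1 or not peaksets:
        raise ValueError("need at least one gene and one PeakSet")
    names = [ps.tf_name for ps in peaksets]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ValueError(f"duplicate tf_name {dup!r}")

    genes = annotation.gene_ids
    tss = annotation.df["tss"].to_numpy(dtype=float)
    chroms = annotation.df["chrom"].to_numpy()
    out = np.zeros((len(genes), len(peaksets)))
    for j, ps in enumerate(peaksets):
        warn_if_disjoint(annotation, ps)
        # group the TF's peak midpoints by chromosome, then score each gene
        # against the sorted midpoints of its own chromosome
        by_chrom: dict[str, list[int]] = {}
        for iv in ps.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv.midpoint)
        sorted_mids = {c: np.sort(np.asarray(m, dtype=float)) for c, m in by_chrom.items()}
        for i in range(len(genes)):
            mids = sorted_mids.get(chroms[i])
            if mids is None:
                continue
            lo = np.searchsorted(mids, tss[i] - params.window_bp, side="left")
            hi = np.searchsorted(mids, tss[i] + params.window_bp, side="right")
            if hi > lo:
                d = np.abs(mids[lo:hi] - tss[i])
                out[i, j] = np.exp(
                    -(params.alpha + params.beta * d / params.window_bp)
                ).sum()
    return pd.DataFrame(out, index=pd.Index(genes, name="gene_id"), columns=names)


def empirical_pvalues(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-TF empirical p-values: the fraction of genes scoring >= each gene.

    Computed column-wise; ties share a p-value and the strict maximum gets
    1/N, so every p lies in {1/N, 2/N, ..., 1}.
    """
    n = len(scores)
    if n < 1:
        raise ValueError("need at least one gene")
    vals = scores.to_numpy()
    # ascending min-rank r = 1 + #(strictly smaller), so #(>=) = N - r + 1
    ranks = np.apply_along_axis(lambda c: rankdata(c, method="min"), 0, vals)
    p = (n - ranks + 1) / n
    return pd.DataFrame(p, index=scores.index, columns=scores.columns)


def build_target_matrix(pvals: pd.DataFrame, cutoff: float = 0.01) -> TargetMatrix:
    """Threshold empirical p-values (inclusive: p <= cutoff marks a target)."""
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    values = (pvals.to_numpy() <= cutoff).astype(np.int8)
    return TargetMatrix(
        values=pd.DataFrame(values, index=pvals.index, columns=pvals.columns),
        cutoff=cutoff,
    )


def write_matrix(
    df: pd.DataFrame, path: str | Path, cutoff: float | None = None
) -> None:
    """Shared TSV writer for score / p-value / target matrices.

    A target matrix carries its cutoff as a '# cutoff=<value>' comment line.
    """
    with open(path, "w") as fh:
        if cutoff is not None:
            fh.write(f"# cutoff={cutoff:g}\n")
        df.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.10g")


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, float | None]:
    """Read a matrix TSV written by write_matrix; returns (matrix, cutoff|None)."""
    cutoff = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# cutoff="):
            cutoff = float(first.split("=", 1)[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col="gene_id")
    df.index = df.index.astype(str)
    return df, cutoff


def read_target_matrix(path: str | Path) -> TargetMatrix:
    df, cutoff = read_matrix(path)
    if cutoff is None:
        raise ValueError(f"{path}: missing '# cutoff=' header for a target matrix")
    return TargetMatrix(values=df.astype(np.int8), cutoff=cutoff)
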