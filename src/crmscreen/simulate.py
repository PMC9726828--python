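"""Synthetic dataset generator with planted regulator enrichment.

Emulates the statistical structure the regulator screen assumes: a single
chromosome of genes, per-TF genome-wide background binding at a uniform rate,
and a configurable subset of "planted" TFs that additionally bind near each
foreground gene's TSS. Distances - not chromosome structure - drive every
downstream computation, so one chromosome suffices.

The generator emits exactly the file formats the pipeline consumes
(annotation TSV, one BED per TF, a plain-text foreground list, and a TSV
truth file naming the planted TFs), so every stage is testable without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import GeneAnnotation, GenomicInterval, PeakSet, write_intervals

# rng stream tags: annotation draws vs per-TF peak draws
_ANNOT_STREAM = 0
_PEAK_STREAM = 1


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 200
    chrom_length_bp: int = 10_000_000
    n_tfs: int = 20
    planted_tfs: tuple[str, ...] = ()
    n_foreground: int = 4
    background_peak_rate: float = 300.0  # expected peaks per TF genome-wide
    peak_width_bp: int = 200
    planted_bind_prob: float = 1.0
    planted_offset_max_bp: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_foreground > self.n_genes:
            raise ValueError("n_foreground must be <= n_genes")
        if self.planted_offset_max_bp >= self.chrom_length_bp:
            raise ValueError("planted_offset_max_bp must be < chrom_length_bp")
        if not (0 <= self.planted_bind_prob <= 1):
            raise ValueError("planted_bind_prob must be in [0, 1]")


def tf_names(config: SimConfig) -> list[str]:
    width = max(2, len(str(config.n_tfs)))
    return [f"TF{i + 1:0{width}d}" for i in range(config.n_tfs)]


def planted_names(config: SimConfig) -> list[str]:
    """Resolve config.planted_tfs entries (names or integer indices) to names."""
    names = tf_names(config)
    out = []
    for p in config.planted_tfs:
        if isinstance(p, int):
            out.append(names[p])
        elif p in names:
            out.append(p)
        else:
            raise ValueError(f"unknown planted TF {p!r}")
    return out


def simulate_annotation(config: SimConfig) -> tuple[GeneAnnotation, list[str]]:
    """Simulate the gene annotation and pick the foreground.

    Genes g001.. get collision-free uniform TSS positions on one chromosome
    and random strands; the foreground is the first n_foreground gene ids
    after a seeded shuffle. Fully reproducible from config.seed.
    """
    if config.n_genes > config.chrom_length_bp:
        raise ValueError("more genes than distinct TSS positions")
    rng = np.random.default_rng([config.seed, _ANNOT_STREAM])
    positions: np.ndarray = np.unique(
        rng.integers(0, config.chrom_length_bp, size=config.n_genes)
    )
    while positions.size < config.n_genes:
        extra = rng.integers(
            0, config.chrom_length_bp, size=config.n_genes - positions.size
        )
        positions = np.unique(np.concatenate([positions, extra]))
    rng.shuffle(positions)  # decouple gene id from genomic order
    strands = rng.choice(["+", "-"], size=config.n_genes)
    width = max(3, len(str(config.n_genes)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
    annotation = GeneAnnotation.from_records(
        [
            (g, "chrS", int(t), s)
            for g, t, s in zip(gene_ids, positions, strands)
        ]
    )
    shuffled = list(gene_ids)
    rng.shuffle(shuffled)
    foreground = shuffled[: config.n_foreground]
    return annotation, foreground


def simulate_peaks(
    annotation: GeneAnnotation, foreground: list[str], config: SimConfig
) -> list[PeakSet]:
    """Simulate one PeakSet per TF.

    Every TF gets Poisson(background_peak_rate) uniformly placed peaks of
    width peak_width_bp. Each planted TF additionally places, with
    probability planted_bind_prob per foreground gene, one peak whose
    midpoint offset from that gene's TSS is uniform on
    [-planted_offset_max_bp, +planted_offset_max_bp]. Planted peaks are
    additional to the background: enrichment over a base rate, not a swap.
    """
    missing = [g for g in foreground if g not in annotation]
    if missing:
        raise ValueError(f"foreground genes not in annotation: {missing}")
    planted = set(planted_names(config))
    half = config.peak_width_bp // 2
    peaksets = []
    for i, name in enumerate(tf_names(config)):
        rng = np.random.default_rng([config.seed, _PEAK_STREAM, i])
        n_bg = rng.poisson(config.background_peak_rate)
        starts = rng.integers(
            0, max(1, config.chrom_length_bp - config.peak_width_bp), size=n_bg
        )
        intervals = [
            GenomicInterval("chrS", int(s), int(s) + config.peak_width_bp)
            for s in starts
        ]
        if name in planted:
            for gene in foreground:
                if rng.random() < config.planted_bind_prob:
                    offset = int(
                        rng.integers(
                            -config.planted_offset_max_bp,
                            config.planted_offset_max_bp + 1,
                        )
                    )
                    mid = annotation.tss(gene) + offset
                    start = max(0, mid - half)
                    intervals.append(
                        GenomicInterval("chrS", start, start + config.peak_width_bp)
                    )
        peaksets.append(PeakSet(tf_name=name, intervals=intervals))
    return peaksets


@dataclass
class SimulatedDataset:
    annotation: GeneAnnotation
    foreground: list[str]
    peaksets: list[PeakSet]
    planted: list[str] = field(default_factory=list)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    annotation, foreground = simulate_annotation(config)
    peaksets = simulate_peaks(annotation, foreground, config)
    return SimulatedDataset(annotation, foreground, peaksets, planted_names(config))


def write_dataset(data: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write annotation.tsv, peaks/<TF>.bed, foreground.txt and truth.tsv."""
    out = Path(out_dir)
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(parents=True, exist_ok=True)
    paths = {"annotation": out / "annotation.tsv", "foreground": out / "foreground.txt",
             "truth": out / "truth.tsv", "peaks_dir": peaks_dir}
    data.annotation.to_tsv(paths["annotation"])
    paths["foreground"].write_text("".join(g + "\n" for g in data.foreground))
    with open(paths["truth"], "w") as fh:
        fh.write("tf\tplanted\n")
        for ps in data.peaksets:
            fh.write(f"{ps.tf_name}\t{int(ps.tf_name in data.planted)}\n")
    for ps in data.peaksets:
        write_intervals(ps.intervals, peaks_dir / f"{ps.tf_name}.bed")
    return paths
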