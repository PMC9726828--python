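"""Candidate cis-regulatory module (CRM) calling.

A CRM candidate is a cluster of top-regulator binding regions near a
foreground gene's TSS: binding regions intersecting the +/- tss_window_bp
window are clipped to it and merged by single linkage (gap <= max_gap_bp,
overlap counts as gap 0). Clusters survive if they contain at least
min_distinct_tfs distinct regulators, their clipped length lies in
[min_len_bp, max_len_bp], and - when evidence tracks such as open chromatin
or conservation are supplied - they overlap every track by at least
evidence_min_overlap_bp.

This is a deterministic, parameterized replacement for identifying such
clusters by eye in a genome browser; every threshold is explicit and
reported in the output headers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .io import GeneAnnotation, GenomicInterval, PeakSet


@dataclass(frozen=True)
class CRMParams:
    tss_window_bp: int = 2000
    max_gap_bp: int = 50
    min_distinct_tfs: int = 2
    min_len_bp: int = 50
    max_len_bp: int = 400
    evidence_min_overlap_bp: int = 1

    def __post_init__(self) -> None:
        if self.tss_window_bp <= 0:
            raise ValueError("tss_window_bp must be positive")
        if self.min_len_bp > self.max_len_bp:
            raise ValueError("min_len_bp must be <= max_len_bp")
        if self.min_distinct_tfs < 1:
            raise ValueError("min_distinct_tfs must be >= 1")


@dataclass
class CRMCandidate:
    interval: GenomicInterval
    gene_id: str
    member_tfs: tuple[str, ...]
    evidence_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_tfs(self) -> int:
        return len(self.member_tfs)


def merge_clusters(
    labeled: Iterable[tuple[GenomicInterval, str]], max_gap_bp: int
) -> list[tuple[GenomicInterval, tuple[str, ...]]]:
    """Single-linkage merge of labeled intervals on one chromosome.

    Two intervals join the same cluster iff the gap between them is
    <= max_gap_bp (overlapping intervals have gap 0). The merged interval
    spans min start to max end; labels are the sorted union. Output order and
    content are independent of input order.
    """
    items = sorted(labeled, key=lambda t: (t[0].start, t[0].end, t[1]))
    if not items:
        return []
    chroms = {iv.chrom for iv, _ in items}
    if len(chroms) > 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()
    out: list[tuple[GenomicInterval, tuple[str, ...]]] = []
    cur_start, cur_end = items[0][0].start, items[0][0].end
    cur_labels = {items[0][1]}
    for iv, lab in items[1:]:
        if iv.start - cur_end <= max_gap_bp:
            cur_end = max(cur_end, iv.end)
            cur_labels.add(lab)
        else:
            out.append((GenomicInterval(chrom, cur_start, cur_end), tuple(sorted(cur_labels))))
            cur_start, cur_end, cur_labels = iv.start, iv.end, {lab}
    out.append((GenomicInterval(chrom, cur_start, cur_end), tuple(sorted(cur_labels))))
    return out


def _overlap_bp(interval: GenomicInterval, track: PeakSet) -> int:
    """Total bp of `interval` covered by the union of the track's intervals."""
    segs = sorted(
        (max(iv.start, interval.start), min(iv.end, interval.end))
        for iv in track.intervals
        if iv.chrom == interval.chrom and iv.start < interval.end and iv.end > interval.start
    )
    total, cov_end = 0, interval.start
    for s, e in segs:
        s = max(s, cov_end)
        if e > s:
            total += e - s
            cov_end = e
    return total


def call_crm(
    foreground: Sequence[str],
    annotation: GeneAnnotation,
    top_peaks: Sequence[PeakSet],
    evidence: Sequence[PeakSet] | None = None,
    params: CRMParams = CRMParams(),
) -> list[CRMCandidate]:
    """Call CRM candidates around each foreground gene's TSS.

    Output is sorted by (gene order in `foreground`, start); candidates are
    named <gene>_CRM<k> with k restarting at 1 per gene. Results do not
    depend on the order of PeakSets or of intervals within them.
    """
    if not top_peaks:
        raise ValueError("need at least one top-regulator PeakSet")
    results: list[CRMCandidate] = []
    for gene in foreground:
        if gene not in annotation:
            raise KeyError(f"foreground gene {gene!r} not in annotation")
        chrom, tss = annotation.chrom(gene), annotation.tss(gene)
        w_start = max(0, tss - params.tss_window_bp)
        w_end = tss + params.tss_window_bp
        labeled = [
            (
                GenomicInterval(chrom, max(iv.start, w_start), min(iv.end, w_end)),
                ps.tf_name,
            )
            for ps in top_peaks
            for iv in ps.intervals
            if iv.chrom == chrom and iv.start < w_end and iv.end > w_start
        ]
        kept: list[CRMCandidate] = []
        for interval, tfs in merge_clusters(labeled, params.max_gap_bp):
            if len(tfs) < params.min_distinct_tfs:
                continue
            if not (params.min_len_bp <= interval.length <= params.max_len_bp):
                continue
            flags = {
                track.tf_name: _overlap_bp(interval, track)
                >= params.evidence_min_overlap_bp
                for track in (evidence or [])
            }
            if not all(flags.values()):
                continue
            kept.append(CRMCandidate(interval, gene, tfs, flags))
        kept.sort(key=lambda c: c.interval.start)
        for k, cand in enumerate(kept, start=1):
            cand.interval = GenomicInterval(
                cand.interval.chrom,
                cand.interval.start,
                cand.interval.end,
                name=f"{gene}_CRM{k}",
                score=float(cand.n_tfs),
            )
        results.extend(kept)
    return results


def write_crm(
    candidates: Sequence[CRMCandidate],
    bed_path: str | Path,
    tsv_path: str | Path | None = None,
    params: CRMParams | None = None,
) -> None:
    """Write CRM calls as BED6 (score = distinct-TF count) plus a TSV sidecar
    listing member TFs and evidence flags; the sidecar header records the
    calling parameters."""
    with open(bed_path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}"
                f"\t{c.interval.name}\t{c.n_tfs}\t.\n"
            )
    if tsv_path is None:
        return
    track_names = sorted({t for c in candidates for t in c.evidence_flags})
    with open(tsv_path, "w") as fh:
        if params is not None:
            for f in (
                "tss_window_bp",
                "max_gap_bp",
                "min_distinct_tfs",
                "min_len_bp",
                "max_len_bp",
                "evidence_min_overlap_bp",
            ):
                fh.write(f"# {f}={getattr(params, f)}\n")
        cols = ["name", "gene_id", "chrom", "start", "end", "n_tfs", "member_tfs"]
        cols += [f"evidence_{t}" for t in track_names]
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            row = [
                c.interval.name,
                c.gene_id,
                c.interval.chrom,
                str(c.interval.start),
                str(c.interval.end),
                str(c.n_tfs),
                ",".join(c.member_tfs),
            ]
            row += [str(int(c.evidence_flags[t])) for t in track_names]
            fh.write("\t".join(row) + "\n")
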