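"""Call candidate cis-regulatory modules: clusters of selected-regulator
binding regions within 2 kb of each foreground TSS.

Reads the dataset and ranking from the earlier steps; writes crm.bed and
crm_details.tsv under results/analysis/.
"""

from analysis_config import DATA, RESULTS
from crmscreen.crm import CRMParams, call_crm, write_crm
from crmscreen.discovery import read_ranking, select_top_regulators
from crmscreen.io import read_gene_annotation
from crmscreen.pipeline import read_foreground, read_peaks_dir


def main() -> None:
    annotation = read_gene_annotation(DATA / "annotation.tsv")
    foreground = read_foreground(DATA / "foreground.txt")
    ranking = read_ranking(RESULTS / "ranking.tsv")
    selected = set(select_top_regulators(ranking, q_cutoff=0.05))
    top_peaks = [ps for ps in read_peaks_dir(DATA / "peaks") if ps.tf_name in selected]

    params = CRMParams()
    candidates = call_crm(foreground, annotation, top_peaks, params=params) if top_peaks else []
    write_crm(candidates, RESULTS / "crm.bed", RESULTS / "crm_details.tsv", params)

    print(f"scanned +/-{params.tss_window_bp} bp around {len(foreground)} foreground TSSs "
          f"using {len(top_peaks)} selected regulators")
    for c in candidates:
        print(f"  {c.interval.name}: {c.interval.chrom}:{c.interval.start}-{c.interval.end} "
              f"({c.interval.length} bp, TFs: {', '.join(c.member_tfs)})")
    print(f"called {len(candidates)} CRM candidates -> {RESULTS / 'crm.bed'}")


if __name__ == "__main__":
    main()
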