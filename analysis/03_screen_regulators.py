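"""Run the replicated foreground-vs-background discrimination screen, combine
replicates by rank product, and select top regulators at q <= 0.05.

Reads targets.tsv from 02_build_target_matrix.py; writes ranking.tsv and
prints the selected regulators against the simulation truth.
"""

import argparse

import pandas as pd

from analysis_config import DATA, RESULTS, screen_config
from crmscreen.discovery import select_top_regulators, write_ranking
from crmscreen.io import read_gene_annotation
from crmscreen.pipeline import read_foreground, screen_from_target_file


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    annotation = read_gene_annotation(DATA / "annotation.tsv")
    foreground = read_foreground(DATA / "foreground.txt")
    cfg = screen_config(args.seed)
    ranking = screen_from_target_file(RESULTS / "targets.tsv", annotation, foreground, cfg)
    write_ranking(ranking, RESULTS / "ranking.tsv")

    selected = select_top_regulators(ranking, cfg.q_cutoff)
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t")
    planted = sorted(truth.loc[truth["planted"] == 1, "tf"])
    print(ranking[["tf", "rank_product", "p_value", "q_value", "selected"]]
          .head(6).to_string(index=False))
    print(f"\nselected top regulators: {', '.join(selected) or '(none)'}")
    print(f"planted truth:           {', '.join(planted)}")
    print("recovered exactly" if sorted(selected) == planted else "MISMATCH with truth")


if __name__ == "__main__":
    main()
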