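"""Simulate the study dataset: 200 genes on one 10 Mb chromosome, 20 TFs of
which 3 are planted as preferential binders near the 4 foreground TSSs.

Writes annotation.tsv, per-TF BED files, foreground.txt and truth.tsv under
results/analysis/data/.
"""

import argparse

from analysis_config import DATA, sim_config
from crmscreen.simulate import simulate_dataset, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    data = simulate_dataset(sim_config(args.seed))
    paths = write_dataset(data, DATA)
    n_peaks = sum(len(ps) for ps in data.peaksets)
    print(f"simulated {len(data.annotation)} genes, {len(data.peaksets)} TFs, "
          f"{n_peaks} binding regions")
    print(f"foreground genes: {', '.join(data.foreground)}")
    print(f"planted regulators (truth): {', '.join(data.planted)}")
    print(f"wrote dataset under {paths['peaks_dir'].parent}")


if __name__ == "__main__":
    main()
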