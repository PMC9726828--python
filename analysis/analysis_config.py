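"""Shared settings for the numbered analysis drivers.

The demonstration regime plants three regulators over a sparse genome-wide
background (20 expected peaks per TF on a 10 Mb chromosome) with planted
peaks within 500 bp of each foreground TSS, and screens with a target-matrix
cutoff of 0.05 so the 4-gene foreground can be admitted per TF.
"""

from pathlib import Path

from crmscreen.discovery import ScreenConfig
from crmscreen.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
DATA = RESULTS / "data"

PLANTED = ("TF01", "TF02", "TF03")
TARGET_CUTOFF = 0.05

def sim_config(seed: int) -> SimConfig:
    return SimConfig(planted_tfs=PLANTED, background_peak_rate=20,
                     planted_offset_max_bp=500, seed=seed)

def screen_config(seed: int) -> ScreenConfig:
    return ScreenConfig(n_background_sets=200, background_set_size=8,
                        n_replicates=7, n_permutations=2000, seed=seed)
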