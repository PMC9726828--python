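"""Regulator screen: distance-difference contrast of a foreground gene set
against random background sets, replicated, then aggregated by rank product
with a permutation null and Benjamini-Hochberg FDR control.

For each TF, the discrimination score contrasts the mean Hamming distance
between foreground and background target-matrix entries with the mean
distance among foreground genes themselves; the sign is set by the direction
of enrichment (targeted fraction in foreground minus background). A TF that
targets the whole foreground and nothing in the background scores +1; a TF
whose column carries no information scores 0.

Each replicate averages the score over many freshly sampled background sets
and ranks TFs (1 = most discriminative, midranks on ties). Rank products
across replicates are assessed against a Monte-Carlo null of independent
uniform rank permutations and BH-adjusted; TFs with q below the cutoff are
the reported top regulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .io import GeneAnnotation
from .potential import TargetMatrix

# spawn key tag separating the permutation-null stream from replicate streams
_PERM_STREAM = 1 << 16


@dataclass(frozen=True)
class ScreenConfig:
    n_background_sets: int = 1000
    background_set_size: int = 8
    n_replicates: int = 7
    q_cutoff: float = 0.05
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_sets < 1:
            raise ValueError("n_background_sets must be >= 1")
        if self.background_set_size < 1:
            raise ValueError("background_set_size must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 < self.q_cutoff <= 1):
            raise ValueError("q_cutoff must be in (0, 1]")


def derive_replicate_seed(master_seed: int, replicate_index: int) -> int:
    """Deterministic per-replicate seed from one master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate_index,))
    return int(ss.generate_state(1)[0])


def sample_background_sets(
    annotation: GeneAnnotation,
    foreground: list[str],
    config: ScreenConfig,
    replicate_seed: int,
) -> list[list[str]]:
    """Sample n_background_sets lists of background_set_size distinct genes,
    uniformly without replacement from the universe minus the foreground."""
    fg = set(foreground)
    universe = np.array([g for g in annotation.gene_ids if g not in fg])
    if len(universe) < config.background_set_size:
        raise ValueError(
            f"universe has {len(universe)} non-foreground genes, "
            f"need {config.background_set_size}"
        )
    rng = np.random.default_rng(replicate_seed)
    return [
        list(rng.choice(universe, size=config.background_set_size, replace=False))
        for _ in range(config.n_background_sets)
    ]


def _ddm_scores_many(
    m: np.ndarray, fg_idx: np.ndarray, bg_idx: np.ndarray
) -> np.ndarray:
    """Vectorised signed discrimination scores.

    m: (n_genes, n_tfs) binary; fg_idx: (n_fg,); bg_idx: (n_sets, set_size).
    Returns (n_sets, n_tfs). Uses the closed form of the pairwise-distance
    contrast: for binary columns the mean |m_f - m_b| over cross pairs is
    p_f(1-p_b) + p_b(1-p_f), and the mean within-foreground distance is
    k(n_f-k)/C(n_f,2) where k targets of n_f foreground genes.
    """
    n_f = len(fg_idx)
    if n_f < 2:
        raise ValueError("need at least 2 foreground genes")
    n_b = bg_idx.shape[1]
    mi = m.astype(np.int64)
    kf = mi[fg_idx].sum(axis=0)  # (T,) foreground targets
    kb = mi[bg_idx].sum(axis=1)  # (S, T) background targets per set
    # all three terms are ratios of integer pair counts; keeping the counts
    # integral until one final division makes the result bit-identical to a
    # literal pair enumeration
    between = (kf * (n_b - kb) + kb * (n_f - kf)) / (n_f * n_b)
    within = (kf * (n_f - kf)) / (n_f * (n_f - 1) / 2)
    raw = between - within
    return raw * np.sign(kf * n_b - kb * n_f)


def ddm_score(
    targets: TargetMatrix, foreground: list[str], background: list[str]
) -> pd.Series:
    """Signed per-TF discrimination score for one background set."""
    idx = targets.values.index
    for g in list(foreground) + list(background):
        if g not in idx:
            raise KeyError(f"gene {g!r} not in target matrix")
    m = targets.values.to_numpy(dtype=float)
    fg_idx = idx.get_indexer(foreground)
    bg_idx = idx.get_indexer(background)[None, :]
    scores = _ddm_scores_many(m, fg_idx, bg_idx)[0]
    return pd.Series(scores, index=targets.values.columns, name="ddm_score")


def replicate_screen(
    targets: TargetMatrix,
    annotation: GeneAnnotation,
    foreground: list[str],
    config: ScreenConfig,
    replicate_index: int,
) -> tuple[pd.Series, pd.Series]:
    """One replicate: mean score over fresh background sets, plus ranks.

    Ranks are descending by score with midranks on ties (rank 1 = most
    discriminative). The replicate's RNG seed derives deterministically from
    (config.seed, replicate_index).
    """
    replicate_seed = derive_replicate_seed(config.seed, replicate_index)
    sets = sample_background_sets(annotation, foreground, config, replicate_seed)
    idx = targets.values.index
    m = targets.values.to_numpy(dtype=float)
    fg_idx = idx.get_indexer(foreground)
    if (fg_idx < 0).any():
        missing = [g for g, i in zip(foreground, fg_idx) if i < 0]
        raise KeyError(f"foreground gene(s) not in target matrix: {missing}")
    bg_idx = np.array([idx.get_indexer(s) for s in sets])
    scores = _ddm_scores_many(m, fg_idx, bg_idx).mean(axis=0)
    ranks = rankdata(-scores, method="average")
    tfs = targets.values.columns
    return (
        pd.Series(scores, index=tfs, name=f"score_rep{replicate_index + 1}"),
        pd.Series(ranks, index=tfs, name=f"rank_rep{replicate_index + 1}"),
    )


def rank_product(ranks: pd.DataFrame) -> pd.Series:
    """Geometric mean of each TF's ranks across replicates (rows = TFs)."""
    if ranks.isna().any().any():
        missing = ranks.index[ranks.isna().any(axis=1)][0]
        raise ValueError(f"missing rank for TF {missing!r}")
    rp = np.exp(np.log(ranks.to_numpy(dtype=float)).mean(axis=1))
    return pd.Series(rp, index=ranks.index, name="rank_product")


def rank_product_pvalues(
    rank_products: pd.Series,
    n_tfs: int,
    n_replicates: int,
    n_permutations: int,
    seed: int,
) -> pd.Series:
    """Monte-Carlo p-values for observed rank products.

    Each permutation draws an independent uniform permutation of ranks
    1..n_tfs per replicate; every TF slot's rank product enters a pooled null
    of n_permutations * n_tfs values. p = (1 + #{null <= RP}) / (1 + pool size).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if n_tfs < 2:
        raise ValueError("need at least 2 TFs")
    rng = np.random.default_rng(seed)
    base = np.tile(
        np.arange(1, n_tfs + 1, dtype=float), (n_permutations, n_replicates, 1)
    )
    perm = rng.permuted(base, axis=2)
    null = np.sort(np.exp(np.log(perm).mean(axis=1)).ravel())
    obs = rank_products.to_numpy(dtype=float)
    # nudge by one ulp so null values equal to the observed RP (same multiset
    # of ranks, same float path) count as <=
    counts = np.searchsorted(null, np.nextafter(obs, np.inf), side="right")
    p = (1.0 + counts) / (1.0 + null.size)
    return pd.Series(p, index=rank_products.index, name="p_value")


def fdr_adjust(p_values: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    return pd.Series(q, index=p_values.index, name="q_value")


def select_top_regulators(ranking: pd.DataFrame, q_cutoff: float) -> list[str]:
    """TFs with q <= q_cutoff, ordered by ascending rank product then name."""
    hit = ranking[ranking["q_value"] <= q_cutoff]
    hit = hit.sort_values(["rank_product", "tf"], kind="mergesort")
    return list(hit["tf"])


def run_screen(
    targets: TargetMatrix,
    annotation: GeneAnnotation,
    foreground: list[str],
    config: ScreenConfig,
) -> pd.DataFrame:
    """Full replicated screen.

    Returns one row per TF with columns tf, score_rep1..R, rank_rep1..R,
    rank_product, p_value, q_value, selected (0/1), sorted by ascending
    rank product then TF name. A pure function of (inputs, config.seed).
    """
    score_cols, rank_cols = [], []
    for r in range(config.n_replicates):
        s, k = replicate_screen(targets, annotation, foreground, config, r)
        score_cols.append(s)
        rank_cols.append(k)
    scores = pd.concat(score_cols, axis=1)
    ranks = pd.concat(rank_cols, axis=1)
    rp = rank_product(ranks)
    perm_seed = derive_replicate_seed(config.seed, _PERM_STREAM)
    p = rank_product_pvalues(
        rp,
        n_tfs=len(targets.tfs),
        n_replicates=config.n_replicates,
        n_permutations=config.n_permutations,
        seed=perm_seed,
    )
    q = fdr_adjust(p)
    out = pd.concat([scores, ranks, rp, p, q], axis=1)
    out.insert(0, "tf", out.index)
    out["selected"] = (out["q_value"] <= config.q_cutoff).astype(int)
    out = out.sort_values(["rank_product", "tf"], kind="mergesort").reset_index(
        drop=True
    )
    return out


def write_ranking(ranking: pd.DataFrame, path) -> None:
    ranking.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ranking(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
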