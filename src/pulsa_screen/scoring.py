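"""Gene scoring for sorted-pool CRISPR screens.

The scoring chain standardizes guide-level enrichment between the two sorted
tails and summarizes it per gene:

1. **Normalize** each sample: ``count / mean(count) * scale + pseudocount``
   (scale defaults to 1e6; the pseudocount is added after scaling).
2. **Log fold change** per guide between the aggregate-positive and
   aggregate-negative pools (log2 by default).
3. **Local Z**: guides are ranked by their mean normalized abundance across
   the two pools, and each guide's LFC is standardized against the mean and
   sample SD of the LFCs in a window of ``window`` guides (default 2000)
   centered on it in rank space. This corrects the larger LFC variance of
   low-abundance guides without parametrizing a mean-variance trend.
4. **Gene phenotype**: mean signed local Z of the gene's two guides with the
   largest |local Z|.
5. **Gene p-value**: the gene's mean local Z over all its guides is compared
   two-sidedly to an empirical null of means of equally many guide Zs drawn
   from the pooled (targeting) Z values — the permutation of gene-to-guide
   assignments — with add-one smoothing. One shared null per gene size; an
   exhaustive mode enumerates every subset when feasible.
6. **Hit calling**: p below threshold and |phenotype| above threshold.

Non-targeting controls (NTCs) take part in the abundance ranking and window
statistics by default but are excluded from the permutation pool; grouped
into consecutive pseudo-genes they provide an independent null calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pulsa_screen.counting import CountMatrix
from pulsa_screen.screen_model import NTC_GENE, GuideLibrary

GUIDE_STAT_COLUMNS = ["guide_id", "gene", "norm_pos", "norm_neg", "mean_abundance", "lfc", "local_z"]


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable constants of the scoring chain (defaults follow the screen protocol)."""

    pseudocount: float = 1.0
    scale: float = 1e6
    window: int = 2000
    n_perm: int = 100_000
    log_base: float = 2.0
    p_threshold: float = 0.005
    phenotype_threshold: float = 1.0
    seed: int = 0
    include_ntc_in_window: bool = True
    include_ntc_in_null: bool = False
    include_focal_in_window: bool = True
    exhaustive_cap: int = 20_000
    ntc_pseudo_size: int = 4

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.p_threshold <= 0 or self.phenotype_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")


def normalize(counts: np.ndarray | Sequence[float], config: ScoringConfig = ScoringConfig()) -> np.ndarray:
    """Depth-normalize one sample: count / mean * scale + pseudocount."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise ValueError("sample has no positive counts; cannot normalize")
    if c.min() < 0:
        raise ValueError("negative counts")
    return c / c.mean() * config.scale + config.pseudocount


def guide_lfc(
    norm_pos: np.ndarray, norm_neg: np.ndarray, config: ScoringConfig = ScoringConfig()
) -> np.ndarray:
    """Per-guide log fold change, aggregate-positive over aggregate-negative."""
    p = np.asarray(norm_pos, dtype=float)
    n = np.asarray(norm_neg, dtype=float)
    if p.shape != n.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {n.shape}")
    return np.log(p / n) / math.log(config.log_base)


def _window_starts(n: int, window: int) -> np.ndarray:
    """Start of the length-``window`` rank window centered on each position.

    Windows are shifted inward at the edges so every guide is judged against
    exactly ``window`` neighbors; for even windows the focal guide sits just
    right of center.
    """
    return np.clip(np.arange(n) - window // 2, 0, n - window)


def local_z(
    lfc: np.ndarray,
    mean_abundance: np.ndarray,
    window: int,
    tie_breaker: np.ndarray | None = None,
    include_focal: bool = True,
) -> np.ndarray:
    """Abundance-rank-windowed Z-score of each guide's LFC.

    Guides are sorted by ``mean_abundance`` (ties broken by ``tie_breaker``,
    typically the guide id, else input order); each guide's LFC is
    standardized against the mean and sample SD (ddof=1) of the LFCs in its
    rank window. A zero-SD window yields z = 0. Set ``include_focal=False``
    to leave the focal guide out of its own window statistics.
    """
    lfc = np.asarray(lfc, dtype=float)
    mean_abundance = np.asarray(mean_abundance, dtype=float)
    n = len(lfc)
    if n != len(mean_abundance):
        raise ValueError("lfc and mean_abundance must be aligned")
    if n < 2:
        raise ValueError("need at least 2 guides for a local Z")
    if window > n:
        window = n
    if tie_breaker is None:
        order = np.lexsort((np.arange(n), mean_abundance))
    else:
        order = np.lexsort((np.asarray(tie_breaker), mean_abundance))
    ranked = lfc[order]

    starts = _window_starts(n, window)
    win = np.lib.stride_tricks.sliding_window_view(ranked, window)  # (n-window+1, window)
    w_sum = win.sum(axis=1)
    w_sq = (win**2).sum(axis=1)

    s1 = w_sum[starts]
    s2 = w_sq[starts]
    if include_focal:
        mean = s1 / window
        var = (s2 - s1**2 / window) / (window - 1)
    else:
        m = window - 1
        s1 = s1 - ranked
        s2 = s2 - ranked**2
        mean = s1 / m
        var = (s2 - s1**2 / m) / (m - 1) if m > 1 else np.zeros(n)
    sd = np.sqrt(np.maximum(var, 0.0))
    z_ranked = np.where(sd > 0, (ranked - mean) / np.where(sd > 0, sd, 1.0), 0.0)

    z = np.empty(n)
    z[order] = z_ranked
    return z


def gene_phenotype(
    z: np.ndarray, genes: Sequence[str], guide_order: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-gene phenotype: mean signed Z of the two guides with largest |Z|.

    Ties in |Z| are broken by ``guide_order`` (default: input order). Genes
    with a single guide return that guide's Z and are identifiable via
    ``n_guides == 1``. Returns columns ``gene, n_guides, phenotype, mean_z``.
    """
    z = np.asarray(z, dtype=float)
    genes = np.asarray(genes)
    if len(z) != len(genes):
        raise ValueError("z and genes must be aligned")
    if len(z) == 0:
        raise ValueError("empty gene group")
    order = np.arange(len(z)) if guide_order is None else np.asarray(guide_order)
    df = pd.DataFrame({"gene": genes, "z": z, "absz": np.abs(z), "ord": order})
    df = df.sort_values(["gene", "absz", "ord"], ascending=[True, False, True], kind="stable")
    top2 = df.groupby("gene", sort=True).head(2)
    out = top2.groupby("gene", sort=True).agg(phenotype=("z", "mean"))
    full = df.groupby("gene", sort=True).agg(n_guides=("z", "size"), mean_z=("z", "mean"))
    res = full.join(out).reset_index()
    return res[["gene", "n_guides", "phenotype", "mean_z"]]


def _sample_index_without_replacement(
    rng: np.random.Generator, n: int, size: int, n_draws: int
) -> np.ndarray:
    """(n_draws, size) index matrix, each row sampled without replacement.

    Uses rejection of rows with duplicates; for size << n almost no rows are
    redrawn, which keeps the permutation loop vectorized.
    """
    if size > n:
        raise ValueError("gene size exceeds permutation pool size")
    idx = rng.integers(0, n, size=(n_draws, size))
    if size > 1:
        while True:
            srt = np.sort(idx, axis=1)
            bad = (np.diff(srt, axis=1) == 0).any(axis=1)
            n_bad = int(bad.sum())
            if not n_bad:
                break
            idx[bad] = rng.integers(0, n, size=(n_bad, size))
    return idx


def _exhaustive_null_means(pool: np.ndarray, size: int) -> np.ndarray:
    means = [sum(c) / size for c in combinations(pool, size)]
    return np.asarray(means)


def gene_pvalue(
    z: np.ndarray,
    genes: Sequence[str],
    config: ScoringConfig = ScoringConfig(),
    null_pool: np.ndarray | None = None,
    mode: str = "auto",
) -> pd.DataFrame:
    """Two-sided permutation p-value of each gene's mean guide Z.

    The observed statistic is the mean local Z over the gene's guides. The
    null re-assigns gene labels over the pooled Z values: for each gene size
    s, draw ``n_perm`` subsets of s values without replacement from
    ``null_pool`` (default: the supplied z) and take their means — one
    shared null per size class. p = (1 + #{|null| >= |obs|}) / (n_perm + 1).

    ``mode`` is ``"sampled"``, ``"exhaustive"`` (exact tail fraction over
    all C(n, s) subsets, no smoothing), or ``"auto"`` (exhaustive when the
    subset count is at most ``config.exhaustive_cap``).

    Null draws are seeded per size class from ``config.seed`` so results do
    not depend on gene iteration order.
    """
    z = np.asarray(z, dtype=float)
    genes = np.asarray(genes)
    pool = z if null_pool is None else np.asarray(null_pool, dtype=float)
    if len(pool) == 0:
        raise ValueError("empty permutation pool")
    if mode not in ("auto", "sampled", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")

    obs = pd.DataFrame({"gene": genes, "z": z}).groupby("gene", sort=True).agg(
        n_guides=("z", "size"), mean_z=("z", "mean")
    )
    pvals = np.empty(len(obs))
    for size in np.unique(obs["n_guides"].to_numpy()):
        size = int(size)
        if size > len(pool):
            raise ValueError(f"gene size {size} exceeds pool size {len(pool)}")
        n_subsets = math.comb(len(pool), size)
        exhaustive = mode == "exhaustive" or (mode == "auto" and n_subsets <= config.exhaustive_cap)
        sel = (obs["n_guides"] == size).to_numpy()
        observed = np.abs(obs.loc[sel, "mean_z"].to_numpy())
        if exhaustive:
            null_abs = np.sort(np.abs(_exhaustive_null_means(pool, size)))
            # exact tail fraction over all subsets
            ge = len(null_abs) - np.searchsorted(null_abs, observed - 1e-12, side="left")
            pvals[sel] = ge / n_subsets
        else:
            rng = np.random.default_rng([config.seed, size])
            idx = _sample_index_without_replacement(rng, len(pool), size, config.n_perm)
            null_abs = np.sort(np.abs(pool[idx].mean(axis=1)))
            ge = len(null_abs) - np.searchsorted(null_abs, observed, side="left")
            pvals[sel] = (1 + ge) / (config.n_perm + 1)
    out = obs.reset_index()
    out["p_value"] = pvals
    return out[["gene", "n_guides", "mean_z", "p_value"]]


def aggregate_replicates(replicates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-replicate guide stats by unweighted per-guide means.

    All replicates must cover the identical guide set; a single replicate
    passes through unchanged.
    """
    if not replicates:
        raise ValueError("no replicates to aggregate")
    first = replicates[0]
    if len(replicates) == 1:
        return first.copy()
    ref = set(first["guide_id"])
    for i, rep in enumerate(replicates[1:], start=2):
        other = set(rep["guide_id"])
        if other != ref:
            missing = sorted(ref ^ other)[:10]
            raise ValueError(f"replicate {i} guide set differs; e.g. {missing}")
    numeric = ["norm_pos", "norm_neg", "mean_abundance", "lfc", "local_z"]
    stacked = pd.concat([r.set_index("guide_id") for r in replicates])
    combined = stacked.groupby("guide_id", sort=False)[numeric].mean()
    combined = combined.loc[first["guide_id"]]
    out = first[["guide_id", "gene"]].copy()
    for col in numeric:
        out[col] = combined[col].to_numpy()
    return out


def call_hits(results: pd.DataFrame, config: ScoringConfig = ScoringConfig()) -> pd.DataFrame:
    """Flag hits: p below threshold and |phenotype| above threshold.

    ``direction`` (+1 / −1, sign of the phenotype) separates knockouts that
    increase inclusion formation from those that decrease it.
    """
    out = results.copy()
    out["is_hit"] = (out["p_value"] < config.p_threshold) & (
        out["phenotype"].abs() > config.phenotype_threshold
    )
    out["direction"] = np.sign(out["phenotype"]).astype(int)
    return out


def ntc_pseudogenes(
    ntc_z: np.ndarray,
    pseudo_size: int,
    config: ScoringConfig = ScoringConfig(),
    null_pool: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score non-targeting controls as consecutive pseudo-genes.

    NTC guides are partitioned, in order, into groups of ``pseudo_size``
    (remainder dropped) and scored exactly like genes against the supplied
    null pool. On a well-calibrated screen their p-values are uniform.
    """
    ntc_z = np.asarray(ntc_z, dtype=float)
    if pseudo_size < 1:
        raise ValueError("pseudo_size must be >= 1")
    n_groups = len(ntc_z) // pseudo_size
    if n_groups == 0:
        raise ValueError(f"only {len(ntc_z)} NTC guides; need at least {pseudo_size}")
    used = ntc_z[: n_groups * pseudo_size]
    labels = np.repeat([f"NTC_pseudo_{i + 1:04d}" for i in range(n_groups)], pseudo_size)
    pheno = gene_phenotype(used, labels)
    pv = gene_pvalue(used, labels, config, null_pool=null_pool)
    res = pheno.merge(pv[["gene", "p_value"]], on="gene")
    return call_hits(res, config)


def score_replicate(
    pos_counts: np.ndarray,
    neg_counts: np.ndarray,
    library: GuideLibrary,
    config: ScoringConfig = ScoringConfig(),
) -> pd.DataFrame:
    """Guide-level stats for one replicate: normalize → LFC → local Z."""
    norm_pos = normalize(pos_counts, config)
    norm_neg = normalize(neg_counts, config)
    lfc = guide_lfc(norm_pos, norm_neg, config)
    mean_ab = (norm_pos + norm_neg) / 2.0
    stats = pd.DataFrame(
        {
            "guide_id": library.guide_ids,
            "gene": library.genes,
            "norm_pos": norm_pos,
            "norm_neg": norm_neg,
            "mean_abundance": mean_ab,
            "lfc": lfc,
        }
    )
    if config.include_ntc_in_window:
        stats["local_z"] = local_z(
            lfc, mean_ab, config.window,
            tie_breaker=library.guide_ids,
            include_focal=config.include_focal_in_window,
        )
    else:
        mask = ~library.is_ntc
        z = np.full(len(stats), np.nan)
        z[mask] = local_z(
            lfc[mask], mean_ab[mask], config.window,
            tie_breaker=library.guide_ids[mask],
            include_focal=config.include_focal_in_window,
        )
        stats["local_z"] = z
    return stats


def score_screen(
    counts: CountMatrix,
    library: GuideLibrary,
    config: ScoringConfig = ScoringConfig(),
    sample_pairs: Sequence[tuple[str, str]] | None = None,
    pvalue_mode: str = "sampled",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Full scoring chain over replicate (aggregate+, aggregate−) sample pairs.

    ``sample_pairs`` lists the (positive, negative) column pairs, one per
    replicate; by default consecutive column pairs are used. Returns
    ``(gene_results, guide_stats, ntc_results)`` with gene results sorted by
    p-value, then |phenotype| descending, then gene — the stable report
    order. ``ntc_results`` is None when too few NTCs exist.
    """
    if sample_pairs is None:
        cols = counts.sample_ids
        if len(cols) < 2 or len(cols) % 2:
            raise ValueError("need an even number of sample columns to pair")
        sample_pairs = [(cols[i], cols[i + 1]) for i in range(0, len(cols), 2)]
    mat = counts.counts.reindex(library.guide_ids)
    if mat.isna().to_numpy().any():
        missing = mat.index[mat.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"count matrix missing library guides, e.g. {missing}")

    reps = [
        score_replicate(
            mat[pos].to_numpy(), mat[neg].to_numpy(), library, config
        )
        for pos, neg in sample_pairs
    ]
    combined = aggregate_replicates(reps)

    targeting = ~library.is_ntc
    z_all = combined["local_z"].to_numpy()
    pool = z_all[targeting] if not config.include_ntc_in_null else z_all[~np.isnan(z_all)]
    tz = z_all[targeting]
    tgenes = combined.loc[targeting, "gene"].to_numpy()

    gene_results = None
    if targeting.any():
        pheno = gene_phenotype(tz, tgenes)
        pv = gene_pvalue(tz, tgenes, config, null_pool=pool, mode=pvalue_mode)
        gene_results = pheno.merge(pv[["gene", "p_value"]], on="gene")
        gene_results = call_hits(gene_results, config)
        gene_results = gene_results.sort_values(
            ["p_value", "phenotype", "gene"],
            key=lambda s: -s.abs() if s.name == "phenotype" else s,
            kind="stable",
        ).reset_index(drop=True)
    else:
        gene_results = pd.DataFrame(
            columns=["gene", "n_guides", "phenotype", "mean_z", "p_value", "is_hit", "direction"]
        )

    ntc_results = None
    n_ntc = int(library.is_ntc.sum())
    if n_ntc >= config.ntc_pseudo_size and len(pool):
        ntc_z = z_all[library.is_ntc]
        ntc_z = ntc_z[~np.isnan(ntc_z)]
        if len(ntc_z) >= config.ntc_pseudo_size:
            ntc_results = ntc_pseudogenes(
                ntc_z, config.ntc_pseudo_size, config, null_pool=pool
            )
    return gene_results, combined, ntc_results
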