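"""Permutation null models and TE-free control regions.

Two nulls separate TE-induced effects from confounders:

* a positional null — are the expression changes near TEs with epigenetic
  effects larger than near random TEs matched by their location relative
  to genes? — which controls for the mere presence of an insertion; and
* a TE-free null — are the expression changes near mark-enriched TE
  regions larger than near mark-enriched regions without any TE? — which
  controls for strain-level epigenetic variability.

Empirical p-values use the add-one rule p = (1 + #{null >= observed}) /
(N + 1), so p is never 0 and is exactly 1/(N+1) when the observed
statistic beats every draw.  Null sets are drawn without replacement
within a draw and independently across draws.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_link import GeneModel, positional_category
from .io_formats import GenomicInterval

PROPORTION_DOWN = "proportion_down"
MEAN_Z = "mean_z"


@dataclass
class TEFreeRegion:
    interval: GenomicInterval
    strain: str
    positional_category: str
    matched_te_id: str


@dataclass
class PermutationResult:
    observed: float
    n_null: int
    count_ge: int
    p_value: float
    seed: int
    degenerate: bool = False
    null_values: np.ndarray = field(repr=False, default=None)


def permutation_pvalue(
    observed: float, null_values: np.ndarray, seed: int = 0
) -> PermutationResult:
    """Add-one empirical p for observed >= null."""
    null_values = np.asarray(null_values, dtype=np.float64)
    n = null_values.size
    count = int(np.sum(null_values >= observed))
    return PermutationResult(
        observed=float(observed),
        n_null=n,
        count_ge=count,
        p_value=(1 + count) / (n + 1),
        seed=seed,
        null_values=null_values,
    )


# ---------------------------------------------------------------------------
# TE-free control regions
# ---------------------------------------------------------------------------

def sample_te_free_regions(
    te_intervals: dict[str, GenomicInterval],
    genes: list[GeneModel],
    chrom: str,
    chrom_length: int,
    matched: list[tuple[str, str, int]],
    seed: int = 0,
    strain: str = "",
    clearance_bp: int = 1000,
    max_tries_per_region: int = 2000,
) -> tuple[list[TEFreeRegion], dict[str, int]]:
    """Sample control regions with no TE within ``clearance_bp``.

    ``matched`` lists (te_id, positional_category, length) triples: each
    control region copies its TE's length and must fall in the same
    positional category relative to the gene annotation.  Returns the
    regions plus a shortfall report per category (categories with too few
    candidates are reported, never silently truncated).
    """
    rng = np.random.default_rng(seed)
    te_sorted = sorted(
        (iv.start, iv.end) for iv in te_intervals.values() if iv.chrom == chrom
    )
    te_starts = np.array([s for s, _ in te_sorted], dtype=np.int64)
    te_ends = np.array([e for _, e in te_sorted], dtype=np.int64)

    def clear_of_tes(start: int, end: int) -> bool:
        # no TE within clearance of [start, end)
        i = np.searchsorted(te_starts, end + clearance_bp)
        j = np.searchsorted(te_ends, start - clearance_bp, side="right")
        return i == j

    regions: list[TEFreeRegion] = []
    shortfall: dict[str, int] = {}
    for te_id, category, length in matched:
        hit = None
        if chrom_length > length:
            for _ in range(max_tries_per_region):
                start = int(rng.integers(0, chrom_length - length))
                if not clear_of_tes(start, start + length):
                    continue
                iv = GenomicInterval(chrom, start, start + length)
                cat = _region_category(iv, genes)
                if cat == category:
                    hit = iv
                    break
        if hit is None:
            shortfall[category] = shortfall.get(category, 0) + 1
        else:
            regions.append(TEFreeRegion(hit, strain, category, te_id))
    return regions, shortfall


def _region_category(
    iv: GenomicInterval, genes: list[GeneModel], max_gene_distance: int = 1000
) -> str:
    """Category relative to the nearest gene within ``max_gene_distance``.

    Regions with no gene nearby are "intergenic" (the positional null only
    matches regions located near genes).
    """
    best = None
    best_dist = None
    for gene in genes:
        g = gene.interval
        if g.chrom != iv.chrom:
            continue
        if g.start >= iv.end:
            d = g.start - iv.end
        elif g.end <= iv.start:
            d = iv.start - g.end
        else:
            d = 0
        if best_dist is None or d < best_dist:
            best, best_dist = gene, d
    if best is None or best_dist > max_gene_distance:
        return "intergenic"
    cat, _ = positional_category(iv, best)
    return cat


# ---------------------------------------------------------------------------
# Positional permutation test
# ---------------------------------------------------------------------------

def positional_permutation_test(
    te_table: pd.DataFrame,
    focal_ids: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Observed effect of focal TEs vs category-matched random TE sets.

    ``te_table`` has one row per TE with columns ``te_id``, ``category``
    and ``value`` — the TE's per-link statistic already reduced (for
    ``proportion_down`` the fraction of its gene links significantly
    downregulated, for ``mean_z`` the mean link z-score is negated so that
    larger means stronger downregulation).  Null sets preserve the focal
    set's category histogram exactly; draws are without replacement within
    a category.
    """
    if not focal_ids:
        raise ValueError("focal set is empty")
    rng = np.random.default_rng(seed)
    tab = te_table.set_index("te_id")
    focal = tab.loc[list(focal_ids)]
    m = len(focal)
    observed = float(focal["value"].mean())

    null_sums = np.zeros(n_perm)
    for category, cnt in focal["category"].value_counts().items():
        pool = tab.loc[tab["category"] == category, "value"].to_numpy()
        if pool.size < cnt:
            raise ValueError(
                f"cannot match category {category!r}: need {cnt}, pool has {pool.size}"
            )
        if pool.size == cnt:
            null_sums += pool.sum()
            continue
        # vectorized sampling without replacement: argpartition of random keys
        keys = rng.random((n_perm, pool.size))
        idx = np.argpartition(keys, cnt - 1, axis=1)[:, :cnt]
        null_sums += pool[idx].sum(axis=1)
    null_values = null_sums / m
    return permutation_pvalue(observed, null_values, seed)


def te_value_table(
    links: pd.DataFrame,
    statistic: str = PROPORTION_DOWN,
    z_threshold: float = 1.96,
) -> pd.DataFrame:
    """Reduce a link table to one (te_id, category, value) row per TE.

    For ``proportion_down`` the value is the fraction of the TE's links
    with z <= -z_threshold; for ``mean_z`` it is -mean(z) (larger =
    stronger downregulation) so both statistics are one-sided in the same
    direction.
    """
    def reduce(group: pd.DataFrame) -> float:
        z = group["z"].to_numpy(dtype=np.float64)
        z = z[np.isfinite(z)]
        if z.size == 0:
            return 0.0
        if statistic == PROPORTION_DOWN:
            return float(np.mean(z <= -z_threshold))
        if statistic == MEAN_Z:
            return float(-np.mean(z))
        raise ValueError(f"unknown statistic {statistic!r}")

    rows = []
    for te_id, group in links.groupby("te_id"):
        rows.append(
            {
                "te_id": te_id,
                "category": group["positional_category"].iloc[0],
                "value": reduce(group),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TE-free expression permutation
# ---------------------------------------------------------------------------

def tefree_expression_permutation(
    te_de_count: int,
    n_focal: int,
    tefree_de_flags: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """TE-associated DE-gene count against a TE-free resampling null.

    ``tefree_de_flags`` marks, for each gene associated with a
    mark-enriched TE-free region, whether it is differentially expressed;
    each null draw takes ``n_focal`` of those regions without replacement
    and counts DE genes.  p is the add-one probability that a TE-free draw
    matches or exceeds the TE-associated count, so a small p means the
    TE-associated count exceeds what TE-free regions produce.
    """
    flags = np.asarray(tefree_de_flags, dtype=bool)
    rng = np.random.default_rng(seed)
    if flags.size == 0 or flags.size < n_focal:
        res = permutation_pvalue(float(te_de_count), np.zeros(0), seed)
        res.degenerate = True
        res.p_value = float("nan")
        return res
    if flags.size == n_focal:
        null_values = np.full(n_perm, float(flags.sum()))
    else:
        keys = rng.random((n_perm, flags.size))
        idx = np.argpartition(keys, n_focal - 1, axis=1)[:, :n_focal]
        null_values = flags[idx].sum(axis=1).astype(np.float64)
    # p small when the TE-associated count beats the TE-free null
    n = null_values.size
    count_ge_obs = int(np.sum(null_values >= te_de_count))
    res = PermutationResult(
        observed=float(te_de_count),
        n_null=n,
        count_ge=count_ge_obs,
        p_value=(1 + count_ge_obs) / (n + 1),
        seed=seed,
        null_values=null_values,
    )
    return res
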