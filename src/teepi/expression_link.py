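"""Expression normalization and TE-gene linkage statistics.

Counts are normalized between samples with the trimmed mean of M-values
(TMM): per sample, a weighted mean of the log2 expression ratios against a
reference sample is taken after trimming the most extreme 30% of log
ratios (M) and 5% of average log abundances (A) from each tail, weighted
by the inverse asymptotic (delta-method) variance of M; factors are
rescaled to a unit geometric mean.  Normalized abundances are counts per
million over the TMM-effective library size.

Each TE with an epigenetic effect is assigned to the gene(s) overlapping
it or lying within the histone-mark spread of its edges.  The linkage
statistic is a z-score: the difference of mean normalized expression
between carrier and non-carrier samples of the matched body part, divided
by the combined standard error sqrt(SE+^2 + SE-^2).  A negative z means
the gene is less expressed when the TE is present.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import Config
from .effect_calling import DEPLETION, ENRICHMENT, EffectCall
from .io_formats import GeneModel, GenomicInterval, TEInsertion

UP = "up"
DOWN = "down"
NONE = "none"

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
UTR5 = "5'UTR"
UTR3 = "3'UTR"
CDS = "CDS"
INTRON = "intron"


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def compute_tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Per-sample TMM normalization factors (unit geometric mean).

    The reference sample is the one whose 75th percentile of
    counts/library-size is closest to the mean across samples.  Genes with
    a zero count in either member of a comparison are excluded pairwise.
    A sample identical in composition to the reference (all M equal)
    yields factor 1 before rescaling.
    """
    x = np.asarray(counts, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a gene x sample matrix with >= 2 samples")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    lib = x.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("a sample has all-zero counts")
    f75 = np.quantile(x / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(x.shape[1])
    for s in range(x.shape[1]):
        factors[s] = _tmm_pair(x[:, s], x[:, ref], lib[s], lib[ref], trim_m, trim_a)
    return factors / np.exp(np.mean(np.log(factors)))


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    o, r = obs[pos], ref[pos]
    log_r = np.log2((o / n_obs) / (r / n_ref))
    abs_e = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    var = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(log_r)
    rank_a = stats.rankdata(abs_e)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    w = 1.0 / var[keep]
    f = np.sum(w * log_r[keep]) / np.sum(w)
    return float(2.0**f) if np.isfinite(f) else 1.0


def tmm_cpm(counts: pd.DataFrame, factors: np.ndarray | None = None) -> pd.DataFrame:
    """Counts per million over TMM-scaled library sizes."""
    if factors is None:
        factors = compute_tmm_factors(counts)
    lib = counts.sum(axis=0).to_numpy() * np.asarray(factors)
    return counts / lib * 1e6


# ---------------------------------------------------------------------------
# TE-gene linking
# ---------------------------------------------------------------------------

@dataclass
class TEGeneLink:
    te_id: str
    gene_id: str
    body_part: str
    mark: str
    effect: str  # class of the TE's epigenetic effect
    z: float = float("nan")
    significant: bool = False
    direction: str = NONE  # up | down | none
    positional_category: str = ""
    distance_bp: int = 0
    category_approximate: bool = False  # gene lacked sub-feature structure


def positional_category(
    te_iv: GenomicInterval, gene: GeneModel
) -> tuple[str, bool]:
    """TE position relative to a gene model.

    Overlap precedence: CDS > 5'UTR > 3'UTR > intron; non-overlapping TEs
    are upstream/downstream in the gene's reading orientation.  Genes
    without sub-feature structure get distance-only categories, flagged.
    """
    g = gene.interval
    overlaps = te_iv.start < g.end and g.start < te_iv.end

    def hits(feats):
        return any(te_iv.start < e and s < te_iv.end for s, e in feats)

    if overlaps:
        if not gene.has_structure:
            return INTRON, True
        if hits(gene.cds):
            return CDS, False
        if hits(gene.utr5):
            return UTR5, False
        if hits(gene.utr3):
            return UTR3, False
        return INTRON, False
    before = te_iv.end <= g.start  # TE left of the gene in reference coords
    if g.strand == "-":
        return (DOWNSTREAM if before else UPSTREAM), not gene.has_structure
    return (UPSTREAM if before else DOWNSTREAM), not gene.has_structure


def link_te_genes(
    effect_calls: list[EffectCall],
    tes: dict[str, TEInsertion],
    genes: list[GeneModel],
    te_intervals: dict[str, GenomicInterval],
    config: Config | None = None,
) -> list[TEGeneLink]:
    """Candidate TE-gene pairs for TEs with epigenetic effects.

    A gene is linked to a TE iff its body overlaps the TE or lies within
    the called spread S kb of the TE's edges.  ``te_intervals`` gives the
    TE span in the coordinate system of the gene annotation.  Only calls
    with S >= 1 produce links.
    """
    links: list[TEGeneLink] = []
    for ec in effect_calls:
        if ec.effect not in (ENRICHMENT, DEPLETION):
            continue
        if not np.isfinite(ec.spread_kb) or ec.spread_kb < 1:
            continue
        iv = te_intervals.get(ec.te_id)
        if iv is None:
            continue
        reach = int(round(ec.spread_kb * 1000))
        for gene in genes:
            g = gene.interval
            if g.chrom != iv.chrom:
                continue
            if g.start >= iv.end:
                dist = g.start - iv.end
            elif g.end <= iv.start:
                dist = iv.start - g.end
            else:
                dist = 0
            if dist > reach:
                continue
            cat, approx = positional_category(iv, gene)
            links.append(
                TEGeneLink(
                    te_id=ec.te_id,
                    gene_id=gene.gene_id,
                    body_part=ec.body_part,
                    mark=ec.mark,
                    effect=ec.effect,
                    positional_category=cat,
                    distance_bp=dist,
                    category_approximate=approx,
                )
            )
    return links


# ---------------------------------------------------------------------------
# z-score
# ---------------------------------------------------------------------------

def zscore(expr_pos: np.ndarray, expr_neg: np.ndarray) -> float:
    """Standardized carrier-minus-non-carrier expression difference.

    z = (mean+ - mean-) / sqrt(SE+^2 + SE-^2) with SE = sd/sqrt(n) per
    group (sample sd, ddof=1).  Both groups constant and equal gives 0;
    zero combined variance with unequal means gives a signed infinity.
    """
    x = np.asarray(expr_pos, dtype=np.float64)
    y = np.asarray(expr_neg, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 samples per group")
    diff = x.mean() - y.mean()
    se2 = x.var(ddof=1) / x.size + y.var(ddof=1) / y.size
    if se2 == 0:
        if diff == 0:
            return 0.0
        return float(np.inf) if diff > 0 else float(-np.inf)
    return float(diff / np.sqrt(se2))


def score_links(
    links: list[TEGeneLink],
    cpm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    tes: dict[str, TEInsertion],
    config: Config | None = None,
    average_replicates_first: bool = False,
) -> list[TEGeneLink]:
    """Attach z-scores to candidate links (in place; returns the list).

    Groups are all samples of carrier strains vs all samples of
    non-carrier strains within the link's body part.  With
    ``average_replicates_first`` the replicates of each strain are averaged
    before the group statistics (one value per strain).  Links whose gene
    is not expressed (mean normalized abundance below the configured
    cutoff in that body part) get a missing z.
    """
    cfg = config or Config()
    meta = sample_meta.set_index("sample")
    for link in links:
        te = tes[link.te_id]
        in_bp = meta.index[meta["body_part"] == link.body_part]
        sub = cpm.loc[link.gene_id, in_bp]
        if sub.mean() < cfg.expressed_min_cpm:
            link.z = float("nan")
            link.significant = False
            link.direction = NONE
            continue
        pos_samples = [s for s in in_bp if meta.loc[s, "strain"] in te.carriers]
        neg_samples = [s for s in in_bp if meta.loc[s, "strain"] in te.non_carriers]
        if average_replicates_first:
            xs = cpm.loc[link.gene_id, pos_samples].groupby(
                meta.loc[pos_samples, "strain"]
            ).mean().to_numpy()
            ys = cpm.loc[link.gene_id, neg_samples].groupby(
                meta.loc[neg_samples, "strain"]
            ).mean().to_numpy()
        else:
            xs = cpm.loc[link.gene_id, pos_samples].to_numpy()
            ys = cpm.loc[link.gene_id, neg_samples].to_numpy()
        z = zscore(xs, ys)
        link.z = z
        link.significant = bool(np.isfinite(z) and abs(z) >= cfg.z_threshold)
        link.direction = (DOWN if z < 0 else UP) if link.significant else NONE
    return links


def links_frame(links: list[TEGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "te_id": l.te_id,
                "gene_id": l.gene_id,
                "body_part": l.body_part,
                "mark": l.mark,
                "effect": l.effect,
                "z": l.z,
                "significant": l.significant,
                "direction": l.direction,
                "positional_category": l.positional_category,
                "distance_bp": l.distance_bp,
            }
            for l in links
        ]
    )


def quadrant_counts(links: list[TEGeneLink]) -> pd.DataFrame:
    """Effect class x expression direction tabulation of significant links.

    The concordant quadrants are enrichment of the repressive mark with
    downregulation and enrichment of the active mark with upregulation
    (and the reverse for depletion).
    """
    rows = []
    for l in links:
        if not l.significant:
            continue
        rows.append((l.mark, l.effect, l.direction))
    df = pd.DataFrame(rows, columns=["mark", "effect", "direction"])
    if df.empty:
        return pd.DataFrame(columns=["mark", "effect", "direction", "n"])
    return df.value_counts().rename("n").reset_index()
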