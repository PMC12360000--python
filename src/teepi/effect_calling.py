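"""Per-TE epigenetic effect calls from carrier / non-carrier genome pairs.

For every TE x body part x mark and every (carrier, non-carrier) strain
pair, each of the 20 windows per side is compared between the two genomes
with a two-sided Wilcoxon rank-sum test on the replicate-averaged 10 bp
bin values (~100 per genome per window).  From the window tests the pair
gets:

* ``P`` — the percentage change of the median fold-enrichment in the
  pooled innermost (+/- 1 kb) windows, denominated by the non-carrier
  level: ``P = 100 * (median+ - median-) / median-``;
* ``S`` — the spread: per side, the farthest window such that windows
  1..k are all significant in the same direction, minimized over the two
  sides (conservative), 0 when window 1 is not significant on either side;
* a class: enrichment (S >= 1, carrier higher), depletion (S >= 1, carrier
  lower), none (S = 0), or NA on missing/contradictory data.

Pairs are then reduced to one call per TE x body part x mark: the modal
non-NA class, allowing at most one deviating pair (by class or by NA);
otherwise the TE is excluded.  No multiple-testing correction is applied
across windows.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import Config
from .io_formats import SignalTrack, TEInsertion
from .signal_windows import LEFT, RIGHT, WindowProfile, build_window_profile

ENRICHMENT = "enrichment"
DEPLETION = "depletion"
NONE = "none"
NA = "NA"
EXCLUDED = "excluded"

HIGHER = "higher"
LOWER = "lower"

BIVALENT = "bivalent"
MIX = "mix"


@dataclass
class WindowTestResult:
    p_value: float  # NaN when the test could not be run
    direction: str  # higher | lower | none
    n_bins: int  # bins used from the smaller group

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.p_value)


@dataclass
class PairCall:
    """One carrier vs non-carrier comparison for a TE x body part x mark."""

    te_id: str
    carrier: str
    non_carrier: str
    body_part: str
    mark: str
    effect: str  # enrichment | depletion | none | NA
    percentage: float  # NaN when undefined
    spread_kb: float  # NaN when undefined
    p_left: np.ndarray = field(repr=False, default=None)
    p_right: np.ndarray = field(repr=False, default=None)


@dataclass
class EffectCall:
    te_id: str
    body_part: str
    mark: str
    effect: str  # enrichment | depletion | none | excluded
    percentage: float
    spread_kb: float
    n_pairs: int
    n_concordant: int
    combined: str = ""  # filled by combine_marks


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum window test
# ---------------------------------------------------------------------------

def window_test(
    carrier_bins: np.ndarray,
    noncarrier_bins: np.ndarray,
    config: Config | None = None,
) -> WindowTestResult:
    """Two-sided rank-sum test of one window between two genomes.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation with continuity correction
    otherwise.  Returns a missing result when either genome has fewer than
    ``min_bins_per_window`` usable bins.  Direction is the sign of the
    median difference (carrier minus non-carrier) and is reported only
    when p < alpha.
    """
    cfg = config or Config()
    x = np.asarray(carrier_bins, dtype=np.float64)
    y = np.asarray(noncarrier_bins, dtype=np.float64)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    n = int(min(x.size, y.size))
    if x.size < cfg.min_bins_per_window or y.size < cfg.min_bins_per_window:
        return WindowTestResult(float("nan"), NONE, n)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return WindowTestResult(1.0, NONE, n)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 25 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    direction = NONE
    if p < cfg.alpha:
        diff = np.median(x) - np.median(y)
        if diff == 0:
            diff = res.statistic - x.size * y.size / 2.0
        direction = HIGHER if diff > 0 else LOWER
    return WindowTestResult(p, direction, n)


def _batch_ranksum(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise tie-corrected asymptotic rank-sum tests.

    X: (n_tests, nx), Y: (n_tests, ny); rows must be NaN-free.  Returns
    (two-sided p, signed z) with z > 0 when X tends larger.
    """
    nx, ny = X.shape[1], Y.shape[1]
    pooled = np.concatenate([X, Y], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    u = ranks[:, :nx].sum(axis=1) - nx * (nx + 1) / 2.0
    n = nx + ny
    mu = nx * ny / 2.0
    # tie correction per row
    srt = np.sort(pooled, axis=1)
    tie_term = np.zeros(pooled.shape[0])
    tied_rows = np.flatnonzero((np.diff(srt, axis=1) == 0).any(axis=1))
    for r in tied_rows:
        _, counts = np.unique(srt[r], return_counts=True)
        tie_term[r] = np.sum(counts**3 - counts)
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_cc = (u - mu - np.sign(u - mu) * 0.5) / sigma
    p = 2.0 * stats.norm.sf(np.abs(z_cc))
    p = np.clip(p, 0.0, 1.0)
    p[sigma == 0] = 1.0
    return p, np.where(sigma > 0, (u - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)


# ---------------------------------------------------------------------------
# Pair-level statistics
# ---------------------------------------------------------------------------

def percent_change(
    profile_pos: WindowProfile,
    profile_neg: WindowProfile,
    config: Config | None = None,
) -> float:
    """Signed % change of median fold-enrichment in the innermost +/- 1 kb.

    The bins of the two innermost windows (left 1 and right 1) are pooled
    per genome before taking medians; the denominator is the non-carrier
    median.  NaN when the denominator is 0 or either pool is unusable.
    """
    cfg = config or Config()
    pools = []
    for prof in (profile_pos, profile_neg):
        w = np.concatenate([prof.window(LEFT, 1), prof.window(RIGHT, 1)])
        w = w[np.isfinite(w)]
        if w.size < cfg.min_bins_per_window:
            return float("nan")
        pools.append(np.median(w))
    med_pos, med_neg = pools
    if med_neg == 0:
        return float("nan")
    return 100.0 * (med_pos - med_neg) / med_neg


def spread_extent(
    sig_left: np.ndarray,
    dir_left: list[str],
    sig_right: np.ndarray,
    dir_right: list[str],
    direction: str,
) -> int:
    """Spread in windows: min over sides of the consecutive significant run.

    ``sig_*`` are per-window significance booleans for windows 1..n (index
    0 innermost), ``dir_*`` the per-window directions.  The run on each
    side counts windows 1..k all significant with ``direction``; the
    reported spread is the smaller of the two (the window closer to the
    TE, the conservative choice).
    """
    def run(sig, dirs):
        k = 0
        for s, d in zip(sig, dirs):
            if s and d == direction:
                k += 1
            else:
                break
        return k

    return min(run(sig_left, dir_left), run(sig_right, dir_right))


def classify_pair(
    te_id: str,
    profile_pos: WindowProfile,
    profile_neg: WindowProfile,
    config: Config | None = None,
) -> PairCall:
    """Full pair comparison: window tests, percentage, spread and class.

    NA when the innermost test is missing on either side, when the two
    sides disagree in direction at window 1, or when the percentage is
    undefined.
    """
    cfg = config or Config()
    n = cfg.n_windows_per_side
    p_vals = {LEFT: np.full(n, np.nan), RIGHT: np.full(n, np.nan)}
    dirs = {LEFT: [NONE] * n, RIGHT: [NONE] * n}

    for side in (LEFT, RIGHT):
        pos_w = profile_pos.left if side == LEFT else profile_pos.right
        neg_w = profile_neg.left if side == LEFT else profile_neg.right
        clean = _all_finite_rows(pos_w) & _all_finite_rows(neg_w)
        idx = np.flatnonzero(clean)
        if idx.size:
            p, z = _batch_ranksum(pos_w[idx], neg_w[idx])
            for j, i in enumerate(idx):
                p_vals[side][i] = p[j]
                if p[j] < cfg.alpha:
                    med_diff = np.median(pos_w[i]) - np.median(neg_w[i])
                    d = med_diff if med_diff != 0 else z[j]
                    dirs[side][i] = HIGHER if d > 0 else LOWER
        for i in np.flatnonzero(~clean):
            res = window_test(pos_w[i], neg_w[i], cfg)
            p_vals[side][i] = res.p_value
            dirs[side][i] = res.direction

    def make(effect, pct=float("nan"), spread=float("nan")):
        return PairCall(
            te_id, profile_pos.strain, profile_neg.strain,
            profile_pos.body_part, profile_pos.mark,
            effect, pct, spread, p_vals[LEFT], p_vals[RIGHT],
        )

    if not np.isfinite(p_vals[LEFT][0]) or not np.isfinite(p_vals[RIGHT][0]):
        return make(NA)
    sig1 = [p_vals[LEFT][0] < cfg.alpha, p_vals[RIGHT][0] < cfg.alpha]
    d1 = [dirs[LEFT][0], dirs[RIGHT][0]]
    pct = percent_change(profile_pos, profile_neg, cfg)
    if not all(sig1):
        # not significant in the innermost windows on both sides -> no effect
        return make(NONE, pct, 0.0)
    if d1[0] != d1[1]:
        return make(NA)  # contradictory directions at window 1
    direction = d1[0]
    sig_l = p_vals[LEFT] < cfg.alpha
    sig_r = p_vals[RIGHT] < cfg.alpha
    s = spread_extent(sig_l, dirs[LEFT], sig_r, dirs[RIGHT], direction)
    if not np.isfinite(pct):
        return make(NA)
    effect = ENRICHMENT if direction == HIGHER else DEPLETION
    if (effect == ENRICHMENT and pct <= 0) or (effect == DEPLETION and pct >= 0):
        return make(NA)  # rank test and median percentage disagree
    return make(effect, pct, float(s))


def _all_finite_rows(arr: np.ndarray) -> np.ndarray:
    return np.isfinite(arr).all(axis=1)


# ---------------------------------------------------------------------------
# Consensus across strain pairs
# ---------------------------------------------------------------------------

def consensus_call(pair_calls: list[PairCall], config: Config | None = None) -> EffectCall:
    """Reduce pair calls for one TE x body part x mark to a single call.

    The TE-level class is the modal non-NA class when at most one pair
    deviates from it (by a different class or by NA); otherwise the TE is
    excluded.  Reported percentage and spread are means over the
    concordant pairs.
    """
    if not pair_calls:
        raise ValueError("consensus_call needs at least one pair")
    p0 = pair_calls[0]
    classes = [pc.effect for pc in pair_calls]
    valid = [c for c in classes if c != NA]

    def make(effect, pct=float("nan"), spread=float("nan"), n_conc=0):
        return EffectCall(
            p0.te_id, p0.body_part, p0.mark, effect, pct, spread,
            n_pairs=len(pair_calls), n_concordant=n_conc,
        )

    if not valid:
        return make(EXCLUDED)
    counts = Counter(valid)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return make(EXCLUDED)  # modal class tie
    modal, n_modal = top[0]
    if len(pair_calls) - n_modal > 1:
        return make(EXCLUDED)  # more than one deviating comparison
    concordant = [pc for pc in pair_calls if pc.effect == modal]
    if modal == NONE:
        return make(NONE, float("nan"), 0.0, len(concordant))
    pct = float(np.mean([pc.percentage for pc in concordant]))
    spread = float(np.mean([pc.spread_kb for pc in concordant]))
    return make(modal, pct, spread, len(concordant))


def combine_marks(calls_by_mark: dict[str, EffectCall]) -> str:
    """Combined class of the two marks within one TE x body part.

    bivalent: both marks change in the same direction; mix: opposite
    directions; otherwise mark-only or none.
    """
    affected = {
        mk: c.effect for mk, c in calls_by_mark.items()
        if c.effect in (ENRICHMENT, DEPLETION)
    }
    if len(affected) == 2:
        return BIVALENT if len(set(affected.values())) == 1 else MIX
    if len(affected) == 1:
        return f"{next(iter(affected))}-only"
    return NONE


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

def call_all_effects(
    tes: list[TEInsertion],
    averaged_tracks: dict[tuple[str, str, str], SignalTrack],
    breakpoints: dict[tuple[str, str], int],
    chrom: str,
    config: Config | None = None,
) -> tuple[list[PairCall], list[EffectCall]]:
    """Run the pair tests and consensus for every TE x body part x mark.

    ``averaged_tracks`` maps (strain, body_part, mark) to replicate-averaged
    tracks; ``breakpoints`` maps (te_id, non-carrier strain) to the
    projected junction.  Non-carrier strains without a breakpoint are
    skipped; TEs with no usable pair are excluded.
    """
    cfg = config or Config()
    conditions = sorted({(bp, mk) for (_s, bp, mk) in averaged_tracks})
    pair_calls: list[PairCall] = []
    effect_calls: list[EffectCall] = []
    for te in tes:
        if not te.is_polymorphic:
            continue
        carriers = te.carriers
        non_carriers = [s for s in te.non_carriers if (te.te_id, s) in breakpoints]
        for bp, mk in conditions:
            profiles_pos = {}
            for s in carriers:
                iv = te.interval[s]
                profiles_pos[s] = build_window_profile(
                    te.te_id, iv.start, iv.end, averaged_tracks[(s, bp, mk)], chrom, cfg
                )
            profiles_neg = {}
            for s in non_carriers:
                pos = breakpoints[(te.te_id, s)]
                profiles_neg[s] = build_window_profile(
                    te.te_id, pos, pos, averaged_tracks[(s, bp, mk)], chrom, cfg
                )
            pairs = [
                classify_pair(te.te_id, profiles_pos[c], profiles_neg[n], cfg)
                for c in carriers
                for n in non_carriers
            ]
            pair_calls.extend(pairs)
            if pairs:
                effect_calls.append(consensus_call(pairs, cfg))
            else:
                effect_calls.append(
                    EffectCall(te.te_id, bp, mk, EXCLUDED, float("nan"),
                               float("nan"), 0, 0)
                )
    # combined class per TE x body part
    by_te_bp: dict[tuple[str, str], dict[str, EffectCall]] = {}
    for ec in effect_calls:
        by_te_bp.setdefault((ec.te_id, ec.body_part), {})[ec.mark] = ec
    for calls in by_te_bp.values():
        combined = combine_marks(calls)
        for ec in calls.values():
            ec.combined = combined
    return pair_calls, effect_calls


def effect_calls_frame(effect_calls: list[EffectCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "te_id": ec.te_id,
                "body_part": ec.body_part,
                "mark": ec.mark,
                "class": ec.effect,
                "percentage": ec.percentage,
                "spread_kb": ec.spread_kb,
                "n_pairs": ec.n_pairs,
                "n_concordant": ec.n_concordant,
                "combined_class": ec.combined,
            }
            for ec in effect_calls
        ]
    )


def pair_calls_frame(pair_calls: list[PairCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "te_id": pc.te_id,
                "carrier": pc.carrier,
                "non_carrier": pc.non_carrier,
                "body_part": pc.body_part,
                "mark": pc.mark,
                "effect": pc.effect,
                "percentage": pc.percentage,
                "spread_kb": pc.spread_kb,
            }
            for pc in pair_calls
        ]
    )
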