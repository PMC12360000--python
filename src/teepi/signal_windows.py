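"""Per-TE window profiles of fold-enrichment and cohort metaprofiles.

The +/- 20 kb flank of every TE is divided into 20 non-overlapping 1 kb
windows per side, each holding 100 replicate-averaged 10 bp bins.  In a
carrier strain the windows are anchored at the TE's outer edges; in a
non-carrier strain both sides are anchored at the projected breakpoint, so
homologous flanking sequence is compared with the TE body excluded.
Window index 1 is the innermost window.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import Config
from .io_formats import SignalTrack

LEFT = "left"
RIGHT = "right"


@dataclass
class WindowProfile:
    """Binned signal in the windows flanking one TE in one strain/condition.

    ``left``/``right`` are (n_windows, bins_per_window) arrays with NaN for
    missing bins.  Row 0 is window 1 (innermost).  Within a row, bins run in
    genomic order; on the left side row i covers
    [anchor - i*window_bp, anchor - (i-1)*window_bp).
    """

    te_id: str
    strain: str
    body_part: str
    mark: str
    left: np.ndarray
    right: np.ndarray

    def window(self, side: str, i: int) -> np.ndarray:
        """Bin values of window i (1-based, innermost first)."""
        arr = self.left if side == LEFT else self.right
        return arr[i - 1]

    def usable(self, side: str, i: int, max_missing_fraction: float) -> bool:
        w = self.window(side, i)
        return np.isnan(w).mean() <= max_missing_fraction


def _slice_bins(values: np.ndarray, b0: int, b1: int) -> np.ndarray:
    """values[b0:b1] padded with NaN where the range leaves the array."""
    n = values.shape[0]
    out = np.full(b1 - b0, np.nan)
    lo, hi = max(b0, 0), min(b1, n)
    if hi > lo:
        out[lo - b0 : hi - b0] = values[lo:hi]
    return out


def build_window_profile(
    te_id: str,
    anchor_left: int,
    anchor_right: int,
    track: SignalTrack,
    chrom: str,
    config: Config | None = None,
) -> WindowProfile:
    """Window the (replicate-averaged) signal around a TE anchor.

    ``anchor_left``/``anchor_right`` are the TE outer edges in a carrier
    strain, or both equal to the breakpoint position in a non-carrier.
    Bins beyond contig ends are NaN.
    """
    cfg = config or Config()
    if anchor_right < anchor_left:
        raise ValueError("anchor_right must be >= anchor_left")
    values = track.values[chrom]
    b = cfg.bin_bp
    if anchor_left % b or anchor_right % b:
        # anchors are rounded down to bin boundaries; sub-bin offsets are
        # below the signal resolution
        anchor_left -= anchor_left % b
        anchor_right -= anchor_right % b
    n, k = cfg.n_windows_per_side, cfg.bins_per_window
    la, ra = anchor_left // b, anchor_right // b
    left = np.stack([_slice_bins(values, la - (i + 1) * k, la - i * k) for i in range(n)])
    right = np.stack([_slice_bins(values, ra + i * k, ra + (i + 1) * k) for i in range(n)])
    return WindowProfile(te_id, track.strain, track.body_part, track.mark, left, right)


def average_profiles(profiles: list[WindowProfile]) -> WindowProfile:
    """Per-bin mean across replicate profiles (NaN-aware)."""
    with np.errstate(invalid="ignore"):
        left = np.nanmean(np.stack([p.left for p in profiles]), axis=0)
        right = np.nanmean(np.stack([p.right for p in profiles]), axis=0)
    p0 = profiles[0]
    return WindowProfile(p0.te_id, p0.strain, p0.body_part, p0.mark, left, right)


# ---------------------------------------------------------------------------
# Metaprofiles
# ---------------------------------------------------------------------------

@dataclass
class Metaprofile:
    """Median fold-enrichment by distance from the TE edge, across TEs.

    ``offsets`` are bin midpoint distances in bp: negative on the left
    flank, positive on the right, the TE body excluded.  ``median`` is the
    per-offset median over contributing TEs; ``smoothed`` its local-linear
    (tricube-weighted) fit.
    """

    body_part: str
    mark: str
    group: str
    offsets: np.ndarray
    median: np.ndarray
    smoothed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "body_part": self.body_part,
                "mark": self.mark,
                "group": self.group,
                "offset_bp": self.offsets,
                "median": self.median,
                "smoothed": self.smoothed,
            }
        )


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Degree-1 LOWESS with tricube weights, no robustness iterations."""
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return y.copy()
    fit = sm.nonparametric.lowess(
        y[ok], x[ok], frac=span, it=0, xvals=x[ok], is_sorted=True
    )
    out = np.full_like(y, np.nan, dtype=np.float64)
    out[ok] = fit
    return out


def compute_metaprofile(
    profiles: list[WindowProfile],
    group: str = "all",
    config: Config | None = None,
) -> Metaprofile:
    """Per-offset median across TEs, then LOESS smoothing (span = 10%).

    All profiles must share body part and mark; the median at an offset is
    over the TEs contributing a non-missing value there.
    """
    cfg = config or Config()
    if not profiles:
        raise ValueError("empty profile group")
    body_part, mark = profiles[0].body_part, profiles[0].mark
    n_bins_side = cfg.n_windows_per_side * cfg.bins_per_window
    # left flank reversed so offsets increase left->right
    stack = np.stack(
        [
            np.concatenate([p.left[::-1].reshape(-1), p.right.reshape(-1)])
            for p in profiles
        ]
    )
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(stack, axis=0)
    b = cfg.bin_bp
    offsets = np.concatenate(
        [
            -(np.arange(n_bins_side, 0, -1) * b - b // 2),
            np.arange(n_bins_side) * b + b // 2,
        ]
    ).astype(np.int64)
    smoothed = loess_smooth(offsets.astype(np.float64), med, cfg.loess_span)
    return Metaprofile(body_part, mark, group, offsets, med, smoothed)
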