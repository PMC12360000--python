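"""Family-level proportion tests and generic 2x2 contingency tests.

A TE family is tested only when it has enough copies in the genome
(default >= 20) and enough copies with epigenetic effects (default >= 8).
Its observed effect/no-effect split is compared against the cohort-wide
proportion with a one-sample chi-square goodness-of-fit test; when an
expected cell drops below 1 the exact binomial test is used instead.  The
cohort-wide proportion is always recomputed from the analysed cohort, never
hard-coded.  Raw p-values are reported (matching the original analysis);
a Benjamini-Hochberg adjusted column is emitted alongside for
transparency.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import Config

OVER = "over"
UNDER = "under"
NS = "ns"
EXCLUDED = "excluded"

CHI2_YATES = "chi2_yates"
FISHER = "fisher"


@dataclass
class FamilyTestResult:
    family: str
    n_copies: int
    n_with_effect: int
    expected_proportion: float
    statistic: float  # chi-square (NaN for exact binomial fallback)
    p_value: float
    direction: str  # over | under | ns | excluded
    method: str = "chi2"  # chi2 | binomial | none


def family_proportion_test(
    family: str,
    n_copies: int,
    n_with_effect: int,
    global_proportion: float,
    config: Config | None = None,
) -> FamilyTestResult:
    """One-sample goodness-of-fit of a family's effect proportion.

    Eligibility gates are applied first: families below the copy-number or
    effect-copy minima are excluded without testing.  Direction is the
    sign of (observed - expected proportion), reported only when
    p < alpha.
    """
    cfg = config or Config()
    if not 0 < global_proportion < 1:
        raise ValueError("global proportion must lie strictly in (0, 1)")
    if n_with_effect > n_copies:
        raise ValueError("n_with_effect cannot exceed n_copies")
    if n_copies < cfg.min_copies_family or n_with_effect < cfg.min_effect_copies_family:
        return FamilyTestResult(
            family, n_copies, n_with_effect, global_proportion,
            float("nan"), float("nan"), EXCLUDED, method="none",
        )
    expected = np.array(
        [n_copies * global_proportion, n_copies * (1 - global_proportion)]
    )
    observed = np.array([n_with_effect, n_copies - n_with_effect])
    if expected.min() < 1:
        p = stats.binomtest(n_with_effect, n_copies, global_proportion).pvalue
        stat = float("nan")
        method = "binomial"
    else:
        stat, p = stats.chisquare(observed, expected)
        stat = float(stat)
        method = "chi2"
    obs_prop = n_with_effect / n_copies
    if p < cfg.alpha:
        direction = OVER if obs_prop > global_proportion else UNDER
    else:
        direction = NS
    return FamilyTestResult(
        family, n_copies, n_with_effect, global_proportion, stat, float(p),
        direction, method,
    )


def family_table(
    copies_per_family: pd.Series,
    effects_per_family: pd.Series,
    config: Config | None = None,
    global_proportion: float | None = None,
) -> pd.DataFrame:
    """Test every family against the cohort-wide effect proportion.

    ``copies_per_family`` counts analysed copies per family;
    ``effects_per_family`` counts those with the effect under test.  The
    global proportion defaults to total effects / total copies of the
    input itself.
    """
    cfg = config or Config()
    effects = effects_per_family.reindex(copies_per_family.index).fillna(0).astype(int)
    if global_proportion is None:
        global_proportion = float(effects.sum() / copies_per_family.sum())
    rows = []
    for family, n_copies in copies_per_family.items():
        res = family_proportion_test(
            str(family), int(n_copies), int(effects[family]), global_proportion, cfg
        )
        rows.append(
            {
                "family": res.family,
                "n_copies": res.n_copies,
                "n_with_effect": res.n_with_effect,
                "observed_proportion": res.n_with_effect / res.n_copies,
                "expected_proportion": res.expected_proportion,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "direction": res.direction,
                "method": res.method,
            }
        )
    df = pd.DataFrame(rows)
    tested = df["p_value"].notna()
    df["p_adj_bh"] = np.nan
    if tested.any():
        df.loc[tested, "p_adj_bh"] = multipletests(
            df.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return df


def contingency_2x2(
    table: np.ndarray | list, method: str = CHI2_YATES
) -> tuple[float, float, float]:
    """(statistic, p, odds ratio) for a 2x2 count table.

    ``chi2_yates`` is the chi-square test of independence with continuity
    correction (df = 1); ``fisher`` is the two-sided exact test under the
    usual convention (sum of hypergeometric probabilities <= the observed
    table's).  The odds ratio is the sample value ad/bc with inf/0
    sentinels for zero cells.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cells must be non-negative")
    if t.sum(axis=0).min() == 0 and t.sum(axis=1).min() == 0:
        raise ValueError("need at least one non-zero margin")
    a, b, c, d = t.ravel()
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = float(a * d) / float(b * c)
    if method == CHI2_YATES:
        stat, p, _dof, _exp = stats.chi2_contingency(t, correction=True)
        return float(stat), float(p), odds
    if method == FISHER:
        _stat, p = stats.fisher_exact(t, alternative="two-sided")
        return float("nan"), float(p), odds
    raise ValueError(f"unknown method {method!r}")
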