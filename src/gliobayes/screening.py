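"""Nonparametric feature screening before network construction.

Each continuous feature is compared between the high- and low-grade groups
with the two-group Kruskal–Wallis rank test (equivalent to a two-sided
Wilcoxon rank-sum test up to the chi-square approximation). Features whose
p-value exceeds the significance level are dropped before any structure or
parameter learning; the discrete enhancement category is never screened by
this test. Screening is available-case: a feature's test uses exactly the
rows where that feature is observed, so perfusion features are screened on
the perfusion-complete subset and MRSI features on the MRSI-complete subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

from .features import CONTINUOUS_FEATURES, GRADE_COL

__all__ = ["ScreeningResult", "kruskal_wallis", "screen_features"]


@dataclass(frozen=True)
class ScreeningResult:
    feature_name: str
    H: float
    p_value: float
    retained: bool
    n_high: int
    n_low: int
    reason: str = ""


def kruskal_wallis(group_a, group_b) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and chi-square p-value for two groups.

    H = (12 / (N(N+1))) * sum_i n_i (Rbar_i - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi-square with 1 df.
    A fully tied sample (every value identical) is the degenerate case
    H = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("groups must not contain NaN")
    pooled = np.concatenate([a, b])
    n = pooled.size
    ranks = rankdata(pooled)  # midranks for ties
    r_a = ranks[: a.size]
    r_b = ranks[a.size:]
    expect = (n + 1) / 2.0
    h = (12.0 / (n * (n + 1))) * (
        a.size * (r_a.mean() - expect) ** 2
        + b.size * (r_b.mean() - expect) ** 2
    )
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0.0:
        # all values identical across both groups
        return 0.0, 1.0
    h /= denom
    return float(h), float(chi2.sf(h, df=1))


def screen_features(
    table: pd.DataFrame,
    alpha: float = 0.05,
    features=CONTINUOUS_FEATURES,
) -> list[ScreeningResult]:
    """Screen every continuous feature on its available cases.

    ``retained`` is ``p_value <= alpha`` (a p-value exactly at alpha is
    kept). A feature observed in fewer than two cases of either grade group
    is flagged un-screenable and excluded with a reason.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    results: list[ScreeningResult] = []
    for feat in features:
        if feat not in table.columns:
            continue
        sub = table[[GRADE_COL, feat]].dropna(subset=[feat])
        high = sub.loc[sub[GRADE_COL] == "high", feat].to_numpy(float)
        low = sub.loc[sub[GRADE_COL] == "low", feat].to_numpy(float)
        if high.size < 2 or low.size < 2:
            results.append(ScreeningResult(
                feat, float("nan"), float("nan"), False,
                high.size, low.size,
                reason="un-screenable: fewer than 2 observed cases in a "
                       "grade group",
            ))
            continue
        h, p = kruskal_wallis(high, low)
        results.append(ScreeningResult(
            feat, h, p, bool(p <= alpha), high.size, low.size,
        ))
    return results


def retained_features(results: list[ScreeningResult]) -> list[str]:
    return [r.feature_name for r in results if r.retained]


def screening_to_frame(results: list[ScreeningResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature_name, "H": r.H, "p": r.p_value,
                "retained": r.retained, "n_high": r.n_high, "n_low": r.n_low,
                "reason": r.reason,
            }
            for r in results
        ]
    )
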