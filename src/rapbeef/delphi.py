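"""Delphi-round consensus analysis via tie-corrected Kendall's W.

A round's ratings form an m x n matrix (m expert raters, n candidate
policies, 5-point priority Likert cells). Each rater's row is converted to
mid-ranks; concordance is

    W = 12 S / (m^2 (n^3 - n) - m sum_r T_r),

with S the sum of squared deviations of the item rank sums R_i from their
mean m(n+1)/2 and T_r = sum over a rater's tie groups of (t^3 - t). The
associated statistic chi^2 = m (n - 1) W is referred to a chi-squared
distribution with n - 1 degrees of freedom. Rounds stop once W reaches the
stopping threshold (0.5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata

from .errors import InputError

CONSENSUS_STRONG = "strong"
CONSENSUS_MODERATE = "moderate"
CONSENSUS_WEAK = "weak"
CONSENSUS_INDETERMINATE = "indeterminate"


@dataclass
class KendallResult:
    W: float
    S: float
    tie_correction: float  # sum over raters of sum(t^3 - t)
    chi2: float
    df: int
    p: float
    consensus: str
    m: int
    n: int

    def to_dict(self) -> dict:
        return {
            "W": self.W,
            "S": self.S,
            "tie_correction": self.tie_correction,
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "consensus": self.consensus,
            "m": self.m,
            "n": self.n,
        }


def validate_ratings(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a complete m x n matrix of integer 1-5 ratings."""
    if matrix.isna().any().any():
        raise InputError("rating matrix has missing cells")
    values = matrix.to_numpy(dtype=float)
    if matrix.shape[1] < 2:
        raise InputError("need at least 2 items to rank")
    if not np.array_equal(values, np.round(values)) or values.min() < 1 or values.max() > 5:
        raise InputError("ratings must be integers in 1..5")
    return matrix


def rank_with_ties(row) -> np.ndarray:
    """Mid-ranks of one rater's ratings; higher rating = higher rank.

    Tied values share the average of the ranks they span, so ranks always
    sum to n(n+1)/2.
    """
    values = np.asarray(row, dtype=float)
    if values.size == 0:
        raise InputError("cannot rank an empty row")
    return rankdata(values)


def consensus_level(W: float) -> str:
    """Band a concordance value: > 0.7 strong, [0.5, 0.7] moderate,
    < 0.3 weak; the unlabelled (0.3, 0.5) gap is reported indeterminate."""
    if np.isnan(W):
        return CONSENSUS_INDETERMINATE
    if W > 0.7:
        return CONSENSUS_STRONG
    if W >= 0.5:
        return CONSENSUS_MODERATE
    if W < 0.3:
        return CONSENSUS_WEAK
    return CONSENSUS_INDETERMINATE


def kendall_chi_square(W: float, m: int, n: int) -> tuple[float, int, float]:
    """chi^2 = m (n-1) W with df = n - 1 and its upper-tail p-value."""
    if not 0.0 <= W <= 1.0:
        raise InputError(f"W must lie in [0, 1], got {W}")
    if m < 2 or n < 2:
        raise InputError("need m >= 2 raters and n >= 2 items")
    df = n - 1
    chi2 = m * df * W
    return float(chi2), int(df), float(chi2_dist.sf(chi2, df))


def kendall_w(matrix: pd.DataFrame) -> KendallResult:
    """Tie-corrected Kendall's coefficient of concordance for one round."""
    matrix = validate_ratings(pd.DataFrame(matrix))
    m, n = matrix.shape
    if m < 2:
        raise InputError("need at least 2 raters")
    ranks = np.vstack([rank_with_ties(row) for _, row in matrix.iterrows()])
    rank_sums = ranks.sum(axis=0)
    S = float(((rank_sums - m * (n + 1) / 2.0) ** 2).sum())
    T = 0.0
    for _, row in matrix.iterrows():
        _, counts = np.unique(np.asarray(row, dtype=float), return_counts=True)
        T += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * T
    if denom <= 0:
        # every rater rates every item identically: no ranking information
        return KendallResult(
            W=float("nan"), S=S, tie_correction=T, chi2=float("nan"),
            df=n - 1, p=float("nan"), consensus=CONSENSUS_INDETERMINATE, m=m, n=n,
        )
    W = 12.0 * S / denom
    chi2, df, p = kendall_chi_square(W, m, n)
    return KendallResult(
        W=float(W), S=S, tie_correction=T, chi2=chi2, df=df, p=p,
        consensus=consensus_level(W), m=m, n=n,
    )


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * digits), rounding=ROUND_HALF_UP))


@dataclass
class RoundSummary:
    means: pd.Series  # per item, rounded half-up to 1 dp
    ranking: list[str]  # items by descending mean, ties kept in id order
    below_threshold: list[str]  # items with mean < 3 (not essential)
    kendall: KendallResult | None
    stop: bool | None  # None when W is undefined (indeterminate)
    w_stop_threshold: float

    def to_dict(self) -> dict:
        return {
            "means": {k: float(v) for k, v in self.means.items()},
            "ranking": self.ranking,
            "below_threshold": self.below_threshold,
            "kendall": None if self.kendall is None else self.kendall.to_dict(),
            "stop": self.stop,
            "w_stop_threshold": self.w_stop_threshold,
        }


def summarize_round(matrix: pd.DataFrame, w_stop_threshold: float = 0.5) -> RoundSummary:
    """Full analysis of one Delphi round.

    Per-item mean ratings (half-up to 1 decimal), the descending policy
    ranking (stable id order within ties), items rated below the
    'essential' mean of 3, concordance, and the stop decision
    ``W >= w_stop_threshold`` (indeterminate when W is undefined, e.g. a
    single rater or an all-constant matrix).
    """
    matrix = validate_ratings(pd.DataFrame(matrix))
    raw_means = matrix.mean(axis=0)
    means = raw_means.map(_round_half_up)
    order = sorted(matrix.columns, key=str)
    by_mean = sorted(order, key=lambda c: -raw_means[c])
    below = [str(c) for c in matrix.columns if raw_means[c] < 3.0]
    if matrix.shape[0] < 2:
        kendall = None
        stop = None
    else:
        kendall = kendall_w(matrix)
        stop = None if np.isnan(kendall.W) else bool(kendall.W >= w_stop_threshold)
    return RoundSummary(
        means=means,
        ranking=[str(c) for c in by_mean],
        below_threshold=below,
        kendall=kendall,
        stop=stop,
        w_stop_threshold=w_stop_threshold,
    )
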