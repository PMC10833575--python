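"""Observer-agreement statistics: Dice overlap schedules and ICC.

Two complementary views of reproducibility:

* **ROI overlap** — the Dice similarity coefficient (DSC) between the
  masks drawn (or derived) by different observers/sessions, computed on
  the fixed comparison schedule of the evaluation design: 3 observer pairs
  x 4 session combinations = 12 interobserver records, and one session-I
  vs session-II record per observer = 3 intraobserver records, per loaf
  and per ROI kind.
* **Measurement reliability** — the intraclass correlation of the SBR/TBR
  values, using the two-way mixed-effects, absolute-agreement,
  mean-of-k-raters model, i.e. McGraw & Wong's ICC(A,k) with their F-based
  95% confidence interval (Satterthwaite-approximated denominator degrees
  of freedom).  Interobserver reliability stacks loaf x session as
  subjects with the k=3 observers as raters; intraobserver reliability
  stacks loaf x observer as subjects with the k=2 sessions as raters.

ICC point estimates are qualitatively rated poor (< 0.5), moderate
([0.5, 0.75]), good ((0.75, 0.9]) or excellent (> 0.9); the rating of the
confidence bounds gives a rating range.  Two ICCs are called significantly
different iff their confidence intervals do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ROI_KIND_SIGNAL = "signal_or_tumor"
ROI_KIND_BACKGROUND = "background"

RATING_ORDER = ("poor", "moderate", "good", "excellent")


class DegenerateMatrixError(ValueError):
    """Rater matrix has neither subject variance nor residual variance."""


# ---------------------------------------------------------------------------
# Dice similarity coefficient
# ---------------------------------------------------------------------------


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A ∩ B| / (|A| + |B|)`` in [0, 1]."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("undefined DSC: both masks are empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass
class DscRecord:
    """One Dice comparison between two delineations of the same loaf."""

    loaf_id: str
    roi_kind: str
    comparison: str  # "interobserver" | "intraobserver"
    observers: tuple[str, ...]  # pair for inter-, single observer for intra-
    sessions: tuple[str, ...]
    dsc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dsc <= 1.0:
            raise ValueError(f"DSC out of range: {self.dsc}")

    def to_record(self) -> dict:
        return {
            "loaf_id": self.loaf_id,
            "roi_kind": self.roi_kind,
            "comparison": self.comparison,
            "observers": "|".join(self.observers),
            "sessions": "|".join(self.sessions),
            "dsc": self.dsc,
        }


def _check_full_design(masks: Mapping[tuple[str, str], np.ndarray]) -> tuple[list[str], list[str]]:
    observers = sorted({obs for obs, _ in masks})
    sessions = sorted({ses for _, ses in masks})
    if len(observers) != 3 or len(sessions) != 2:
        raise ValueError(
            "evaluation design requires exactly 3 observers and 2 sessions; "
            f"got observers={observers}, sessions={sessions}"
        )
    missing = [(o, s) for o in observers for s in sessions if (o, s) not in masks]
    if missing:
        raise ValueError(f"missing observer/session combinations: {missing}")
    return observers, sessions


def interobserver_dsc_schedule(
    masks: Mapping[tuple[str, str], np.ndarray],
    loaf_id: str = "",
    roi_kind: str = ROI_KIND_SIGNAL,
) -> list[DscRecord]:
    """All interobserver Dice comparisons for one loaf and ROI kind.

    ``masks`` maps ``(observer_id, session_id)`` to the boolean mask of the
    ROI.  With the full 3-observer x 2-session design this yields 3
    observer pairs x 4 session combinations (I-I, I-II, II-I, II-II) = 12
    records.
    """
    observers, sessions = _check_full_design(masks)
    records = []
    for obs_a, obs_b in combinations(observers, 2):
        for ses_a in sessions:
            for ses_b in sessions:
                records.append(
                    DscRecord(
                        loaf_id=loaf_id,
                        roi_kind=roi_kind,
                        comparison="interobserver",
                        observers=(obs_a, obs_b),
                        sessions=(ses_a, ses_b),
                        dsc=dice(masks[(obs_a, ses_a)], masks[(obs_b, ses_b)]),
                    )
                )
    return records


def intraobserver_dsc_schedule(
    masks: Mapping[tuple[str, str], np.ndarray],
    loaf_id: str = "",
    roi_kind: str = ROI_KIND_SIGNAL,
) -> list[DscRecord]:
    """Session-I vs session-II Dice per observer: 3 records per loaf/kind."""
    observers, sessions = _check_full_design(masks)
    ses_a, ses_b = sessions
    return [
        DscRecord(
            loaf_id=loaf_id,
            roi_kind=roi_kind,
            comparison="intraobserver",
            observers=(obs,),
            sessions=(ses_a, ses_b),
            dsc=dice(masks[(obs, ses_a)], masks[(obs, ses_b)]),
        )
        for obs in observers
    ]


# ---------------------------------------------------------------------------
# Intraclass correlation, ICC(A,k)
# ---------------------------------------------------------------------------


@dataclass
class RaterMatrix:
    """Complete n-subjects x k-raters measurement table."""

    values: np.ndarray
    subject_ids: Sequence[str] | None = None
    rater_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("rater matrix must be 2-D (subjects x raters)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"need at least 2 subjects and 2 raters, got {n}x{k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("rater matrix must be complete (no missing cells)")
        if self.subject_ids is None:
            self.subject_ids = [str(i) for i in range(n)]
        if self.rater_ids is None:
            self.rater_ids = [str(j) for j in range(k)]
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise ValueError("id lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_long(
        cls,
        df: pd.DataFrame,
        subject_col: str,
        rater_col: str,
        value_col: str,
    ) -> "RaterMatrix":
        """Pivot a long-format table into a complete rater matrix."""
        wide = df.pivot_table(index=subject_col, columns=rater_col, values=value_col)
        if wide.isna().any().any():
            missing = [
                (str(i), str(c))
                for i in wide.index
                for c in wide.columns
                if pd.isna(wide.loc[i, c])
            ]
            raise ValueError(f"incomplete design; missing cells: {missing}")
        return cls(
            wide.to_numpy(),
            subject_ids=[str(i) for i in wide.index],
            rater_ids=[str(c) for c in wide.columns],
        )


@dataclass
class ICCResult:
    """ICC(A,k) estimate with confidence interval and qualitative ratings."""

    estimate: float
    ci_low: float
    ci_high: float
    alpha: float
    n: int
    k: int
    rating_point: str = field(init=False)
    rating_range: tuple[str, str] = field(init=False)
    negative_estimate: bool = field(init=False)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"confidence interval [{self.ci_low}, {self.ci_high}] "
                f"does not bracket the estimate {self.estimate}"
            )
        self.rating_point = rate_icc(self.estimate)
        self.rating_range = (rate_icc(self.ci_low), rate_icc(self.ci_high))
        self.negative_estimate = self.estimate < 0

    def to_record(self, **extra) -> dict:
        rec = {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "n": self.n,
            "k": self.k,
            "rating_point": self.rating_point,
            "rating_range": f"{self.rating_range[0]} to {self.rating_range[1]}",
        }
        rec.update(extra)
        return rec


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Mean squares (rows/subjects, columns/raters, residual) of a complete
    two-way layout with one observation per cell."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_absolute_agreement(matrix: RaterMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC for absolute agreement of mean-of-k ratings (McGraw-Wong A,k).

    The point estimate is ``(MSR - MSE) / (MSR + (MSC - MSE) / n)`` from
    the two-way ANOVA mean squares.  The confidence interval is the
    F-based interval for the single-rater ICC(A,1) with Satterthwaite
    denominator degrees of freedom, stepped up to k raters by the
    Spearman-Brown relation.  Negative estimates are returned as computed
    (``negative_estimate`` flag), not truncated to zero.
    """
    x = matrix.values
    n, k = x.shape
    msr, msc, mse = _two_way_mean_squares(x)

    denom_k = msr + (msc - mse) / n
    if mse == 0 and denom_k == 0:
        raise DegenerateMatrixError("degenerate matrix: no subject or residual variance")
    if denom_k == 0:
        raise DegenerateMatrixError("degenerate matrix: zero ICC denominator")
    est_k = (msr - mse) / denom_k

    if mse == 0 and msc == 0:
        # perfect absolute agreement: every rater reproduces every subject
        return ICCResult(estimate=est_k, ci_low=est_k, ci_high=est_k, alpha=alpha, n=n, k=k)

    est_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    one_minus = 1.0 - est_1
    if one_minus <= 0:
        # estimate at the ceiling; interval collapses at 1 from below
        return ICCResult(estimate=est_k, ci_low=est_k, ci_high=est_k, alpha=alpha, n=n, k=k)

    a = k * est_1 / (n * one_minus)
    b = 1.0 + k * est_1 * (n - 1) / (n * one_minus)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lb_1 = n * (msr - f_low * mse) / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
    ub_1 = n * (f_up * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
    lb_k = lb_1 * k / (1 + (k - 1) * lb_1)
    ub_k = ub_1 * k / (1 + (k - 1) * ub_1)
    # numerical guard: the F bounds bracket the estimate analytically, but
    # floating point can nick the invariant at the boundaries
    lb_k = min(lb_k, est_k)
    ub_k = max(ub_k, est_k)
    return ICCResult(estimate=est_k, ci_low=lb_k, ci_high=ub_k, alpha=alpha, n=n, k=k)


def rate_icc(value: float) -> str:
    """Qualitative reliability band of an ICC value.

    poor < 0.5 <= moderate <= 0.75 < good <= 0.9 < excellent.  The two
    interior boundaries are assigned to the lower band, consistent with
    the strict inequalities defining poor and excellent.
    """
    if value > 1:
        raise ValueError(f"ICC cannot exceed 1, got {value}")
    if value < 0.5:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def compare_by_ci_overlap(a: ICCResult, b: ICCResult) -> str:
    """Two ICCs differ significantly iff their CIs do not overlap."""
    for r in (a, b):
        if not (np.isfinite(r.ci_low) and np.isfinite(r.ci_high)):
            raise ValueError("confidence interval must be finite")
    disjoint = a.ci_high < b.ci_low or b.ci_high < a.ci_low
    return "significant" if disjoint else "not_significant"


# ---------------------------------------------------------------------------
# Stacking measurement tables into rater matrices
# ---------------------------------------------------------------------------


def interobserver_rater_matrix(df: pd.DataFrame, value_col: str = "ratio") -> RaterMatrix:
    """Interobserver design: subjects = loaf x session, raters = observers.

    Expects one row per (loaf_id, observer, session); the reliability is
    computed over both delineation sessions jointly, giving n = 2 x loaves
    subjects rated by the k = 3 observers.
    """
    df = df.copy()
    df["_subject"] = df["loaf_id"].astype(str) + "::" + df["session"].astype(str)
    return RaterMatrix.from_long(df, "_subject", "observer", value_col)


def intraobserver_rater_matrix(df: pd.DataFrame, value_col: str = "ratio") -> RaterMatrix:
    """Intraobserver design: subjects = loaf x observer, raters = sessions.

    All measurements enter a single k = 2 (sessions) reliability analysis
    with n = loaves x observers subjects.
    """
    df = df.copy()
    df["_subject"] = df["loaf_id"].astype(str) + "::" + df["observer"].astype(str)
    return RaterMatrix.from_long(df, "_subject", "session", value_col)
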