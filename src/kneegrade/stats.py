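"""Evaluation metrics and rater-agreement statistics.

Confusion-matrix orientation
----------------------------
Throughout the package, confusion matrices have **rows = algorithm
prediction** and **columns = expert annotation**.  The reference study this
package reimplements reports "precision" and "recall" with the denominators
swapped relative to the standard definitions: its precision for a grade is
the diagonal count over the *expert's* total (the column sum) and its
recall is the diagonal over the *algorithm's* total (the row sum).  Both
conventions are available via ``convention=`` — ``"paper"`` reproduces the
published tables, ``"standard"`` gives the textbook definitions (which are
simply the same numbers with the two labels exchanged).

Agreement tests
---------------
Two raters' per-grade counts are compared with

* a chi-square goodness-of-fit where the expected count for each grade is
  the average of the two raters' observed counts, summed over both raters'
  columns, with df = 4 (five grades); and
* a paired t statistic over the five per-grade count differences
  D = X - Y:  t = (sum D / N) / sqrt((sum D^2 - (sum D)^2 / N) / ((N-1) N)),
  compared against the one-sided Student-t critical value at df = 4.

Both follow the published procedure exactly, including the df convention
and the one-sided t table value; their statistical appropriateness for
aggregate counts is outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as spstats

from .exceptions import DegenerateInputError, InvalidArgumentError
from .grades import GRADE_LABELS, KLGrade

__all__ = [
    "ConfusionMatrix",
    "GradeCounts",
    "AgreementTestResult",
    "confusion_from_predictions",
    "overall_accuracy",
    "precision_recall",
    "chi_square_agreement",
    "paired_t_agreement",
    "chi2_critical",
    "t_critical",
    "round_half_up",
]

N_GRADES = 5


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up, matching how printed tables are rounded."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """5x5 counts; rows = predicted grade, columns = expert grade."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = GRADE_LABELS
    col_labels: tuple[str, ...] = GRADE_LABELS

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_GRADES, N_GRADES):
            raise InvalidArgumentError("confusion matrix must be 5x5")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("confusion counts must be non-negative")
        if self.counts.sum() <= 0:
            raise InvalidArgumentError("confusion matrix must have a positive total")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def predicted_counts(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def expert_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class GradeCounts:
    """Per-grade counts for one rater or one algorithm."""

    counts: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64).ravel()
        if self.counts.shape != (N_GRADES,):
            raise InvalidArgumentError("grade counts need exactly 5 entries")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise InvalidArgumentError("grade counts must be >= 0 with positive sum")


@dataclass
class AgreementTestResult:
    """Outcome of one agreement test between two sets of grade counts."""

    test: str  # "chi-square" | "paired-t"
    statistic: float
    df: int
    critical_value: float
    alpha: float
    decision: str  # "accept-H0" | "reject-H0"
    per_class_detail: dict = field(default_factory=dict)
    infinite_statistic: bool = False

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "critical_value": self.critical_value,
            "alpha": self.alpha,
            "decision": self.decision,
            "per_class_detail": self.per_class_detail,
            "infinite_statistic": self.infinite_statistic,
        }


def confusion_from_predictions(pred, truth) -> ConfusionMatrix:
    """Tally counts[i][j] = #(prediction = i and truth = j)."""
    p = [int(KLGrade.coerce(v)) for v in np.ravel(pred)]
    t = [int(KLGrade.coerce(v)) for v in np.ravel(truth)]
    if len(p) != len(t):
        raise InvalidArgumentError("prediction and truth lists differ in length")
    if not p:
        raise InvalidArgumentError("need at least one (prediction, truth) pair")
    counts = np.zeros((N_GRADES, N_GRADES), dtype=np.int64)
    np.add.at(counts, (p, t), 1)
    return ConfusionMatrix(counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Trace over grand total."""
    if cm.total <= 0:
        raise DegenerateInputError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def precision_recall(cm: ConfusionMatrix, convention: str = "paper"):
    """Per-grade (precision, recall) under either denominator convention.

    ``"paper"``: precision = diag / expert column total, recall = diag /
    algorithm row total (reproduces the published tables).  ``"standard"``:
    the textbook definitions — the same two vectors swapped.  Classes whose
    denominator is zero get ``nan`` (undefined-metric flag).

    Returns a dict with unrounded ``precision`` and ``recall`` arrays and
    4-decimal half-up ``precision_rounded`` / ``recall_rounded`` for table
    comparison.
    """
    if convention not in ("paper", "standard"):
        raise InvalidArgumentError(f"unknown convention {convention!r}")
    diag = np.diag(cm.counts).astype(float)
    row = cm.predicted_counts().astype(float)  # algorithm totals
    col = cm.expert_counts().astype(float)  # expert totals

    def ratio(den):
        out = np.full(N_GRADES, np.nan)
        nz = den > 0
        out[nz] = diag[nz] / den[nz]
        return out

    if convention == "paper":
        precision, recall = ratio(col), ratio(row)
    else:
        precision, recall = ratio(row), ratio(col)
    return {
        "precision": precision,
        "recall": recall,
        "precision_rounded": np.array(
            [round_half_up(v, 4) if np.isfinite(v) else np.nan for v in precision]
        ),
        "recall_rounded": np.array(
            [round_half_up(v, 4) if np.isfinite(v) else np.nan for v in recall]
        ),
    }


def chi2_critical(df: int, alpha: float) -> float:
    """Upper-alpha chi-square quantile (e.g. df=4, alpha=0.05 -> 9.48773)."""
    if df < 1 or not (0 < alpha < 1):
        raise InvalidArgumentError("need df >= 1 and 0 < alpha < 1")
    return float(spstats.chi2.ppf(1.0 - alpha, df))


def t_critical(df: int, alpha: float, tails: str = "one") -> float:
    """Student-t critical value; one-sided by default (df=4, 0.05 -> 2.1318)."""
    if df < 1 or not (0 < alpha < 1):
        raise InvalidArgumentError("need df >= 1 and 0 < alpha < 1")
    if tails == "one":
        return float(spstats.t.ppf(1.0 - alpha, df))
    if tails == "two":
        return float(spstats.t.ppf(1.0 - alpha / 2.0, df))
    raise InvalidArgumentError(f"tails must be 'one' or 'two', got {tails!r}")


def chi_square_agreement(
    algorithm: GradeCounts, expert: GradeCounts, alpha: float = 0.05
) -> AgreementTestResult:
    """Goodness-of-fit chi-square between an algorithm's and a rater's counts.

    For each grade the expected count is the average of the two observed
    counts; the statistic sums (fo - fe)^2 / fe over both columns.  df = 4.
    H0 (close consensus) is accepted when the statistic is below the
    critical value.
    """
    fo_a = algorithm.counts.astype(float)
    fo_e = expert.counts.astype(float)
    fe = (fo_a + fo_e) / 2.0
    if np.any(fe == 0):
        raise DegenerateInputError("expected count of zero for some grade")
    stat = float((((fo_a - fe) ** 2 + (fo_e - fe) ** 2) / fe).sum())
    df = N_GRADES - 1
    crit = chi2_critical(df, alpha)
    detail = {
        label: {"fo_algorithm": float(a), "fo_expert": float(e), "fe": float(f)}
        for label, a, e, f in zip(GRADE_LABELS, fo_a, fo_e, fe)
    }
    return AgreementTestResult(
        test="chi-square",
        statistic=stat,
        df=df,
        critical_value=crit,
        alpha=alpha,
        decision="accept-H0" if stat < crit else "reject-H0",
        per_class_detail=detail,
    )


def paired_t_agreement(
    x: GradeCounts, y: GradeCounts, alpha: float = 0.05, tails: str = "one"
) -> AgreementTestResult:
    """Paired t statistic over the five per-grade count differences.

    All-equal non-zero differences have zero variance with a non-zero mean:
    the result is flagged infinite rather than raising, while identical
    count vectors legitimately give t = 0.
    """
    D = x.counts.astype(float) - y.counts.astype(float)
    n = float(N_GRADES)
    sum_d = float(D.sum())
    sum_d2 = float((D**2).sum())
    var_term = (sum_d2 - sum_d**2 / n) / ((n - 1) * n)
    infinite = False
    if var_term <= 0:
        if sum_d == 0:
            stat = 0.0
        else:
            stat = float(np.inf) if sum_d > 0 else float(-np.inf)
            infinite = True
    else:
        stat = (sum_d / n) / np.sqrt(var_term)
    df = N_GRADES - 1
    crit = t_critical(df, alpha, tails)
    detail = {
        label: {"x": float(a), "y": float(b), "D": float(dd), "D2": float(dd**2)}
        for label, a, b, dd in zip(GRADE_LABELS, x.counts, y.counts, D)
    }
    detail["totals"] = {"sum_D": sum_d, "sum_D2": sum_d2}
    return AgreementTestResult(
        test="paired-t",
        statistic=float(stat),
        df=df,
        critical_value=crit,
        alpha=alpha,
        decision="accept-H0" if abs(stat) <= crit else "reject-H0",
        per_class_detail=detail,
        infinite_statistic=infinite,
    )
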