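"""Normal/abnormal classification from ASI and its statistical evaluation.

The per-subject classification statistic is the minimum of the two
epoch-level mean ASI values,

    ASI_class = min(mean_1 ASI, mean_2 ASI),

representing the lowest synchrony level observed in the subject.  Low ASI
means asynchronous bursting, so a subject is called *abnormal* when
ASI_class falls at or below a threshold (the published operating point is
3.6).  Classifier quality over all thresholds is summarized by the ROC
curve, whose trapezoid AUC equals the normalized Mann-Whitney U statistic
(ties counted 1/2) -- an identity this module asserts on every call.

Also here: the data-budget study (how accuracy degrades as the available
EEG shrinks from 20 to 5 min), the Welch t-test between groups, and the
postmenstrual-age regression used to check that ASI needs no age
correction near term.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats

from .asi import ASIConfig, asi_for_window
from .errors import IncompleteSubjectError, StatisticsError
from .pipeline import split_epoch, WindowScheme, _window_clean
from .records import CENTRO_OCCIPITAL, EEGRecord

__all__ = [
    "ClassificationConfig",
    "ROCResult",
    "asi_class",
    "classify",
    "roc",
    "youden_threshold",
    "data_budget_study",
    "group_difference_test",
    "pma_regression",
]

logger = logging.getLogger(__name__)

#: Published fixed operating point on the ASI scale.
DEFAULT_THRESHOLD = 3.6


@dataclass(frozen=True)
class ClassificationConfig:
    """Decision rule: abnormal iff ASI_class <= threshold.

    ``combine_rule`` selects how per-window ASI values within an epoch are
    combined (mean by default); the two epoch-level values are then always
    reduced by ``min`` (the ASI_class statistic).  Ties at exactly the
    threshold are classified abnormal -- conservative for screening.
    """

    threshold: float = DEFAULT_THRESHOLD
    combine_rule: str = "mean"   # mean | min | max, over windows within an epoch
    positive_class: str = "abnormal"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.combine_rule not in ("mean", "min", "max"):
            raise ValueError(f"unknown combine rule {self.combine_rule!r}")


@dataclass
class ROCResult:
    """Staircase ROC over all distinct ASI_class cut points."""

    thresholds: np.ndarray       # candidate cut points, ascending
    sensitivity: np.ndarray      # per threshold (abnormal = positive)
    specificity: np.ndarray      # per threshold
    auc: float
    regime: dict = field(default_factory=dict)


def asi_class(mean1: float, mean2: float) -> float:
    """Min of the two epoch-level mean ASI values (lowest synchrony seen)."""
    if mean1 is None or mean2 is None or not (math.isfinite(mean1)
                                              and math.isfinite(mean2)):
        raise IncompleteSubjectError("both epoch means must be present and finite")
    return min(mean1, mean2)


def _combine(values: list[float], rule: str) -> float:
    if rule == "mean":
        return float(np.mean(values))
    return float(min(values) if rule == "min" else max(values))


def classify(subjects: list[tuple[float, str]],
             config: ClassificationConfig = ClassificationConfig()) -> dict:
    """Threshold classification of ``(ASI_class, true label)`` subjects.

    Returns a dict with per-subject predictions and accuracy / sensitivity /
    specificity from the confusion matrix (abnormal = positive class).
    Metrics whose class is absent are reported as ``None``, not 0.
    """
    preds = []
    tp = fp = tn = fn = 0
    for score, label in subjects:
        pred = "abnormal" if score <= config.threshold else "normal"
        preds.append(pred)
        if label == "abnormal":
            tp += pred == "abnormal"
            fn += pred == "normal"
        else:
            tn += pred == "normal"
            fp += pred == "abnormal"
    n = len(subjects)
    return {
        "predictions": preds,
        "accuracy": (tp + tn) / n if n else None,
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "specificity": tn / (tn + fp) if (tn + fp) else None,
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        "threshold": config.threshold,
    }


def _pair_counting_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Brute-force AUC: P(abnormal scores below normal) with 1/2 for ties."""
    ab = scores[labels == 1]
    no = scores[labels == 0]
    wins = 0.0
    for a in ab:
        wins += np.sum(a < no) + 0.5 * np.sum(a == no)
    return wins / (ab.size * no.size)


def roc(subjects: list[tuple[float, str]], regime: dict | None = None) -> ROCResult:
    """ROC curve of the ASI_class statistic (low score => abnormal/positive).

    Thresholds step through every distinct score (tied scores form one
    step).  The trapezoid AUC is asserted, on every call, to equal the
    Mann-Whitney pair-counting probability that an abnormal subject scores
    below a normal one.
    """
    scores = np.array([s for s, _ in subjects], dtype=float)
    labels = np.array([1 if g == "abnormal" else 0 for _, g in subjects])
    if labels.min() == labels.max():
        raise StatisticsError("ROC needs both classes present")
    cuts = np.unique(scores)
    sens = np.empty(cuts.size + 2)
    spec = np.empty(cuts.size + 2)
    # sweep thresholds from -inf to +inf; abnormal iff score <= t
    thr = np.concatenate([[-np.inf], cuts, [np.inf]])
    n_ab = (labels == 1).sum()
    n_no = (labels == 0).sum()
    for i, t in enumerate(thr):
        pred_ab = scores <= t
        sens[i] = (pred_ab & (labels == 1)).sum() / n_ab
        spec[i] = (~pred_ab & (labels == 0)).sum() / n_no
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    bf = _pair_counting_auc(scores, labels)
    assert abs(auc - bf) < 1e-12, f"AUC-U identity violated: {auc} vs {bf}"
    return ROCResult(thresholds=thr, sensitivity=sens, specificity=spec,
                     auc=auc, regime=dict(regime or {}))


def youden_threshold(result: ROCResult) -> tuple[float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Returns ``(threshold, J)``; finite-threshold steps only.  Ties in J are
    broken toward the lower threshold.
    """
    j = result.sensitivity + result.specificity - 1.0
    finite = np.isfinite(result.thresholds)
    idx = np.flatnonzero(finite)
    best = idx[np.argmax(j[idx])]
    return float(result.thresholds[best]), float(j[best])


def data_budget_study(
    cohort: list[tuple[EEGRecord, str, float]],
    budgets_min: tuple[float, ...] = (5.0, 10.0, 20.0),
    window_minutes: tuple[float, ...] = (2.5, 5.0, 10.0),
    combine_rules: tuple[str, ...] = ("mean", "min", "max"),
    config: ASIConfig = ASIConfig(),
    qs_tags: tuple[str, str] = ("QS1", "QS2"),
) -> pd.DataFrame:
    """ROC/AUC for every (EEG budget, ASI window length, combine rule) regime.

    A budget of ``b`` minutes takes the first ``b/2`` minutes of each of the
    two quiet-sleep epochs; each half is cut into windows of the given
    length, per-window ASIs are combined by the rule within each half, and
    the subject score is the min of the two halves (ASI_class).  Regimes
    whose window exceeds the per-epoch share are skipped with a warning.
    Returns a tidy DataFrame with one row per realizable regime, including
    the AUC and the ROCResult in the ``roc`` column.
    """
    rows = []
    scored = _score_windows(cohort, window_minutes, budgets_min, config, qs_tags)
    for budget, wmin, rule in itertools.product(budgets_min, window_minutes,
                                                combine_rules):
        share = budget / 2.0
        if wmin > share + 1e-9:
            logger.warning("regime skipped: %.1f-min window > %.1f-min share",
                           wmin, share)
            continue
        n_windows = int(share // wmin)
        subjects = []
        for (rec, group, _pma) in cohort:
            key = id(rec)
            epoch_vals = []
            for k in (1, 2):
                vals = scored[key][(wmin, k)][:n_windows]
                epoch_vals.append(_combine(vals, rule))
            subjects.append((asi_class(*epoch_vals), group))
        r = roc(subjects, regime={"budget_min": budget, "window_min": wmin,
                                  "combine": rule})
        rows.append({"budget_min": budget, "window_min": wmin, "combine": rule,
                     "auc": r.auc, "n_windows_per_epoch": n_windows, "roc": r})
    return pd.DataFrame(rows)


def _score_windows(cohort, window_minutes, budgets_min, config, qs_tags):
    """Per-record cache: ASI for every window length over each full epoch."""
    max_share = max(budgets_min) / 2.0
    out: dict[int, dict[tuple[float, int], list[float]]] = {}
    for rec, _group, _pma in cohort:
        per = {}
        for wmin in window_minutes:
            for k, tag in enumerate(qs_tags, start=1):
                anns = rec.annotations_tagged(tag)
                if not anns:
                    raise IncompleteSubjectError(f"no annotation tagged {tag!r}")
                start = anns[0].start
                usable = min(anns[0].end - start, max_share * 60.0)
                n_win = int(usable // (wmin * 60.0))
                if n_win == 0:
                    per[(wmin, k)] = []
                    continue
                scheme = WindowScheme(f"{n_win}x{wmin}", wmin, n_win)
                windows = split_epoch((start, start + n_win * wmin * 60.0), scheme)
                per[(wmin, k)] = [
                    asi_for_window(rec, CENTRO_OCCIPITAL, w, config).asi
                    for w in windows if _window_clean(rec, w)
                ]
        out[id(rec)] = per
    return out


def group_difference_test(normal: list[float], abnormal: list[float]) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-sided.

    Returns ``(t, p)``.  Degenerate case: both groups constant with equal
    means gives p = 1.
    """
    if len(normal) < 2 or len(abnormal) < 2:
        raise StatisticsError("need n >= 2 per group for a t-test")
    if np.ptp(normal) == 0 and np.ptp(abnormal) == 0:
        equal = float(np.mean(normal)) == float(np.mean(abnormal))
        return 0.0 if equal else math.inf, 1.0 if equal else 0.0
    t, p = spstats.ttest_ind(normal, abnormal, equal_var=False)
    return float(t), float(p)


def pma_regression(subjects: list[tuple[float, float, str]],
                   alpha: float = 0.05) -> dict[str, dict]:
    """OLS of ASI_class on postmenstrual age, per group and pooled.

    ``subjects`` is a list of ``(asi_class, pma_weeks, group)``.  Returns,
    for "pooled" and each group with >= 3 subjects, the slope (ASI units per
    week) with confidence interval, intercept, Pearson correlation and the
    slope's p-value.
    """
    if len(subjects) < 3:
        raise StatisticsError("regression needs n >= 3")
    frame = pd.DataFrame(subjects, columns=["asi", "pma", "group"])
    if np.ptp(frame["pma"].to_numpy()) == 0:
        raise StatisticsError("PMA range is degenerate")
    out = {}
    for name, sub in [("pooled", frame)] + list(frame.groupby("group")):
        if len(sub) < 3:
            continue
        x = sm.add_constant(sub["pma"].to_numpy())
        fit = sm.OLS(sub["asi"].to_numpy(), x).fit()
        ci = fit.conf_int(alpha)
        r = (np.corrcoef(sub["pma"], sub["asi"])[0, 1]
             if np.ptp(sub["pma"].to_numpy()) > 0
             and np.ptp(sub["asi"].to_numpy()) > 0 else np.nan)
        out[str(name)] = {
            "slope": float(fit.params[1]),
            "slope_ci": (float(ci[1][0]), float(ci[1][1])),
            "intercept": float(fit.params[0]),
            "correlation": float(r),
            "p_value": float(fit.pvalues[1]),
            "n": int(len(sub)),
        }
    return out
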