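"""Frame-to-subject aggregation, metrics, CV protocols and statistics.

Frame-level predictions become one diagnosis per subject through voting: on
binary tasks a subject is positive iff the fraction of positive frames
reaches the threshold (inclusive, default 0.5); on multi-class tasks the
subject label is the mode, with ties broken by the highest mean predicted
probability and then by the lowest class index. Metrics follow the usual
screening conventions: sensitivity is the recall of the disease class,
specificity the recall of the control class; undefined ratios (zero
denominators) are reported as missing, never silently as 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from sklearn.model_selection import StratifiedKFold

from .core import MONTAGE_19


# ---------------------------------------------------------------------------
# voting

def subject_vote(frame_labels, positive_class=None, threshold: float = 0.5,
                 frame_probabilities=None):
    """Aggregate frame labels into one subject label.

    With ``positive_class`` given (binary task), the subject is positive iff
    the fraction of positive frames is >= ``threshold``. Otherwise the mode
    rule applies, with documented tie-breaks.
    """
    labels = list(frame_labels)
    if not labels:
        raise ValueError("no frame labels to vote on")
    if positive_class is not None:
        frac = sum(1 for l in labels if l == positive_class) / len(labels)
        if frac >= threshold:
            return positive_class
        rest = [l for l in labels if l != positive_class]
        return Counter(rest).most_common(1)[0][0] if rest else positive_class

    counts = Counter(labels)
    top = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == top)
    if len(tied) == 1:
        return tied[0]
    if frame_probabilities is not None:
        probs = np.asarray(frame_probabilities)
        means = {c: probs[:, c].mean() for c in tied}
        best = max(means.values())
        tied = sorted(c for c, m in means.items() if m == best)
    return tied[0]


# ---------------------------------------------------------------------------
# metrics

@dataclass
class MetricsReport:
    """Confusion matrix plus the derived screening metrics.

    ``None`` marks a metric whose denominator was zero.
    """

    confusion: np.ndarray
    classes: tuple
    level: str = "frame"
    positive_class: object = None
    negative_class: object = None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    f1: float | None = None

    @property
    def n(self) -> int:
        return int(self.confusion.sum())


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    classes = list(classes)
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[classes.index(t), classes.index(p)] += 1
    return cm


def compute_metrics(confusion, classes, positive_class=None,
                    negative_class=None, level: str = "frame") -> MetricsReport:
    """Derive accuracy / sensitivity / specificity / F1 from a confusion matrix.

    Rows are true classes, columns predicted. ``positive_class`` is the
    disease class (defaults to the first class), ``negative_class`` the
    control (defaults to the last).
    """
    cm = np.asarray(confusion)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (cm < 0).any():
        raise ValueError("confusion counts must be non-negative")
    classes = tuple(classes)
    pos = positive_class if positive_class is not None else classes[0]
    neg = negative_class if negative_class is not None else classes[-1]
    pi, ni = classes.index(pos), classes.index(neg)

    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else None

    def ratio(num, den):
        return float(num / den) if den > 0 else None

    sensitivity = ratio(cm[pi, pi], cm[pi].sum())
    specificity = ratio(cm[ni, ni], cm[ni].sum())
    precision = ratio(cm[pi, pi], cm[:, pi].sum())
    f1 = None
    if precision is not None and sensitivity is not None and (precision + sensitivity) > 0:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(confusion=cm, classes=classes, level=level,
                         positive_class=pos, negative_class=neg,
                         accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, f1=f1)


def per_class_recall(confusion) -> np.ndarray:
    """Recall (sensitivity) of every class; nan where a class has no examples."""
    cm = np.asarray(confusion, dtype=float)
    row = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(row > 0, np.diag(cm) / row, np.nan)


# ---------------------------------------------------------------------------
# protocols

def kfold_subject_split(subject_ids, labels, k: int = 5, seed: int = 0):
    """Stratified subject-disjoint folds: list of (train_ids, test_ids)."""
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    counts = Counter(labels.tolist())
    if min(counts.values()) < k:
        raise ValueError(f"need at least {k} subjects per class for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, te in skf.split(subject_ids, labels):
        folds.append((subject_ids[tr].tolist(), subject_ids[te].tolist()))
    return folds


def loso_evaluate(items, fit_predict, classes, threshold: float = 0.5,
                  positive_class=None):
    """Leave-one-subject-out evaluation of any frame classifier.

    ``items`` is a list of ``(subject_id, label, payload)``; ``fit_predict``
    is called once per held-out subject as ``fit_predict(train_items,
    test_item)`` and must return ``(frame_labels, frame_probabilities)`` for
    the held-out subject's frames. Frame confusions are concatenated across
    subjects; subject-level confusion comes from the votes.
    """
    labels_present = {label for _, label, _ in items}
    if len(labels_present) < 2:
        raise ValueError("LOSO needs at least two classes in the cohort")
    classes = tuple(classes)
    frame_cm = np.zeros((len(classes), len(classes)), dtype=int)
    true_subj, pred_subj = [], []
    for i, held in enumerate(items):
        train_items = items[:i] + items[i + 1 :]
        frame_labels, frame_probs = fit_predict(train_items, held)
        frame_cm += confusion_matrix([held[1]] * len(frame_labels), frame_labels, classes)
        voted = subject_vote(frame_labels, positive_class=positive_class,
                             threshold=threshold, frame_probabilities=frame_probs)
        true_subj.append(held[1])
        pred_subj.append(voted)
    subject_cm = confusion_matrix(true_subj, pred_subj, classes)
    pos = positive_class if positive_class is not None else classes[0]
    frame_report = compute_metrics(frame_cm, classes, positive_class=pos, level="frame")
    subject_report = compute_metrics(subject_cm, classes, positive_class=pos, level="subject")
    return frame_report, subject_report


# ---------------------------------------------------------------------------
# feature similarity

@dataclass
class CorrelationReport:
    """3x3 Pearson correlation matrix of the three modality feature vectors."""

    R: np.ndarray
    missing: np.ndarray  # boolean mask of undefined entries
    names: tuple = ("spectrogram", "scalogram", "hilbert")


def pearson(a, b) -> float:
    """Pearson correlation as covariance over the product of SDs."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ac, bc = a - a.mean(), b - b.mean()
    sa, sb = np.sqrt(np.sum(ac * ac)), np.sqrt(np.sum(bc * bc))
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.dot(ac, bc) / (sa * sb))


def correlation_matrix(f1, f2, f3) -> CorrelationReport:
    """Pairwise Pearson correlations of three feature vectors.

    2-D inputs ``(n_samples, n_features)`` are flattened sample-wise so the
    correlation is computed over all per-sample feature values. Entries with
    a zero-variance vector are flagged missing (nan).
    """
    vecs = [np.asarray(f).ravel() for f in (f1, f2, f3)]
    R = np.eye(3)
    for i in range(3):
        for j in range(i + 1, 3):
            R[i, j] = R[j, i] = pearson(vecs[i], vecs[j])
    return CorrelationReport(R=R, missing=np.isnan(R))


# ---------------------------------------------------------------------------
# channel importance

@dataclass
class ChannelImportance:
    """Min-max-normalised single-channel sensitivity per class."""

    channels: tuple
    classes: tuple
    sensitivity: np.ndarray  # (n_classes, n_channels) mean sensitivity
    importance: np.ndarray   # (n_classes, n_channels) in [0, 1]
    degenerate: np.ndarray   # per-class flag: all sensitivities equal

    def top_channel(self, class_label) -> str:
        ci = self.classes.index(class_label)
        return self.channels[int(np.nanargmax(self.importance[ci]))]


def normalize_importance(sensitivities, channels=MONTAGE_19, classes=("A", "F", "C")):
    """Min-max normalise per-class channel sensitivities to [0, 1].

    A degenerate class (all channels equal) maps to all ones with a flag.
    """
    sens = np.atleast_2d(np.asarray(sensitivities, dtype=float))
    imp = np.empty_like(sens)
    degenerate = np.zeros(sens.shape[0], dtype=bool)
    for i, row in enumerate(sens):
        lo, hi = np.nanmin(row), np.nanmax(row)
        if hi == lo:
            imp[i] = 1.0
            degenerate[i] = True
        else:
            imp[i] = (row - lo) / (hi - lo)
    return ChannelImportance(channels=tuple(channels), classes=tuple(classes),
                             sensitivity=sens, importance=imp, degenerate=degenerate)


# ---------------------------------------------------------------------------
# statistical battery

COHEN_THRESHOLDS = ((0.8, "large"), (0.5, "medium"), (0.2, "small"))


def cohens_d_label(d: float) -> str:
    """Effect-size label at the conventional 0.2/0.5/0.8 cut points."""
    for thr, label in COHEN_THRESHOLDS:
        if abs(d) >= thr:
            return label
    return "negligible"


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    p_adjusted: float
    cohens_d: float
    effect_label: str
    shapiro_p: float | None = None


def compare_methods(a, b, family_size: int = 1, alpha: float = 0.05) -> ComparisonResult:
    """Paired comparison of two per-fold metric vectors.

    A Shapiro-Wilk gate on the paired differences chooses between the
    paired t-test and the Wilcoxon signed-rank test; Cohen's d is the
    paired-difference effect size; the Bonferroni adjustment multiplies p
    by ``family_size`` (capped at 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of equal length >= 3")
    diff = a - b
    if np.allclose(diff, 0):
        return ComparisonResult(test="none", statistic=0.0, p_value=1.0,
                                p_adjusted=1.0, cohens_d=0.0,
                                effect_label="negligible", shapiro_p=None)
    if np.ptp(diff) == 0:
        # constant non-zero shift: normality is undefined, rank test applies
        res = sst.wilcoxon(a, b)
        d = float(np.sign(diff.mean()) * np.inf)
        return ComparisonResult(test="wilcoxon", statistic=float(res.statistic),
                                p_value=float(res.pvalue),
                                p_adjusted=min(1.0, float(res.pvalue) * family_size),
                                cohens_d=d, effect_label=cohens_d_label(d),
                                shapiro_p=None)
    sw = sst.shapiro(diff)
    if sw.pvalue >= alpha:
        res = sst.ttest_rel(a, b)
        test = "paired-t"
    else:
        res = sst.wilcoxon(a, b)
        test = "wilcoxon"
    sd = diff.std(ddof=1)
    # constant non-zero difference: effect size is unbounded by convention
    d = float(diff.mean() / sd) if sd > 0 else float(np.sign(diff.mean()) * np.inf)
    p_adj = min(1.0, float(res.pvalue) * family_size)
    return ComparisonResult(test=test, statistic=float(res.statistic),
                            p_value=float(res.pvalue), p_adjusted=p_adj,
                            cohens_d=d, effect_label=cohens_d_label(d),
                            shapiro_p=float(sw.pvalue))


def repeated_measures_anova(groups: dict):
    """RM-ANOVA plus Tukey HSD for >= 3 paired metric vectors.

    ``groups`` maps method name -> per-fold metric vector (equal lengths).
    Returns ``(anova_table, tukey_summary_frame)``.
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    names = list(groups)
    if len(names) < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 groups")
    lengths = {len(v) for v in groups.values()}
    if len(lengths) != 1:
        raise ValueError("all groups must have the same number of folds")
    n = lengths.pop()
    long = pd.DataFrame({
        "value": np.concatenate([np.asarray(groups[m], float) for m in names]),
        "method": np.repeat(names, n),
        "fold": np.tile(np.arange(n), len(names)),
    })
    anova = AnovaRM(long, depvar="value", subject="fold", within=["method"]).fit()
    tukey = pairwise_tukeyhsd(long["value"], long["method"])
    tukey_frame = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return anova.anova_table, tukey_frame


def bootstrap_ci(samples, n_boot: int = 1000, level: float = 0.95,
                 seed: int = 0, statistic=np.mean):
    """Seeded percentile bootstrap CI of a statistic (default: the mean)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, samples.size, size=(n_boot, samples.size))
    stats = statistic(samples[idx], axis=1)
    lo = float(np.percentile(stats, 100 * (1 - level) / 2))
    hi = float(np.percentile(stats, 100 * (1 + level) / 2))
    return lo, hi
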