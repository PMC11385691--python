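"""ROC/AUC analysis, Youden thresholds, confusion metrics and consensus rules.

Each scalar classifier of SIM inhibition has a fixed physiological
orientation: inhibition slows tracer transit, so LOW rho and LOW cPDR90
indicate inhibition while HIGH T50 and HIGH T_peak do.  Scores are oriented
(sign-flipped where needed) so that larger oriented score = more inhibited
before any ROC or threshold computation; orientations are declared a
priori, never learned from the data, to avoid inflating AUC on small
samples.

Thresholds are chosen in-sample by maximizing Youden's J = sensitivity +
specificity - 1 over all cutpoints that can matter (midpoints between
consecutive distinct scores, plus the two degenerate all-positive /
all-negative rules).  This mirrors the common diagnostic-study protocol and
is optimistic; no cross-validation is attempted.

Consensus diagnoses combine the per-classifier binary calls by intersection
(AND), union (OR) or majority (positive if at least two member classifiers
are positive).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

__all__ = [
    "ORIENTATIONS",
    "LabeledScores",
    "RocResult",
    "ConfusionMetrics",
    "ConsensusRule",
    "ThresholdResult",
    "Grouping",
    "STANDARD_GROUPINGS",
    "roc_and_auc",
    "optimal_threshold",
    "confusion_metrics",
    "consensus_diagnose",
    "consensus_rule_battery",
    "table1_layout",
    "evaluate_grouping",
]

#: Direction in which each classifier indicates inhibition: -1 means low
#: values are positive (rho, cPDR90), +1 means high values are (T50, T_peak).
ORIENTATIONS: dict[str, int] = {"rho": -1, "cpdr90": -1, "t50": +1, "tpeak": +1}


class UndefinedRocError(ValueError):
    """ROC is undefined when one of the classes is empty."""


@dataclass(frozen=True)
class LabeledScores:
    """Classifier scores with binary inhibition labels.

    ``orientation`` is +1 if a high raw score indicates inhibition and -1
    if a low raw score does; ``oriented()`` returns scores flipped so that
    higher always means more inhibited.
    """

    ids: tuple
    scores: np.ndarray
    labels: np.ndarray
    orientation: int = +1

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if s.shape != y.shape or s.ndim != 1:
            raise ValueError("scores and labels must be 1-D and equal length")
        if len(self.ids) != s.size:
            raise ValueError("ids must match scores in length")
        if self.orientation not in (-1, +1):
            raise ValueError("orientation must be +1 or -1")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y)

    def oriented(self) -> np.ndarray:
        return self.orientation * self.scores

    def check_two_classes(self) -> None:
        if self.labels.sum() in (0, self.labels.size):
            raise UndefinedRocError("both classes must be non-empty")


@dataclass(frozen=True)
class RocResult:
    """One ROC sweep: thresholds (oriented scale), rates and trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and the derived accuracy / sens / spec / MCC."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ThresholdResult:
    """Youden-optimal cutpoint (on the oriented scale) and its metrics."""

    threshold: float
    orientation: int
    youden_j: float
    metrics: ConfusionMetrics

    def predict(self, raw_scores) -> np.ndarray:
        """Binary calls for raw (unoriented) scores at this threshold."""
        s = self.orientation * np.asarray(raw_scores, dtype=float)
        return (s >= self.threshold).astype(int)


def roc_and_auc(data: LabeledScores) -> RocResult:
    """ROC sweep over all distinct oriented scores with trapezoidal AUC.

    The trapezoidal area equals the Mann-Whitney pair statistic
    (#concordant + half #tied) / (n+ * n-), ties contributing diagonal
    segments.
    """
    data.check_two_classes()
    fpr, tpr, thr = roc_curve(data.labels, data.oriented(), drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def confusion_metrics(predictions, labels) -> ConfusionMetrics:
    """Counts and accuracy / sensitivity / specificity / MCC.

    MCC is set to 0 whenever any factor of its denominator vanishes (e.g.
    constant predictions), the convention under which a degenerate
    classifier scores as a coin toss.
    """
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    if pred.size < 1:
        raise ValueError("need at least one sample")
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n = pred.size
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=acc, sensitivity=sens, specificity=spec, mcc=float(mcc),
    )


def optimal_threshold(data: LabeledScores) -> ThresholdResult:
    """Cutpoint maximizing sensitivity + specificity (Youden's J).

    Candidates are midpoints between consecutive distinct oriented scores
    plus -inf and +inf; a sample is called positive when its oriented score
    is >= the threshold.  Ties in J are broken toward higher specificity,
    then toward the lower threshold.
    """
    data.check_two_classes()
    s = data.oriented()
    y = data.labels
    distinct = np.unique(s)
    candidates = [-np.inf]
    candidates.extend((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append(np.inf)
    best: ThresholdResult | None = None
    for thr in candidates:
        m = confusion_metrics((s >= thr).astype(int), y)
        j = m.sensitivity + m.specificity - 1.0
        if (
            best is None
            or j > best.youden_j + 1e-12
            or (
                abs(j - best.youden_j) <= 1e-12
                and (
                    m.specificity > best.metrics.specificity + 1e-12
                    or (
                        abs(m.specificity - best.metrics.specificity) <= 1e-12
                        and thr < best.threshold
                    )
                )
            )
        ):
            best = ThresholdResult(
                threshold=float(thr),
                orientation=data.orientation,
                youden_j=float(j),
                metrics=m,
            )
    assert best is not None
    return best


# --- consensus rules ---------------------------------------------------------


@dataclass(frozen=True)
class ConsensusRule:
    """A rule over the columns of a per-classifier binary call matrix."""

    kind: str  # "single" | "and" | "or" | "majority"
    members: tuple[int, ...] = ()
    min_votes: int = 2


def consensus_diagnose(binary_calls, rule: ConsensusRule) -> np.ndarray:
    """Apply one consensus rule to an (n_samples, n_classifiers) call matrix."""
    calls = np.asarray(binary_calls, dtype=bool)
    if calls.ndim != 2:
        raise ValueError("binary_calls must be 2-D (samples x classifiers)")
    if rule.kind == "single":
        (k,) = rule.members
        return calls[:, k].astype(int)
    if rule.kind in ("and", "or"):
        if len(rule.members) == 0:
            raise ValueError("AND/OR rule requires a non-empty member subset")
        sub = calls[:, list(rule.members)]
        agg = sub.all(axis=1) if rule.kind == "and" else sub.any(axis=1)
        return agg.astype(int)
    if rule.kind == "majority":
        if calls.shape[1] < 3:
            raise ValueError("majority rule requires >= 3 classifiers")
        return (calls.sum(axis=1) >= rule.min_votes).astype(int)
    raise ValueError(f"unknown rule kind {rule.kind!r}")


def consensus_rule_battery(names: Sequence[str]) -> list[tuple[str, ConsensusRule]]:
    """The standard battery for a classifier subset: singletons, all pairwise
    intersections, the full intersection, all pairwise unions, the full
    union, and (for >= 3 members) the majority rule."""
    k = len(names)
    if k == 0:
        raise ValueError("need at least one classifier")
    battery: list[tuple[str, ConsensusRule]] = [
        (names[i], ConsensusRule("single", (i,))) for i in range(k)
    ]
    for i, j in combinations(range(k), 2):
        battery.append((f"{names[i]} & {names[j]}", ConsensusRule("and", (i, j))))
    if k >= 3:
        battery.append((" & ".join(names), ConsensusRule("and", tuple(range(k)))))
        battery.append((" | ".join(names), ConsensusRule("or", tuple(range(k)))))
    for i, j in combinations(range(k), 2):
        battery.append((f"{names[i]} | {names[j]}", ConsensusRule("or", (i, j))))
    if k >= 3:
        battery.append(("majority", ConsensusRule("majority", tuple(range(k)))))
    return battery


def table1_layout(names: Sequence[str]) -> list[str]:
    """The 11-column report layout for a 3-classifier battery: singletons,
    pairwise intersections, the full union, pairwise unions, majority (the
    full intersection is computed but not part of this layout)."""
    battery = [name for name, _ in consensus_rule_battery(names)]
    if len(names) == 3:
        battery.remove(" & ".join(names))
    return battery


# --- clinical groupings ------------------------------------------------------


@dataclass(frozen=True)
class Grouping:
    """A binary clinical comparison over dose conditions.

    Curves whose condition is in ``positives`` are labelled 1 (inhibited),
    those in ``negatives`` 0; other conditions are dropped.
    """

    name: str
    negatives: tuple[str, ...]
    positives: tuple[str, ...]


#: The four standard comparisons for a 0 / 100 / 750 mg inhibitor crossover.
STANDARD_GROUPINGS: tuple[Grouping, ...] = (
    Grouping("any_inhibition", ("0",), ("100", "750")),
    Grouping("severe_vs_none_mild", ("0", "100"), ("750",)),
    Grouping("mild_inhibition", ("0",), ("100",)),
    Grouping("severe_inhibition", ("0",), ("750",)),
)


def _scores_for(
    table: pd.DataFrame, grouping: Grouping, classifier: str
) -> LabeledScores:
    mask = table["condition"].isin(grouping.negatives + grouping.positives)
    sub = table.loc[mask]
    labels = sub["condition"].isin(grouping.positives).astype(int).to_numpy()
    return LabeledScores(
        ids=tuple(sub["participant_id"]),
        scores=sub[classifier].to_numpy(dtype=float),
        labels=labels,
        orientation=ORIENTATIONS.get(classifier, +1),
    )


def evaluate_grouping(
    classifier_table: pd.DataFrame,
    grouping: Grouping,
    classifier_subset: Sequence[str] = ("rho", "cpdr90", "t50"),
    duration: float | None = None,
) -> dict:
    """Full single-plus-consensus evaluation of one clinical comparison.

    ``classifier_table`` is tidy with columns ``participant_id``,
    ``condition``, optionally ``duration_min``, and one column per
    classifier.  Per classifier: ROC + AUC and the Youden-optimal threshold;
    then every consensus rule of the battery is scored at those
    per-classifier thresholds.  Returns a dict with keys ``roc`` (name ->
    RocResult), ``thresholds`` (name -> ThresholdResult) and ``metrics`` (a
    tidy DataFrame, one row per rule).
    """
    table = classifier_table
    if duration is not None:
        table = table.loc[np.isclose(table["duration_min"], duration)]
    missing = [c for c in classifier_subset if c not in table.columns]
    if missing:
        raise KeyError(f"classifier columns missing from table: {missing}")

    roc: dict[str, RocResult] = {}
    thresholds: dict[str, ThresholdResult] = {}
    calls = []
    labels = None
    for name in classifier_subset:
        data = _scores_for(table, grouping, name)
        labels = data.labels
        roc[name] = roc_and_auc(data)
        thr = optimal_threshold(data)
        thresholds[name] = thr
        calls.append(thr.predict(data.scores))
    call_matrix = np.column_stack(calls)

    rows = []
    for rule_name, rule in consensus_rule_battery(list(classifier_subset)):
        pred = consensus_diagnose(call_matrix, rule)
        m = confusion_metrics(pred, labels)
        rows.append(
            {
                "grouping": grouping.name,
                "rule": rule_name,
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "mcc": m.mcc,
                "tp": m.tp,
                "fp": m.fp,
                "tn": m.tn,
                "fn": m.fn,
            }
        )
    return {"roc": roc, "thresholds": thresholds, "metrics": pd.DataFrame(rows)}
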