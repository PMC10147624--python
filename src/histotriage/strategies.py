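"""Triage strategies for a two-step diagnostic pipeline.

A risk score from histology acts as a first-line gate before gold-standard
sequencing (treated as a perfect test).  Writing P for the number of truly
mutated slides, n for the cohort size, Se(X) = TP / P for the sensitivity
of the full gate-then-sequence pipeline, and P(DL) / N(DL) for the
fractions called positive / negative by the gate, the three strategies are
constrained optimizations over the score threshold:

* **Save-all** — maximize the avoided-test fraction N(DL) subject to
  Se(X) >= T (default T = 0.95): spare as many sequencing tests as a
  sensitivity floor allows.
* **Fixed-capacity** — maximize Se(X) subject to P(DL) <= T
  (T = 0.30 / 0.50 / 0.70): sequence the T·n highest-scoring slides when
  only a fraction T of tests is available.  A random gate attains
  Se(X) = T in expectation.
* **Prioritize** — fast-track the top T fraction (T = 0.05 / 0.10) and
  report its positive predictive value, the relative risk RR = PPV /
  prevalence, and the prevalence-free odds ratio of the selected-by-mutated
  2x2 table.

All three depend on the scores only through their ranks, so any strictly
monotone rescaling of the scores leaves the results unchanged.
Cross-validated variants report per-fold values with mean and the standard
deviation of the mean (SD across folds / sqrt(#folds)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import derive_seed
from .cohort import Cohort
from .split import FoldPlan

__all__ = ["OperatingPoint", "StrategyResult", "save_all", "fixed_capacity",
           "prioritize", "cross_validated_strategy", "prevalence_dependence",
           "fold_summary", "strategy_table", "DegenerateCapacityError"]

_EPS = 1e-9  # guards ceil/floor of products like 0.95 * P against FP noise


class DegenerateCapacityError(ValueError):
    """Capacity or top fraction selects zero slides."""


@dataclass
class OperatingPoint:
    """A score threshold and the classification counts it induces.

    Slides with score >= threshold are gate-positive and get sequenced;
    sequencing is assumed perfect, so pipeline sensitivity is TP / (TP+FN).
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    feasible: bool = True

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def dl_positive_fraction(self) -> float:
        """P(DL): fraction of slides sent to sequencing."""
        return (self.tp + self.fp) / self.n

    @property
    def dl_negative_fraction(self) -> float:
        """N(DL): fraction of slides spared sequencing."""
        return (self.tn + self.fn) / self.n

    @property
    def sensitivity(self) -> float:
        """Se(X): pipeline sensitivity with a perfect downstream test."""
        return self.tp / (self.tp + self.fn)


@dataclass
class StrategyResult:
    """Cross-validated metric for one (gene, strategy, parameter) triple."""

    gene: str
    strategy: str
    parameter: float
    fold_values: list[float]
    mean: float
    dispersion: float
    extras: dict = field(default_factory=dict)


def _check_scores_labels(scores, labels, need_both_classes=True):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d arrays")
    if need_both_classes and (labels.min() == labels.max()):
        raise ValueError("both label classes are required")
    return scores, labels


def _rank_order(scores: np.ndarray, slide_ids=None) -> np.ndarray:
    """Indices by descending score; ties broken by slide_id (or position)."""
    tiebreak = np.arange(len(scores)) if slide_ids is None \
        else np.asarray(slide_ids)
    return np.lexsort((tiebreak, -scores))


def save_all(scores, labels, sensitivity_target: float = 0.95) -> OperatingPoint:
    """Maximize avoided tests N(DL) subject to Se(X) >= sensitivity_target.

    Thresholds are drawn from the observed score values (plus +inf); the
    finite-sample constraint is TP >= ceil(target * P).  When only the
    test-everyone threshold satisfies the constraint, the returned point
    has N(DL) = 0 and ``feasible=False``.
    """
    if not (0.0 < sensitivity_target <= 1.0):
        raise ValueError("sensitivity_target must lie in (0, 1]")
    scores, labels = _check_scores_labels(scores, labels)
    n = len(scores)
    n_pos = int((labels == 1).sum())
    required_tp = math.ceil(sensitivity_target * n_pos - _EPS)

    pos_sorted = np.sort(scores[labels == 1])
    all_sorted = np.sort(scores)
    best = None
    for t in np.concatenate((np.unique(scores), [np.inf])):
        tp = n_pos - np.searchsorted(pos_sorted, t, side="left")
        if tp < required_tp:
            continue
        called = n - np.searchsorted(all_sorted, t, side="left")
        point = OperatingPoint(threshold=float(t), tp=int(tp),
                               fp=int(called - tp),
                               fn=int(n_pos - tp),
                               tn=int(n - called - (n_pos - tp)))
        if best is None or point.dl_negative_fraction > best.dl_negative_fraction:
            best = point
    assert best is not None and best.sensitivity >= sensitivity_target - _EPS
    if best.dl_negative_fraction == 0.0:
        best.feasible = False
    return best


def fixed_capacity(scores, labels, capacity: float,
                   slide_ids=None) -> OperatingPoint:
    """Maximize Se(X) under a sequencing budget P(DL) <= capacity.

    Sequences the floor(capacity * n) highest-scoring slides; boundary ties
    are broken by slide identifier so the budget is never exceeded and the
    result is reproducible.
    """
    if not (0.0 < capacity <= 1.0):
        raise ValueError("capacity must lie in (0, 1]")
    scores, labels = _check_scores_labels(scores, labels)
    n = len(scores)
    k = int(math.floor(capacity * n + _EPS))
    if k == 0:
        raise DegenerateCapacityError(
            f"capacity {capacity} selects zero of {n} slides")
    order = _rank_order(scores, slide_ids)
    selected = order[:k]
    n_pos = int((labels == 1).sum())
    tp = int(labels[selected].sum())
    return OperatingPoint(threshold=float(scores[selected[-1]]),
                          tp=tp, fp=k - tp, fn=n_pos - tp,
                          tn=n - k - (n_pos - tp))


@dataclass
class PrioritizeResult:
    """Fast-track metrics for the top fraction of slides by score."""

    n_selected: int
    ppv: float
    prevalence: float
    relative_risk: float
    odds_ratio: float
    continuity_corrected: bool
    operating_point: OperatingPoint


def prioritize(scores, labels, top_fraction: float,
               slide_ids=None) -> PrioritizeResult:
    """PPV, relative risk and odds ratio of the fast-tracked top fraction.

    Selects the top ``max(1, floor(top_fraction * n))`` slides by score.
    RR = PPV / prevalence; the odds ratio is the cross-product of the
    selected-by-mutated 2x2 table with a 0.5 continuity correction applied
    to all cells when any cell is zero (flagged).
    """
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must lie strictly in (0, 1)")
    scores, labels = _check_scores_labels(scores, labels,
                                          need_both_classes=False)
    n = len(scores)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("prevalence is 0; relative risk undefined")
    k = max(1, int(math.floor(top_fraction * n + _EPS)))
    order = _rank_order(scores, slide_ids)
    selected = order[:k]
    a = int(labels[selected].sum())       # selected & mutated
    b = k - a                             # selected & not mutated
    c = n_pos - a                         # unselected & mutated
    d = n - k - c                         # unselected & not mutated
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = ((x + 0.5 for x in (a, b, c, d)) if corrected
                      else (a, b, c, d))
    prevalence = n_pos / n
    ppv = a / k
    op = OperatingPoint(threshold=float(scores[selected[-1]]),
                        tp=a, fp=b, fn=c, tn=d)
    return PrioritizeResult(
        n_selected=k, ppv=ppv, prevalence=prevalence,
        relative_risk=ppv / prevalence,
        odds_ratio=(aa * dd) / (bb * cc),
        continuity_corrected=corrected, operating_point=op)


def fold_summary(fold_values, sd_of_mean: bool = True) -> tuple[float, float]:
    """Mean and dispersion of per-fold metric values.

    Dispersion is the standard deviation of the mean (sample SD across the
    folds used, divided by sqrt of their number); ``sd_of_mean=False``
    reports the raw SD instead.
    """
    arr = np.asarray(fold_values, dtype=float)
    if arr.size == 0:
        raise ValueError("no fold values")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd / math.sqrt(arr.size) if sd_of_mean else sd


_STRATEGIES = ("save_all", "fixed_capacity", "prioritize")


def _fold_metric(strategy: str, scores, labels, parameter, slide_ids):
    if strategy == "save_all":
        op = save_all(scores, labels, parameter)
        return op.dl_negative_fraction, {"sensitivity": op.sensitivity,
                                         "feasible": op.feasible}
    if strategy == "fixed_capacity":
        op = fixed_capacity(scores, labels, parameter, slide_ids)
        return op.sensitivity, {"dl_positive_fraction": op.dl_positive_fraction}
    if strategy == "prioritize":
        res = prioritize(scores, labels, parameter, slide_ids)
        return res.ppv, {"relative_risk": res.relative_risk,
                         "odds_ratio": res.odds_ratio,
                         "prevalence": res.prevalence}
    raise ValueError(f"unknown strategy {strategy!r}; pick from {_STRATEGIES}")


def cross_validated_strategy(cohort: Cohort, gene: str, strategy: str,
                             parameter: float, plan: FoldPlan,
                             scorer=None, seed: int = 0,
                             sd_of_mean: bool = True) -> StrategyResult:
    """Apply one strategy on each fold's test side; mean +/- SD of the mean.

    By default each fold is evaluated on the cohort's precomputed slide
    scores for ``gene``; passing ``scorer(cohort, gene, train_mask, seed)``
    retrains a model per fold instead.  Folds whose test side lacks a label
    class are skipped with a warning; the dispersion divisor shrinks
    accordingly.  The primary metric is N(DL) for save-all, Se(X) for
    fixed-capacity and PPV for prioritize; auxiliary quantities (RR, odds
    ratio, prevalence, ...) are averaged into ``extras``.
    """
    if plan.k < 2:
        raise ValueError("plan must have at least 2 folds")
    labels = cohort.labels(gene)
    ids = cohort.slide_ids()
    fold_values: list[float] = []
    extra_acc: dict[str, list[float]] = {}
    for f in range(plan.k):
        test = plan.fold_mask(cohort, f)
        y = labels[test]
        if len(np.unique(y)) < 2:
            warnings.warn(f"fold {f} lacks a label class for {gene}; skipped",
                          stacklevel=2)
            continue
        if scorer is None:
            s = cohort.scores(gene)[test]
        else:
            s = np.asarray(scorer(cohort, gene, ~test,
                                  derive_seed(seed, strategy, gene, f)))[test]
        value, extras = _fold_metric(strategy, s, y, parameter, ids[test])
        fold_values.append(float(value))
        for key, v in extras.items():
            extra_acc.setdefault(key, []).append(float(v))
    if not fold_values:
        raise ValueError(f"all {plan.k} folds degenerate for gene {gene!r}")
    mean, dispersion = fold_summary(fold_values, sd_of_mean)
    extras = {k: float(np.mean(v)) for k, v in extra_acc.items()}
    extras["n_folds_used"] = len(fold_values)
    return StrategyResult(gene=gene, strategy=strategy, parameter=parameter,
                          fold_values=fold_values, mean=mean,
                          dispersion=dispersion, extras=extras)


def prevalence_dependence(results: list[StrategyResult], prevalences,
                          use_odds_ratio: bool = False) -> tuple[float, float]:
    """Pearson correlation of per-gene performance against prevalence.

    ``prevalences`` maps gene name -> prevalence (or is a sequence aligned
    with ``results``).  With ``use_odds_ratio`` the prevalence-free odds
    ratio from the extras replaces the primary metric, which is how the
    apparent prevalence dependence of RR is shown to be extrinsic.
    Returns (pearson_r, two-sided p-value).
    """
    if len(results) < 3:
        raise ValueError("need results for at least 3 genes")
    if isinstance(prevalences, dict):
        x = np.array([prevalences[r.gene] for r in results], dtype=float)
    else:
        x = np.asarray(prevalences, dtype=float)
    if use_odds_ratio:
        y = np.array([r.extras["odds_ratio"] for r in results], dtype=float)
    else:
        y = np.array([r.mean for r in results], dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def strategy_table(results: list[StrategyResult]) -> pd.DataFrame:
    """One row per (gene, strategy, parameter); fold values ';'-joined."""
    rows = []
    for r in results:
        row = {"gene": r.gene, "strategy": r.strategy,
               "parameter": r.parameter,
               "fold_values": ";".join(f"{v:.6f}" for v in r.fold_values),
               "mean": r.mean, "dispersion": r.dispersion}
        row.update({f"extra_{k}": v for k, v in r.extras.items()})
        rows.append(row)
    return pd.DataFrame(rows)
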