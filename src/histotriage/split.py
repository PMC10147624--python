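"""Site-aware train/test partitions.

Tissue-source sites introduce batch effects (staining, scanners, patient
mix); letting a site contribute slides to both sides of a split inflates
apparent performance.  All partitions here are therefore *site-atomic*:
every slide of a site lands in the same fold.  Within that hard constraint,
fold sizes and positive counts are balanced best-effort.

Two partition schemes are provided, as scikit-learn-compatible cross
validators (``split(X, y, groups)``) and as cohort-level functions
returning a :class:`FoldPlan`:

* a stratified holdout (default 70/30), and
* k-fold cross-validation (default k = 5).

Algorithm: sites are shuffled by seed, stably sorted by size (largest
first), then greedily assigned, each site going to the fold with the
lexicographically best (size fill ratio, positive-count imbalance, fold
index).  Ties break deterministically so identical seeds give identical
plans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import BaseCrossValidator
from sklearn.utils import check_random_state

from .cohort import Cohort

__all__ = ["FoldPlan", "SiteAwareHoldout", "SiteAwareKFold",
           "site_aware_holdout", "site_aware_kfold",
           "InfeasibleSplitError", "StratificationError"]


class InfeasibleSplitError(ValueError):
    """Too few sites to honour the requested site-atomic partition."""


class StratificationError(ValueError):
    """Labels unusable for stratification (single class)."""


@dataclass
class FoldPlan:
    """A site-atomic partition of a cohort's slides into folds.

    For a holdout plan ``k == 2`` with fold 0 = train and fold 1 = test;
    for k-fold CV folds run 0..k-1 and each serves once as the test side.
    """

    assignments: dict[str, int]
    k: int
    gene: str | None = None

    def fold_of(self, slide_id: str) -> int:
        return self.assignments[slide_id]

    def fold_mask(self, cohort: Cohort, fold: int) -> np.ndarray:
        ids = cohort.slide_ids()
        missing = [s for s in ids if s not in self.assignments]
        if missing:
            raise KeyError(f"slides absent from plan: {missing[:5]}")
        return np.array([self.assignments[s] == fold for s in ids])

    def test_mask(self, cohort: Cohort, fold: int = 1) -> np.ndarray:
        return self.fold_mask(cohort, fold)

    def train_mask(self, cohort: Cohort, fold: int = 1) -> np.ndarray:
        return ~self.fold_mask(cohort, fold)

    def fold_sizes(self) -> list[int]:
        counts = [0] * self.k
        for f in self.assignments.values():
            counts[f] += 1
        return counts

    def check_site_atomic(self, cohort: Cohort) -> None:
        df = cohort.slides
        folds = df["slide_id"].map(self.assignments)
        per_site = df.assign(fold=folds).groupby("site_id")["fold"].nunique()
        broken = per_site[per_site > 1]
        if len(broken):
            raise InfeasibleSplitError(
                f"sites split across folds: {list(broken.index)[:5]}")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"slide_id": list(self.assignments),
                      "fold": list(self.assignments.values())}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, gene: str | None = None) -> "FoldPlan":
        df = pd.read_csv(path, dtype={"slide_id": str})
        assignments = dict(zip(df["slide_id"], df["fold"].astype(int)))
        return cls(assignments=assignments, k=int(df["fold"].max()) + 1,
                   gene=gene)


def _greedy_site_assignment(site_ids: list[str], sizes: np.ndarray,
                            positives: np.ndarray, fractions: np.ndarray,
                            rng: np.random.RandomState) -> dict[str, int]:
    """Assign each site to one fold, balancing size then positives."""
    n_total = float(sizes.sum())
    p_total = float(positives.sum())
    size_target = fractions * n_total
    pos_target = fractions * max(p_total, 1.0)

    order = rng.permutation(len(site_ids))
    # largest-first within the shuffled order (stable, so the seed breaks ties)
    order = order[np.argsort(-sizes[order], kind="stable")]

    fold_size = np.zeros(len(fractions))
    fold_pos = np.zeros(len(fractions))
    fold_count = np.zeros(len(fractions), dtype=int)
    out: dict[str, int] = {}
    for step, i in enumerate(order):
        remaining = len(order) - step
        empty = [f for f in range(len(fractions)) if fold_count[f] == 0]
        # never leave a fold without a site: once the leftover sites are
        # only just enough, they must go to the still-empty folds
        candidates = empty if 0 < len(empty) >= remaining else range(len(fractions))
        best = None
        for f in candidates:
            size_fill = (fold_size[f] + sizes[i]) / size_target[f]
            pos_fill = (fold_pos[f] + positives[i]) / pos_target[f]
            key = (round(size_fill, 9), round(abs(pos_fill - size_fill), 9), f)
            if best is None or key < best[0]:
                best = (key, f)
        f = best[1]
        fold_size[f] += sizes[i]
        fold_pos[f] += positives[i]
        fold_count[f] += 1
        out[site_ids[i]] = f
    return out


class _SiteAwareSplitter(BaseCrossValidator):
    """Shared machinery: site-atomic greedy assignment over groups."""

    def __init__(self, fractions: tuple[float, ...], random_state=None):
        self.fractions = fractions
        self.random_state = random_state

    def _site_folds(self, y, groups) -> tuple[np.ndarray, np.ndarray]:
        if groups is None:
            raise ValueError("groups (site identifiers) are required")
        groups = np.asarray(groups)
        y = np.zeros(len(groups), dtype=int) if y is None else np.asarray(y)
        site_ids = sorted(pd.unique(groups))
        if len(site_ids) < len(self.fractions):
            raise InfeasibleSplitError(
                f"{len(site_ids)} site(s) cannot fill {len(self.fractions)} "
                "site-disjoint folds")
        sizes = np.array([(groups == s).sum() for s in site_ids])
        pos = np.array([y[groups == s].sum() for s in site_ids])
        rng = check_random_state(self.random_state)
        site_fold = _greedy_site_assignment(
            site_ids, sizes, pos, np.asarray(self.fractions, dtype=float), rng)
        folds = np.array([site_fold[g] for g in groups])
        return folds, groups

    def _iter_test_masks(self, X=None, y=None, groups=None):
        folds, _ = self._site_folds(y, groups)
        for f in range(len(self.fractions)):
            yield folds == f

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return len(self.fractions)


class SiteAwareKFold(_SiteAwareSplitter):
    """K-fold cross-validator with no tissue-source site shared across folds.

    Drop-in for ``sklearn.model_selection.GroupKFold`` with approximate
    label stratification and seeded determinism.

    Parameters
    ----------
    n_splits : int, default 5
    random_state : int or None
    """

    def __init__(self, n_splits: int = 5, random_state=None):
        if n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        super().__init__(tuple([1.0 / n_splits] * n_splits), random_state)
        self.n_splits = n_splits


class SiteAwareHoldout(_SiteAwareSplitter):
    """Single stratified train/test holdout with site-atomic sides.

    Yields one (train, test) split; the realized test fraction is as close
    to ``test_fraction`` as site granularity permits.
    """

    def __init__(self, test_fraction: float = 0.30, random_state=None):
        if not (0.0 < test_fraction < 1.0):
            raise ValueError("test_fraction must lie in (0, 1)")
        super().__init__((1.0 - test_fraction, test_fraction), random_state)
        self.test_fraction = test_fraction

    def _iter_test_masks(self, X=None, y=None, groups=None):
        folds, _ = self._site_folds(y, groups)
        yield folds == 1  # fold 1 is the test side

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return 1


def _plan_from_cohort(cohort: Cohort, gene: str | None,
                      splitter: _SiteAwareSplitter, k: int,
                      require_both_classes: bool) -> FoldPlan:
    y = None
    if gene is not None:
        y = cohort.labels(gene)
        if require_both_classes and len(np.unique(y)) < 2:
            raise StratificationError(
                f"gene {gene!r} has a single label class; cannot stratify")
    folds, _ = splitter._site_folds(y, cohort.slides["site_id"].to_numpy())
    plan = FoldPlan(assignments=dict(zip(cohort.slide_ids(), map(int, folds))),
                    k=k, gene=gene)
    plan.check_site_atomic(cohort)
    return plan


def site_aware_holdout(cohort: Cohort, gene: str | None = None,
                       test_fraction: float = 0.30,
                       seed: int = 0) -> FoldPlan:
    """70/30-style holdout with no site on both sides (fold 0=train, 1=test)."""
    splitter = SiteAwareHoldout(test_fraction, random_state=seed)
    return _plan_from_cohort(cohort, gene, splitter, k=2,
                             require_both_classes=True)


def site_aware_kfold(cohort: Cohort, gene: str | None = None, k: int = 5,
                     seed: int = 0) -> FoldPlan:
    """Site-disjoint k-fold plan; each fold serves once as the test side."""
    splitter = SiteAwareKFold(n_splits=k, random_state=seed)
    return _plan_from_cohort(cohort, gene, splitter, k=k,
                             require_both_classes=False)
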