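"""Per-gene predictability screen.

A gene's mutational status counts as predictable when the slide-level AUC
of the classifier, over repeated random initializations on one fixed
site-disjoint train/test split, is significantly above the chance value
0.5: a one-sided one-sample t-test on the AUC replicates (normality
assumed), corrected across genes with Benjamini-Hochberg at FDR 0.05.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seeds import derive_seed
from .cohort import Cohort
from .ensemble import MLPConfig, score_slides_by_model
from .split import FoldPlan

__all__ = ["ScreenResult", "compute_auc", "t_test_vs_half", "bh_correct",
           "screen_genes", "screen_from_auc_replicates", "screen_table",
           "DegenerateVarianceError"]


class DegenerateVarianceError(ValueError):
    """All AUC replicates identical; the replicate t-test is undefined."""


@dataclass
class ScreenResult:
    """Screen outcome for one gene."""

    gene: str
    auc_replicates: list[float]
    mean_auc: float
    sd_auc: float
    t_statistic: float
    p_one_sided: float
    p_adjusted: float
    predictable: bool


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    The probability that a uniformly chosen positive outranks a uniformly
    chosen negative, ties counted one half.  Both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: a single label class is present")
    ranks = stats.rankdata(scores)
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def t_test_vs_half(auc_replicates) -> tuple[float, float]:
    """One-sided one-sample t-test of the AUC replicates against 0.5.

    ``t = (mean - 0.5) / (sd / sqrt(n))`` with ``df = n - 1``; the p-value
    is for the alternative "mean AUC > 0.5".  Identical replicates raise
    :class:`DegenerateVarianceError` rather than reporting t = infinity.
    """
    reps = np.asarray(auc_replicates, dtype=float)
    if reps.size < 2:
        raise ValueError("need at least 2 AUC replicates for the t-test")
    if np.all(reps == reps[0]):
        raise DegenerateVarianceError(
            "zero variance across AUC replicates; t-test undefined")
    res = stats.ttest_1samp(reps, popmean=0.5, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def bh_correct(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns ``(adjusted_p, reject)``.  Rejections form a prefix of the
    ascending p-value order; adjusted p-values are the usual step-up
    minima, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return p_adj, reject


def screen_from_auc_replicates(replicates: dict[str, list[float]],
                               fdr: float = 0.05) -> list[ScreenResult]:
    """Run the t-test + BH stage on precomputed per-gene AUC replicates.

    Genes are corrected jointly in one family; the verdict does not depend
    on the dictionary order.
    """
    genes = sorted(replicates)
    stats_out = {}
    for g in genes:
        reps = np.asarray(replicates[g], dtype=float)
        t, p = t_test_vs_half(reps)
        stats_out[g] = (reps, t, p)
    p_adj, reject = bh_correct([stats_out[g][2] for g in genes], fdr=fdr)
    results = []
    for g, pa, rej in zip(genes, p_adj, reject):
        reps, t, p = stats_out[g]
        results.append(ScreenResult(
            gene=g, auc_replicates=[float(x) for x in reps],
            mean_auc=float(reps.mean()), sd_auc=float(np.std(reps, ddof=1)),
            t_statistic=t, p_one_sided=p, p_adjusted=float(pa),
            predictable=bool(rej)))
    # restore the caller's gene order for convenience (verdicts unaffected)
    order = {g: i for i, g in enumerate(replicates)}
    return sorted(results, key=lambda r: order[r.gene])


def screen_genes(cohort: Cohort, plan: FoldPlan, repetitions: int = 5,
                 fdr: float = 0.05, config: MLPConfig | None = None,
                 scorer=None, seed: int = 0) -> list[ScreenResult]:
    """Screen every cohort gene for predictable mutational status.

    For each gene, ``repetitions`` independently initialized ensembles are
    trained on the train side of the holdout ``plan`` (the split itself is
    fixed; only initialization varies) and the test-side AUC is recorded.
    The replicates then go through :func:`t_test_vs_half` and, jointly
    across genes, :func:`bh_correct`.

    ``scorer(cohort, gene, train_mask, seed) -> slide-score Series`` may
    replace the default tile-ensemble scorer (e.g. for precomputed or
    simulated scores).  Per-(gene, repetition) seeds are derived from
    ``seed`` by name, so results are invariant to gene ordering.
    """
    if repetitions < 2:
        raise ValueError("repetitions must be >= 2 (t-test needs variance)")
    if plan.k != 2:
        raise ValueError("screen_genes requires a holdout plan (k == 2)")
    if scorer is None:
        base_config = config or MLPConfig()

        def scorer(c, gene, train_mask, rep_seed):
            cfg = MLPConfig(**{**base_config.__dict__, "seed": rep_seed})
            return score_slides_by_model(c, gene, train_mask, cfg)

    test_mask = plan.test_mask(cohort)
    replicates: dict[str, list[float]] = {}
    for gene in cohort.genes:
        y_test = cohort.labels(gene)[test_mask]
        reps = []
        for rep in range(repetitions):
            rep_seed = derive_seed(seed, "screen", gene, rep)
            slide_scores = scorer(cohort, gene, ~test_mask, rep_seed)
            s_test = np.asarray(slide_scores)[test_mask]
            reps.append(compute_auc(s_test, y_test))
        replicates[gene] = reps
    return screen_from_auc_replicates(replicates, fdr=fdr)


def screen_table(results: list[ScreenResult]) -> pd.DataFrame:
    """One row per gene; AUC replicates as a semicolon-joined field."""
    return pd.DataFrame([{
        "gene": r.gene,
        "auc_replicates": ";".join(f"{a:.6f}" for a in r.auc_replicates),
        "mean_auc": r.mean_auc, "sd_auc": r.sd_auc,
        "t_statistic": r.t_statistic, "p_one_sided": r.p_one_sided,
        "p_adjusted": r.p_adjusted, "predictable": r.predictable,
    } for r in results])


def write_screen_outputs(results: list[ScreenResult], csv_path: str | Path,
                         json_path: str | Path | None = None) -> None:
    screen_table(results).to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {"n_genes": len(results),
                   "n_predictable": int(sum(r.predictable for r in results))}
        Path(json_path).write_text(json.dumps(summary, indent=2))
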