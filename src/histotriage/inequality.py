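"""Sensitivity-inequality analysis for the fixed-capacity strategy.

Populations differ in how much sequencing capacity they can afford.  A
population with capacity c and a random gate reaches pipeline sensitivity
c; a population with full capacity reaches 1.  The *sensitivity gap* of a
capacity-c population is its distance, in percentage points, to the
full-capacity population.  Gating with an informative risk score raises
sensitivity above c at the same budget and therefore shrinks the gap; this
module quantifies that shrinkage, averaging the best-performing genes with
equal weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strategies import StrategyResult

__all__ = ["InequalityTable", "select_top_genes", "inequality_table"]

DEFAULT_CAPACITIES = (0.30, 0.50, 0.70, 1.00)


@dataclass
class InequalityTable:
    """Per-capacity comparison of gated vs random test allocation.

    Sensitivities and gaps are kept on the percent scale (a 'gap' of 70
    means 70 percentage points below the full-capacity population).
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def row(self, capacity: float) -> pd.Series:
        match = self.table[np.isclose(self.table["capacity"], capacity)]
        if match.empty:
            raise KeyError(f"no row at capacity {capacity}")
        return match.iloc[0]


def select_top_genes(results: list[StrategyResult], n: int = 5,
                     ranking_capacity: float = 0.5) -> list[str]:
    """The n genes with highest mean fixed-capacity sensitivity.

    Ranking is done at one capacity (default 0.50); ties break toward the
    lexicographically smaller gene name.
    """
    pool = [r for r in results if r.strategy == "fixed_capacity"
            and np.isclose(r.parameter, ranking_capacity)]
    if len(pool) < n:
        raise ValueError(
            f"need fixed-capacity results at capacity {ranking_capacity} "
            f"for at least {n} genes, have {len(pool)}")
    ranked = sorted(pool, key=lambda r: (-r.mean, r.gene))
    return [r.gene for r in ranked[:n]]


def inequality_table(per_capacity_sensitivities: dict[float, list[float]]
                     ) -> InequalityTable:
    """Build the gap table from per-capacity gene sensitivities (fractions).

    ``per_capacity_sensitivities`` maps capacity -> list of per-gene mean
    pipeline sensitivities (on [0, 1]); genes are averaged with equal
    weights.  The random baseline at capacity c is c itself.  A full
    capacity row (1.0) is appended analytically if absent: there both
    allocations reach sensitivity 1 and all gaps vanish.

    Columns (percent scale): ``sensitivity_with_dl``, ``sensitivity_random``,
    ``gap_with_dl`` / ``gap_random`` (percentage points below the
    full-capacity population), ``absolute_increase`` (DL minus random, in
    points) and ``relative_gap_reduction`` (fraction of the random gap
    closed by the DL gate).
    """
    caps = dict(per_capacity_sensitivities)
    for c, vals in caps.items():
        if not (0.0 < c <= 1.0):
            raise ValueError(f"capacity {c} outside (0, 1]")
        if len(vals) == 0:
            raise ValueError(f"empty gene list at capacity {c}")
    if not any(np.isclose(c, 1.0) for c in caps):
        caps[1.0] = [1.0]

    rows = []
    for c in sorted(caps):
        with_dl = 100.0 * float(np.mean(caps[c])) if not np.isclose(c, 1.0) \
            else 100.0
        random = 100.0 * c
        gap_dl = 100.0 - with_dl
        gap_rand = 100.0 - random
        rows.append({
            "capacity": c,
            "sensitivity_with_dl": with_dl,
            "sensitivity_random": random,
            "gap_with_dl": gap_dl,
            "gap_random": gap_rand,
            "absolute_increase": with_dl - random,
            "relative_gap_reduction":
                (gap_rand - gap_dl) / gap_rand if gap_rand > 0 else 0.0,
        })
    return InequalityTable(pd.DataFrame(rows))
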