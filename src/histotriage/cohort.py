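"""Cohort container shared by every pipeline stage.

A cohort is a table of slides, each belonging to exactly one tissue-source
site, carrying binary per-gene mutation labels and, optionally, slide-level
risk scores and tile-level scores.  All downstream operations (splitting,
screening, triage strategies) consume this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LABEL_PREFIX = "label_"
SCORE_PREFIX = "score_"


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class Cohort:
    """Slides with site membership, per-gene binary labels and optional scores.

    Parameters
    ----------
    slides : pandas.DataFrame
        One row per slide with columns ``slide_id``, ``patient_id``,
        ``site_id``, one ``label_<gene>`` column per gene (values in {0, 1})
        and optionally ``score_<gene>`` columns (values in [0, 1]).
    tiles : pandas.DataFrame, optional
        Long-format tile table with columns ``slide_id``, ``tile_index``,
        ``score`` and optionally feature columns ``f0..f<d-1>``.
    meta : dict
        Free-form provenance (generating config, seed).
    """

    slides: pd.DataFrame
    tiles: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"slide_id", "patient_id", "site_id"}
        missing = required - set(self.slides.columns)
        if missing:
            raise CohortError(f"cohort table lacks columns: {sorted(missing)}")
        if self.slides["slide_id"].duplicated().any():
            dup = self.slides.loc[self.slides["slide_id"].duplicated(), "slide_id"]
            raise CohortError(f"duplicate slide identifiers: {list(dup.unique())[:5]}")
        for gene in self.genes:
            vals = self.slides[LABEL_PREFIX + gene]
            if not np.isin(vals, (0, 1)).all():
                raise CohortError(f"labels for gene {gene!r} are not binary")
        self.slides = self.slides.reset_index(drop=True)

    # -- accessors -----------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return [c[len(LABEL_PREFIX):] for c in self.slides.columns
                if c.startswith(LABEL_PREFIX)]

    @property
    def n_slides(self) -> int:
        return len(self.slides)

    @property
    def sites(self) -> list[str]:
        return sorted(self.slides["site_id"].unique())

    def labels(self, gene: str) -> np.ndarray:
        self._check_gene(gene)
        return self.slides[LABEL_PREFIX + gene].to_numpy(dtype=int)

    def scores(self, gene: str) -> np.ndarray:
        self._check_gene(gene)
        col = SCORE_PREFIX + gene
        if col not in self.slides.columns:
            raise KeyError(f"no slide scores for gene {gene!r}; generate or attach them first")
        return self.slides[col].to_numpy(dtype=float)

    def has_scores(self, gene: str) -> bool:
        return SCORE_PREFIX + gene in self.slides.columns

    def prevalence(self, gene: str) -> float:
        return float(self.labels(gene).mean())

    def slide_ids(self) -> np.ndarray:
        return self.slides["slide_id"].to_numpy()

    def _check_gene(self, gene: str) -> None:
        if gene not in self.genes:
            raise KeyError(f"gene {gene!r} not in cohort (have {self.genes})")

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row-subset of the cohort (tiles restricted to kept slides)."""
        sub = self.slides.loc[np.asarray(mask)].reset_index(drop=True)
        tiles = None
        if self.tiles is not None:
            tiles = self.tiles[self.tiles["slide_id"].isin(sub["slide_id"])]
            tiles = tiles.reset_index(drop=True)
        return Cohort(slides=sub, tiles=tiles, meta=dict(self.meta))

    # -- serialization -------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the slide table; tiles and meta go to sidecar files.

        ``<path>`` gets the slide table, ``<stem>.tiles.csv`` the tile table
        (if present) and ``<stem>.json`` the provenance sidecar.
        """
        path = Path(path)
        self.slides.to_csv(path, index=False)
        if self.tiles is not None:
            self.tiles.to_csv(path.with_suffix(".tiles.csv"), index=False)
        path.with_suffix(".json").write_text(
            json.dumps(self.meta, indent=2, sort_keys=True, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        slides = pd.read_csv(path, dtype={"slide_id": str, "patient_id": str,
                                          "site_id": str})
        tiles_path = path.with_suffix(".tiles.csv")
        tiles = pd.read_csv(tiles_path, dtype={"slide_id": str}) if tiles_path.exists() else None
        meta_path = path.with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(slides=slides, tiles=tiles, meta=meta)
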