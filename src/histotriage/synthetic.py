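"""Synthetic multi-site cohort generator with calibrated score informativeness.

The generator emulates the statistical structure the triage analysis relies
on, without any imaging: slides grouped into tissue-source sites, per-gene
Bernoulli mutation labels at configurable prevalence, and risk scores whose
slide-level discrimination attains a configurable AUC.

Score model
-----------
Scores follow a binormal latent model: each slide carries a latent
``L = mu * y + eps`` with ``eps ~ N(0, 1)`` and ``y`` the binary label, so
the theoretical AUC is ``Phi(mu / sqrt(2))``.  ``auc_to_separation`` inverts
that relation to calibrate ``mu`` from a target AUC.  Latents are squashed
to [0, 1] by a standard logistic map; every downstream strategy is
rank-based, so any strictly monotone squashing is metric-equivalent.

At tile level, a configurable fraction of each slide's tiles ("signal
tiles") share the slide latent plus a small jitter while the remaining
tiles sit at a low background level.  The 99th-percentile slide aggregate
therefore recovers the slide latent (hence the calibrated AUC) even when
only a minority of tiles carry signal -- the situation the high-percentile
aggregation is designed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import Cohort, LABEL_PREFIX, SCORE_PREFIX

__all__ = [
    "GeneSpec",
    "CohortConfig",
    "auc_to_separation",
    "generate_cohort",
    "generate_slide_scores",
    "simulate_null_aucs",
]


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


def auc_to_separation(target_auc: float) -> float:
    """Binormal mean shift ``mu`` giving the requested theoretical AUC.

    For positive latents ~ N(mu, 1) and negative latents ~ N(0, 1) the AUC
    is ``Phi(mu / sqrt(2))``; this returns ``mu = sqrt(2) * Phi^-1(auc)``.

    Parameters
    ----------
    target_auc : float in [0.5, 1)

    Returns
    -------
    float
        Non-negative mean shift; 0 at ``target_auc = 0.5``.
    """
    if not (0.5 <= target_auc < 1.0):
        raise ConfigError(f"target_auc must lie in [0.5, 1), got {target_auc}")
    return float(np.sqrt(2.0) * stats.norm.ppf(target_auc))


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: name, mutation prevalence, score informativeness."""

    name: str
    prevalence: float
    target_auc: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigError(
                f"prevalence for {self.name!r} must lie strictly in (0,1), "
                f"got {self.prevalence}")
        if not (0.5 <= self.target_auc < 1.0):
            raise ConfigError(
                f"target_auc for {self.name!r} must lie in [0.5,1), "
                f"got {self.target_auc}")


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Parameters
    ----------
    n_sites : int
        Number of tissue-source sites.
    slides_per_site : int or list of int
        Uniform site size, or one size per site.
    genes : list of GeneSpec
    tiles_per_slide : int
        Tiles generated per slide (0 disables the tile table).
    signal_tile_fraction : float in (0, 1]
        Fraction of each slide's tiles that carry the slide latent; the
        rest sit at the background level.  Mirrors the assumption that
        mutation-associated morphology affects a minority of the tissue.
    tile_jitter : float
        SD of the jitter added to signal tiles around the slide latent.
    background_level : float
        Latent level of non-signal tiles (well below the signal range so
        a high percentile always lands on signal tiles).
    feature_dim : int
        If > 0, emit tile feature vectors: signal tiles of mutated slides
        are shifted by ``feature_shift`` along the first axis, all other
        tiles are standard Gaussian.  Used to exercise the tile classifier.
    site_dispersion : float
        0 gives equal sites; > 0 draws unequal site sizes (log-normal
        multiplier with this sigma) to stress the site-aware splitter.
    slides_per_patient : int
        Multi-slide patients when > 1 (off by default).
    seed : int
    """

    n_sites: int
    slides_per_site: int | list[int]
    genes: list[GeneSpec]
    tiles_per_slide: int = 0
    signal_tile_fraction: float = 0.1
    tile_jitter: float = 0.25
    background_level: float = -4.0
    feature_dim: int = 0
    site_dispersion: float = 0.0
    slides_per_patient: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ConfigError("n_sites must be positive")
        if isinstance(self.slides_per_site, int):
            if self.slides_per_site <= 0:
                raise ConfigError("slides_per_site must be positive")
        else:
            if len(self.slides_per_site) != self.n_sites:
                raise ConfigError("slides_per_site list must have n_sites entries")
            if any(s <= 0 for s in self.slides_per_site):
                raise ConfigError("slides_per_site entries must be positive")
        if not self.genes:
            raise ConfigError("at least one gene required")
        if not (0.0 < self.signal_tile_fraction <= 1.0):
            raise ConfigError("signal_tile_fraction must lie in (0, 1]")
        if self.tiles_per_slide < 0 or self.feature_dim < 0:
            raise ConfigError("counts must be non-negative")
        self.genes = [g if isinstance(g, GeneSpec) else GeneSpec(*g)
                      for g in self.genes]

    def site_sizes(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.slides_per_site, int):
            base = np.full(self.n_sites, self.slides_per_site, dtype=float)
        else:
            base = np.asarray(self.slides_per_site, dtype=float)
        if self.site_dispersion > 0:
            base = base * rng.lognormal(0.0, self.site_dispersion, self.n_sites)
        return np.maximum(1, np.round(base).astype(int))

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "genes"}
        d["genes"] = [[g.name, g.prevalence, g.target_auc] for g in self.genes]
        return d


def _slide_latents(labels: np.ndarray, mu: float,
                   rng: np.random.Generator) -> np.ndarray:
    return mu * labels + rng.standard_normal(labels.shape[0])


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort; deterministic given ``config.seed``.

    Slide scores (``score_<gene>`` columns) are filled for every gene from
    the calibrated binormal latent.  When ``tiles_per_slide > 0`` a tile
    table is generated for the *first* gene (tile morphology is simulated
    per gene; additional genes use the slide-score fast path).
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.site_sizes(rng)
    site_ids = np.repeat([f"S{i:02d}" for i in range(config.n_sites)], sizes)
    n = int(sizes.sum())
    slide_ids = np.array([f"{s}-{j:04d}" for j, s in enumerate(site_ids)])
    if config.slides_per_patient > 1:
        patient_ids = np.array(
            [f"P{j // config.slides_per_patient:04d}" for j in range(n)])
    else:
        patient_ids = slide_ids.copy()

    slides = pd.DataFrame({"slide_id": slide_ids,
                           "patient_id": patient_ids,
                           "site_id": site_ids})

    latents: dict[str, np.ndarray] = {}
    for gene in config.genes:
        labels = (rng.random(n) < gene.prevalence).astype(int)
        mu = auc_to_separation(gene.target_auc)
        lat = _slide_latents(labels, mu, rng)
        slides[LABEL_PREFIX + gene.name] = labels
        slides[SCORE_PREFIX + gene.name] = expit(lat)
        latents[gene.name] = lat

    tiles = None
    if config.tiles_per_slide > 0:
        tiles = _generate_tiles(config, slides, latents[config.genes[0].name], rng)

    meta = {"config": config.to_dict(), "seed": config.seed,
            "tile_gene": config.genes[0].name if config.tiles_per_slide else None}
    return Cohort(slides=slides, tiles=tiles, meta=meta)


def _generate_tiles(config: CohortConfig, slides: pd.DataFrame,
                    latents: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    n = len(slides)
    m = config.tiles_per_slide
    n_signal = max(1, int(round(config.signal_tile_fraction * m)))
    raw = np.full((n, m), np.nan)
    # background tiles sit far below the signal range
    raw[:, n_signal:] = config.background_level + \
        config.tile_jitter * rng.standard_normal((n, m - n_signal))
    raw[:, :n_signal] = latents[:, None] + \
        config.tile_jitter * rng.standard_normal((n, n_signal))

    gene0 = config.genes[0]
    labels = slides[LABEL_PREFIX + gene0.name].to_numpy()
    tiles = pd.DataFrame({
        "slide_id": np.repeat(slides["slide_id"].to_numpy(), m),
        "tile_index": np.tile(np.arange(m), n),
        "score": expit(raw).ravel(),
    })
    if config.feature_dim > 0:
        feats = rng.standard_normal((n * m, config.feature_dim))
        # mutated slides' signal tiles are shifted in feature space
        signal_mask = (np.tile(np.arange(m), n) < n_signal) & \
            np.repeat(labels, m).astype(bool)
        feats[signal_mask, 0] += 3.0
        for d in range(config.feature_dim):
            tiles[f"f{d}"] = feats[:, d]
    return tiles


def generate_slide_scores(cohort: Cohort, gene: str, target_auc: float,
                          seed: int) -> Cohort:
    """Attach fresh binormal slide scores for one gene (fast path).

    Bypasses the tile level entirely: scores are drawn from the calibrated
    binormal latent conditioned on the existing labels, squashed to [0, 1].
    Returns a new cohort; the input is not modified.
    """
    labels = cohort.labels(gene)  # raises KeyError for unknown gene
    mu = auc_to_separation(target_auc)
    rng = np.random.default_rng(seed)
    slides = cohort.slides.copy()
    slides[SCORE_PREFIX + gene] = expit(_slide_latents(labels, mu, rng))
    return Cohort(slides=slides, tiles=cohort.tiles, meta=dict(cohort.meta))


def simulate_null_aucs(n_sets: int, n_replicates: int, n_slides: int,
                       prevalence: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized AUC draws under the null (scores independent of labels).

    Returns an ``(n_sets, n_replicates)`` array of empirical AUCs, each
    computed from ``n_slides`` exchangeable random scores against a fixed
    label vector with ``round(prevalence * n_slides)`` positives.  Used by
    the complete-null calibration simulations of the predictability screen.
    """
    n_pos = int(round(prevalence * n_slides))
    if not (0 < n_pos < n_slides):
        raise ConfigError("prevalence leaves no positives or no negatives")
    n_neg = n_slides - n_pos
    scores = rng.random((n_sets * n_replicates, n_slides))
    ranks = stats.rankdata(scores, axis=1)
    # labels fixed: first n_pos columns positive (scores are exchangeable)
    pos_rank_sum = ranks[:, :n_pos].sum(axis=1)
    auc = (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return auc.reshape(n_sets, n_replicates)
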