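"""Cell-versus-neighbour-median correlation analysis.

The clustering of a fate marker is quantified as the Spearman rank
correlation between a cell's own level and the median level of its
graph neighbours, pooled over the cells of one population at one
stage.  Standard errors come from 100-fold bootstrap resampling of the
cell pairs; significance is assessed against a geometry-preserving
null model that permutes the (NANOG, GATA6) level pairs across the ICM
cell positions of each embryo; correlation strengths are reported in
the verbal bands of Evans (very weak < 0.20 <= weak < 0.40 <= moderate
< 0.60 <= strong < 0.80 <= very strong); and results based on fewer
than 108 cells are flagged unreliable, the population size below which
a subsampling sensitivity analysis shows more than 3% variability of
the coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.stats import mannwhitneyu, spearmanr

from .cellgraph import CellGraph, select_analysis_cells
from .core_io import Cohort, Embryo, Lineage, Stage
from .populations import PopulationLabel, classify_embryo

logger = logging.getLogger(__name__)

RELIABILITY_MIN_CELLS = 108


class Channel(str, Enum):
    NANOG = "NANOG"
    GATA6 = "GATA6"


_ATTR = {Channel.NANOG: "level_nanog", Channel.GATA6: "level_gata6"}


class Strength(str, Enum):
    VERY_WEAK = "very_weak"
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"


@dataclass
class CorrelationResult:
    """One pooled neighbourhood-correlation estimate."""

    focal_population: PopulationLabel
    stage: Stage | None
    channel_self: Channel
    channel_neigh: Channel
    rho: float
    n_cells: int
    bootstrap_se: float
    strength: Strength
    reliable: bool
    null_p_adjusted: float | None = None


def classify_strength(rho: float) -> Strength:
    """Verbal strength band of a correlation coefficient (Evans).

    Bands on |rho|: [0, 0.20) very weak, [0.20, 0.40) weak,
    [0.40, 0.60) moderate, [0.60, 0.80) strong, [0.80, 1.0] very
    strong.  The sign is reported separately by the caller.
    """
    a = abs(rho)
    if a > 1:
        raise ValueError("|rho| must be <= 1")
    if a < 0.20:
        return Strength.VERY_WEAK
    if a < 0.40:
        return Strength.WEAK
    if a < 0.60:
        return Strength.MODERATE
    if a < 0.80:
        return Strength.STRONG
    return Strength.VERY_STRONG


def reliability_gate(n_cells: int, min_cells: int = RELIABILITY_MIN_CELLS) -> bool:
    """True iff the population is large enough for a robust correlation.

    Populations of fewer than 108 cells (default) are flagged
    unreliable; 108 itself passes.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    return n_cells >= min_cells


def neighbour_median(
    cell_id,
    embryo: Embryo,
    graph: CellGraph,
    channel: Channel,
    scope: str = "analysis_set",
    analysis_set: set | None = None,
) -> float | None:
    """Median marker level over a cell's in-scope graph neighbours.

    ``scope`` is ``'analysis_set'`` (ICM plus ICM-adjacent TE; the
    default) or ``'icm_only'``.  Returns None when the cell has no
    in-scope neighbour; such cells are excluded from correlation pairs.
    """
    levels = {n.cell_id: getattr(n, _ATTR[Channel(channel)]) for n in embryo.nuclei}
    lineage = {n.cell_id: n.lineage for n in embryo.nuclei}
    if analysis_set is None:
        analysis_set = select_analysis_cells(embryo, graph)
    neigh = [c for c in graph.neighbors(cell_id) if c in analysis_set]
    if scope == "icm_only":
        neigh = [c for c in neigh if lineage[c] is Lineage.ICM]
    elif scope != "analysis_set":
        raise ValueError(f"unknown scope {scope!r}")
    if not neigh:
        return None
    return float(np.median([levels[c] for c in neigh]))


def collect_pairs(
    cohort: Cohort,
    graphs: dict,
    labels_per_embryo: dict,
    focal_population: PopulationLabel,
    channel_self: Channel,
    channel_neigh: Channel,
    scope: str = "analysis_set",
    stage: Stage | None = None,
) -> np.ndarray:
    """(own level, neighbour median) pairs pooled across embryos.

    Focal cells are the QC-clean ICM cells of ``focal_population`` (or
    all ICM cells when ``focal_population`` is None), restricted to
    ``stage`` when given; cells without an in-scope neighbour are
    dropped with a logged count.  Returns an (n, 2) array.
    """
    pairs = []
    n_dropped = 0
    for embryo in cohort.embryos:
        if stage is not None and embryo.stage is not Stage(stage):
            continue
        graph = graphs[embryo.embryo_id]
        labels = labels_per_embryo[embryo.embryo_id]
        analysis_set = select_analysis_cells(embryo, graph)
        for n in embryo.icm_nuclei():
            cid = n.cell_id
            if cid not in labels:
                continue
            if focal_population is not None and labels[cid] is not focal_population:
                continue
            med = neighbour_median(
                cid, embryo, graph, channel_neigh, scope, analysis_set
            )
            if med is None:
                n_dropped += 1
                continue
            pairs.append((getattr(n, _ATTR[Channel(channel_self)]), med))
    if n_dropped:
        logger.info("dropped %d focal cells without in-scope neighbours", n_dropped)
    return np.array(pairs, dtype=float).reshape(-1, 2)


def spearman_neighbourhood(pairs: np.ndarray) -> tuple[float, int]:
    """Spearman rho (average ranks for ties) over (own, neighbour-median) pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    rho, _ = spearmanr(pairs[:, 0], pairs[:, 1])
    return float(rho), len(pairs)


def bootstrap_rhos(pairs: np.ndarray, reps: int = 100, seed: int = 0) -> np.ndarray:
    """Spearman rho of ``reps`` with-replacement resamples of the pairs."""
    pairs = np.asarray(pairs, dtype=float)
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    rng = np.random.default_rng(seed)
    out = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, len(pairs), size=len(pairs))
        sample = pairs[idx]
        if np.ptp(sample[:, 0]) == 0 or np.ptp(sample[:, 1]) == 0:
            out[r] = 0.0  # degenerate resample carries no rank information
            continue
        rho, _ = spearmanr(sample[:, 0], sample[:, 1])
        out[r] = rho
    return out


def bootstrap_se(pairs: np.ndarray, reps: int = 100, seed: int = 0) -> float:
    """Bootstrap standard error of rho: SD of the replicate coefficients."""
    reps_rho = bootstrap_rhos(pairs, reps=reps, seed=seed)
    return float(reps_rho.std(ddof=1))


def shuffle_embryo_levels(
    embryo: Embryo, rng: np.random.Generator, joint: bool = True
) -> Embryo:
    """Permute marker levels across the embryo's ICM cell positions.

    The (NANOG, GATA6) pair of each ICM cell is reassigned to a
    uniformly random ICM position; TE cells are untouched and the
    geometry (hence the graph) is unchanged.  With ``joint=False`` the
    two channels are permuted independently, breaking the within-cell
    marker relationship.
    """
    out = embryo.copy()
    icm = out.icm_nuclei()
    nanog = np.array([n.level_nanog for n in icm])
    gata6 = np.array([n.level_gata6 for n in icm])
    perm = rng.permutation(len(icm))
    if joint:
        perm2 = perm
    else:
        perm2 = rng.permutation(len(icm))
    for n, i, j in zip(icm, perm, perm2):
        n.level_nanog = float(nanog[i])
        n.level_gata6 = float(gata6[j])
    return out


def shuffle_null(
    cohort: Cohort,
    graphs: dict,
    focal_population: PopulationLabel,
    channel_self: Channel,
    channel_neigh: Channel,
    reps: int = 100,
    seed: int = 0,
    scope: str = "analysis_set",
    stage: Stage | None = None,
    threshold: float = 1.0,
    joint: bool = True,
) -> np.ndarray:
    """Null distribution of the neighbourhood correlation.

    Per replicate, every embryo's ICM level pairs are permuted across
    its ICM positions, population labels are recomputed from the
    permuted levels, and the pooled correlation is recomputed on the
    same graphs.  Returns the replicate rho values (NaN-free; replicates
    with fewer than 3 pairs are skipped).
    """
    rng = np.random.default_rng(seed)
    rhos = []
    for _ in range(reps):
        shuffled = Cohort(
            label=cohort.label,
            embryos=[shuffle_embryo_levels(e, rng, joint) for e in cohort.embryos],
            units_note=cohort.units_note,
        )
        labels = {
            e.embryo_id: classify_embryo(e, threshold) for e in shuffled.embryos
        }
        pairs = collect_pairs(
            shuffled, graphs, labels, focal_population, channel_self,
            channel_neigh, scope, stage,
        )
        if len(pairs) < 3 or np.ptp(pairs[:, 0]) == 0 or np.ptp(pairs[:, 1]) == 0:
            continue
        rho, _ = spearman_neighbourhood(pairs)
        rhos.append(rho)
    return np.array(rhos)


def null_comparison(
    observed_rhos: np.ndarray, null_rhos: np.ndarray, m_comparisons: int = 1
) -> float:
    """Mann-Whitney comparison of bootstrap and null replicate rhos.

    Two-sided p-value, Bonferroni-multiplied by ``m_comparisons`` and
    capped at 1.
    """
    observed_rhos = np.asarray(observed_rhos, dtype=float)
    null_rhos = np.asarray(null_rhos, dtype=float)
    if observed_rhos.size == 0 or null_rhos.size == 0:
        raise ValueError("both samples must be non-empty")
    _, p = mannwhitneyu(observed_rhos, null_rhos, alternative="two-sided")
    return min(1.0, float(p) * m_comparisons)


def correlate_population(
    cohort: Cohort,
    graphs: dict,
    labels_per_embryo: dict,
    focal_population: PopulationLabel,
    channel_self: Channel,
    channel_neigh: Channel,
    stage: Stage | None = None,
    scope: str = "analysis_set",
    bootstrap_reps: int = 100,
    null_reps: int = 100,
    m_comparisons: int = 1,
    seed: int = 0,
    min_cells: int = RELIABILITY_MIN_CELLS,
    threshold: float = 1.0,
) -> CorrelationResult | None:
    """Full correlation analysis for one (population, stage, channel pair).

    Pools pairs across embryos, estimates rho with a bootstrap SE, and
    compares the bootstrap replicates against the shuffle-null
    replicates.  The null comparison is skipped (p left unset) for
    unreliable populations, mirroring the reporting convention that no
    statistics are computed below the reliability gate.  Returns None
    when fewer than 3 pairs exist.
    """
    pairs = collect_pairs(
        cohort, graphs, labels_per_embryo, focal_population,
        channel_self, channel_neigh, scope, stage,
    )
    if len(pairs) < 3:
        logger.info(
            "population %s at stage %s: %d pairs, correlation undefined",
            focal_population, stage, len(pairs),
        )
        return None
    rho, n = spearman_neighbourhood(pairs)
    se = bootstrap_se(pairs, reps=bootstrap_reps, seed=seed)
    reliable = reliability_gate(n, min_cells)
    p_adj = None
    if reliable and null_reps > 0:
        obs = bootstrap_rhos(pairs, reps=bootstrap_reps, seed=seed)
        null = shuffle_null(
            cohort, graphs, focal_population, channel_self, channel_neigh,
            reps=null_reps, seed=seed + 1, scope=scope, stage=stage,
            threshold=threshold,
        )
        if null.size:
            p_adj = null_comparison(obs, null, m_comparisons)
    return CorrelationResult(
        focal_population=focal_population,
        stage=Stage(stage) if stage is not None else None,
        channel_self=Channel(channel_self),
        channel_neigh=Channel(channel_neigh),
        rho=rho,
        n_cells=n,
        bootstrap_se=se,
        strength=classify_strength(rho),
        reliable=reliable,
        null_p_adjusted=p_adj,
    )


def sensitivity_min_n(
    pairs: np.ndarray,
    n_grid: list[int],
    reps: int = 100,
    variability_threshold: float = 0.03,
    seed: int = 0,
) -> int | None:
    """Smallest subsample size with stable correlation estimates.

    For each n in the grid, draws ``reps`` subsamples of the pairs
    without replacement and computes rho; the variability at n is the
    SD of the replicate coefficients.  Returns the smallest n whose
    variability is below the threshold (0.03 by default, i.e. 3% in
    absolute rho units), or None if no grid value qualifies.
    """
    pairs = np.asarray(pairs, dtype=float)
    if not n_grid:
        raise ValueError("n_grid must be non-empty")
    if max(n_grid) > len(pairs):
        raise ValueError("grid exceeds the number of available pairs")
    rng = np.random.default_rng(seed)
    for n in sorted(n_grid):
        rhos = np.empty(reps)
        for r in range(reps):
            idx = rng.choice(len(pairs), size=n, replace=False)
            rho, _ = spearmanr(pairs[idx, 0], pairs[idx, 1])
            rhos[r] = rho
        if rhos.std(ddof=1) < variability_threshold:
            return n
    return None
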