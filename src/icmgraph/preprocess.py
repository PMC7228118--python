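"""Staging, intensity QC, batch alignment and geometric corrections.

Embryos are staged from their total cell number (early: 32-64, mid:
65-90, late: >90 cells).  Batches imaged in separate confocal sessions
are made comparable by dividing each channel by a per-batch positivity
threshold, so that the positive/negative boundary maps to 1.0
everywhere.  Thresholds may be supplied as configuration or derived
automatically by 1-D 2-means clustering of log intensities.  Unmounted
samples may additionally need an exponential correction of fluorescence
decay along the optical axis, and mounted samples a z-rescaling that
undoes squeezing of the embryo by the mounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.cluster import KMeans

from .core_io import Cohort, Embryo, Lineage, QCFlag, Stage

logger = logging.getLogger(__name__)


class ThresholdMethod(str, Enum):
    CONFIG = "config"
    KMEANS = "kmeans"
    KDE_VALLEY = "kde_valley"


@dataclass
class Thresholds:
    """Per-batch positivity thresholds for the two channels (a.u.)."""

    batch_id: str
    thr_nanog: float
    thr_gata6: float
    method: ThresholdMethod = ThresholdMethod.CONFIG

    def __post_init__(self) -> None:
        self.method = ThresholdMethod(self.method)
        for name in ("thr_nanog", "thr_gata6"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite")


def stage_embryo(
    total_cell_count: int, bounds: tuple[int, int, int] = (32, 64, 90)
) -> Stage:
    """Stage an embryo from its total cell number.

    With the default bounds: early for 32-64 cells, mid for 65-90,
    late above 90.  Counts below the early minimum are rejected; such
    embryos are excluded upstream rather than called early.
    """
    early_min, early_max, mid_max = bounds
    if total_cell_count < early_min:
        raise ValueError(
            f"cell count {total_cell_count} below the staging minimum {early_min}"
        )
    if total_cell_count <= early_max:
        return Stage.EARLY
    if total_cell_count <= mid_max:
        return Stage.MID
    return Stage.LATE


def assign_stages(cohort: Cohort, bounds: tuple[int, int, int] = (32, 64, 90)) -> Cohort:
    """Return a copy of the cohort with stages set from cell counts.

    Embryos below the early minimum are dropped (with a log message).
    """
    out = cohort.copy()
    kept = []
    for e in out.embryos:
        try:
            e.stage = stage_embryo(e.total_cell_count, bounds)
        except ValueError:
            logger.info(
                "dropping embryo %s: %d cells is below the staging range",
                e.embryo_id,
                e.total_cell_count,
            )
            continue
        kept.append(e)
    out.embryos = kept
    return out


def filter_intensity_outliers(levels: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Inclusion mask keeping values within ``k`` sample SDs of the mean.

    A value is kept iff ``|value - mean| <= k * SD`` (SD with n-1
    denominator); boundary values are kept.  Used per channel over a
    cohort's ICM cells to drop oversaturated nuclei.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size < 2:
        raise ValueError("need at least two values to define an outlier rule")
    if k <= 0:
        raise ValueError("k must be positive")
    sd = levels.std(ddof=1)
    if sd == 0:
        return np.ones(levels.shape, dtype=bool)
    return np.abs(levels - levels.mean()) <= k * sd


def flag_cohort_outliers(cohort: Cohort, k: float = 2.0) -> Cohort:
    """Flag ICM cells whose NANOG or GATA6 level is a >k-SD outlier.

    Means and SDs are computed per channel over all ICM cells of the
    cohort; a cell flagged in either channel carries the
    ``intensity_outlier`` QC flag and is dropped from downstream
    statistics.
    """
    out = cohort.copy()
    icm = [n for e in out.embryos for n in e.nuclei if n.lineage is Lineage.ICM]
    if len(icm) < 2:
        return out
    for attr in ("level_nanog", "level_gata6"):
        vals = np.array([getattr(n, attr) for n in icm])
        keep = filter_intensity_outliers(vals, k)
        for n, ok in zip(icm, keep):
            if not ok:
                n.qc_flags.add(QCFlag.INTENSITY_OUTLIER)
    n_flagged = sum(1 for n in icm if QCFlag.INTENSITY_OUTLIER in n.qc_flags)
    out.metadata["n_intensity_outliers"] = n_flagged
    return out


def derive_threshold_kmeans(levels: np.ndarray) -> float:
    """Positivity threshold from 1-D 2-means clustering of log levels.

    The two cluster centres are found on log-transformed intensities
    (initialised at the 25th and 75th percentiles, so the result is
    deterministic) and the threshold is the back-transformed midpoint
    of the centres — the geometric mean on the original scale.
    Scaling every level by c > 0 scales the threshold by c.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size < 4:
        raise ValueError("need at least 4 values for a 2-means threshold")
    if np.any(levels <= 0):
        raise ValueError("levels must be strictly positive for the log transform")
    logs = np.log(levels)
    if np.ptp(logs) == 0:
        raise ValueError(
            "all levels identical; supply a configured threshold instead"
        )
    init = np.percentile(logs, [25, 75]).reshape(-1, 1)
    if init[0, 0] == init[1, 0]:  # heavy ties: fall back to extreme seeds
        init = np.array([[logs.min()], [logs.max()]])
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300)
    km.fit(logs.reshape(-1, 1))
    centres = np.sort(km.cluster_centers_.ravel())
    return float(np.exp(centres.mean()))


def derive_cohort_thresholds_kmeans(cohort: Cohort, batch_id: str | None = None) -> list[Thresholds]:
    """Per-batch k-means thresholds from the cohort's ICM cells."""
    batches: dict[str, list] = {}
    for e in cohort.embryos:
        batches.setdefault(e.batch_id, []).extend(
            n for n in e.nuclei if n.lineage is Lineage.ICM and not n.qc_flags
        )
    out = []
    for bid, nuclei in sorted(batches.items()):
        if batch_id is not None and bid != batch_id:
            continue
        nanog = np.array([n.level_nanog for n in nuclei])
        gata6 = np.array([n.level_gata6 for n in nuclei])
        out.append(
            Thresholds(
                batch_id=bid,
                thr_nanog=derive_threshold_kmeans(nanog[nanog > 0]),
                thr_gata6=derive_threshold_kmeans(gata6[gata6 > 0]),
                method=ThresholdMethod.KMEANS,
            )
        )
    return out


def align_batches(cohort: Cohort, thresholds: list[Thresholds]) -> Cohort:
    """Divide each channel by its batch threshold; boundary maps to 1.0.

    Returns a normalized copy; raises if any batch in the cohort lacks
    a threshold entry.
    """
    table = {t.batch_id: t for t in thresholds}
    out = cohort.copy()
    for e in out.embryos:
        if e.batch_id not in table:
            raise ValueError(f"no thresholds supplied for batch {e.batch_id!r}")
        t = table[e.batch_id]
        for n in e.nuclei:
            n.level_nanog = n.level_nanog / t.thr_nanog
            n.level_gata6 = n.level_gata6 / t.thr_gata6
    out.units_note = "normalized"
    return out


def correct_z_decay(embryo: Embryo, model: str = "exponential") -> Embryo:
    """Correct fluorescence decay along the optical (z) axis.

    For ``model='exponential'`` each channel is fitted as
    ``level = a * exp(-z / lambda)`` by least squares on log levels
    across the embryo's nuclei, and each level is divided by
    ``exp(-z / lambda)`` (the amplitude ``a`` is preserved).  A fit
    implying *increase* with depth leaves that channel untouched, with
    a warning.  ``model='none'`` is the identity.
    """
    if model == "none":
        return embryo.copy()
    if model != "exponential":
        raise ValueError(f"unknown z-decay model {model!r}")
    if len(embryo.nuclei) < 10:
        raise ValueError("need at least 10 nuclei to fit a decay model")
    z = np.array([n.position[2] for n in embryo.nuclei])
    if np.ptp(z) == 0:
        raise ValueError("nuclei span a single z value; decay is unidentifiable")
    out = embryo.copy()
    for attr in ("level_nanog", "level_gata6"):
        levels = np.array([getattr(n, attr) for n in out.nuclei])
        pos = levels > 0
        if pos.sum() < 10:
            continue
        slope, _ = np.polyfit(z[pos], np.log(levels[pos]), 1)
        if slope >= 0:
            logger.warning(
                "embryo %s channel %s: fitted z-trend is non-decaying; "
                "no correction applied",
                embryo.embryo_id,
                attr,
            )
            continue
        # level / exp(-z/lambda) with -1/lambda = slope
        for n in out.nuclei:
            setattr(n, attr, getattr(n, attr) * np.exp(-slope * n.position[2]))
    return out


def rescale_positions(embryo: Embryo, z_factor: float = 1.0) -> Embryo:
    """Multiply every z coordinate by ``z_factor`` (x, y untouched).

    Compensates the squeezing of mounted embryos along the optical axis.
    The default of 1.0 applies no rescaling.
    """
    if z_factor <= 0:
        raise ValueError("z_factor must be positive")
    out = embryo.copy()
    for n in out.nuclei:
        n.position[2] *= z_factor
    return out
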