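"""Cell-fate population classification and proportion statistics.

ICM cells are classified from threshold-normalized NANOG and GATA6
levels into four populations: double positive (DP, N+G6+), double
negative (DN, N-G6-), epiblast progenitor (EpiPro, N+G6-) and
primitive-endoderm progenitor (PrEPro, N-G6+).  TE cells are always
labelled TE.  Positivity is strict (level > 1.0 in normalized units);
a cell exactly at threshold counts as negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

from .core_io import Cohort, Embryo, Lineage


class PopulationLabel(str, Enum):
    TE = "TE"
    DN = "DN"
    DP = "DP"
    EPI_PRO = "EpiPro"
    PRE_PRO = "PrEPro"


ICM_LABELS = (
    PopulationLabel.DN,
    PopulationLabel.DP,
    PopulationLabel.EPI_PRO,
    PopulationLabel.PRE_PRO,
)


def classify_cell(
    nanog_norm: float, gata6_norm: float, threshold: float = 1.0
) -> PopulationLabel:
    """Classify an ICM cell from its normalized marker levels.

    N+ iff ``nanog_norm > threshold``; G6+ iff ``gata6_norm >
    threshold`` (strict inequality); the label is the 2x2 combination.
    """
    if nanog_norm < 0 or gata6_norm < 0:
        raise ValueError("normalized levels must be non-negative")
    n_pos = nanog_norm > threshold
    g_pos = gata6_norm > threshold
    if n_pos and g_pos:
        return PopulationLabel.DP
    if n_pos:
        return PopulationLabel.EPI_PRO
    if g_pos:
        return PopulationLabel.PRE_PRO
    return PopulationLabel.DN


def classify_embryo(
    embryo: Embryo, threshold: float = 1.0, drop_flagged: bool = True
) -> dict:
    """Label every cell of an embryo; TE cells are labelled TE.

    Cells carrying QC flags are omitted when ``drop_flagged``.
    Returns a dict cell_id -> PopulationLabel.
    """
    labels = {}
    for n in embryo.nuclei:
        if drop_flagged and n.qc_flags:
            continue
        if n.lineage is Lineage.TE:
            labels[n.cell_id] = PopulationLabel.TE
        else:
            labels[n.cell_id] = classify_cell(n.level_nanog, n.level_gata6, threshold)
    return labels


def classify_cohort(cohort: Cohort, threshold: float = 1.0) -> dict:
    """Labels for every embryo: embryo_id -> {cell_id -> label}."""
    return {e.embryo_id: classify_embryo(e, threshold) for e in cohort.embryos}


def population_proportions(labels_per_embryo: dict) -> dict:
    """Mean ICM population proportions with SEM across embryos.

    ``labels_per_embryo`` maps embryo_id -> {cell_id -> label}.  TE
    labels are ignored; per-embryo proportions over the four ICM labels
    sum to 1 and are averaged across embryos.  SEM is the across-embryo
    standard error (ddof=1), NaN for a single embryo.
    """
    per_embryo: dict[PopulationLabel, list[float]] = {lab: [] for lab in ICM_LABELS}
    for labels in labels_per_embryo.values():
        icm = [lab for lab in labels.values() if lab is not PopulationLabel.TE]
        if not icm:
            continue
        for lab in ICM_LABELS:
            per_embryo[lab].append(sum(1 for x in icm if x is lab) / len(icm))
    if not per_embryo[PopulationLabel.DP]:
        raise ValueError("no ICM cells in any embryo")
    out = {}
    for lab in ICM_LABELS:
        vals = np.array(per_embryo[lab])
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        out[lab] = {"mean": float(vals.mean()), "sem": sem, "n_embryos": len(vals)}
    return out


def pooled_population_counts(labels_per_embryo: dict) -> dict:
    """Pooled ICM label counts across embryos (basis for z-tests)."""
    counts = {lab: 0 for lab in ICM_LABELS}
    for labels in labels_per_embryo.values():
        for lab in labels.values():
            if lab is not PopulationLabel.TE:
                counts[lab] += 1
    return counts


def proportion_ztest(
    count_a: int, n_a: int, count_b: int, n_b: int, m_comparisons: int = 1
) -> float:
    """Two-proportion pooled z-test, Bonferroni-adjusted.

    Two-sided normal p-value from the pooled z statistic, multiplied by
    ``m_comparisons`` and capped at 1.  Identical proportions give p = 1.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= count_a <= n_a and 0 <= count_b <= n_b):
        raise ValueError("counts must lie within their totals")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    if count_a / n_a == count_b / n_b:
        return 1.0
    _, p = proportions_ztest([count_a, count_b], [n_a, n_b], alternative="two-sided")
    return min(1.0, float(p) * m_comparisons)
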