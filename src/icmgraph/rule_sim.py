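"""Two-rule, three-parameter simulator of ICM population composition.

Each ICM cell receives a GATA6 state and a NANOG state from two
independent rules:

* rule 1 — the cell is G6+ with probability ``p_gata6``, else G6-;
* rule 2 — exactly ``round(p_nanog * n)`` cells are N+, chosen in
  ascending order of the distance of their neighbour count to
  ``start_num_neigh`` (nine or close to nine neighbours first), with
  uniform-random tie-breaking among equal distances; all others are N-.

The 2x2 combination of the two states yields the four ICM populations
(DP, DN, epiblast progenitor, PrE progenitor).  The simulator only
consumes per-cell neighbour counts, which may come from measured
embryo geometries or from the synthetic generator.  Setting
``p_nanog = 0`` reproduces the Nanog-null arm: no N+ cells, hence no
DP or epiblast-progenitor cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .populations import ICM_LABELS, PopulationLabel, proportion_ztest

#: Parameter sets used for the published comparisons: proportions of
#: G6+/N+ ICM cells measured in early blastocysts.  The first comes
#: from the large littermate data set, the wild-type arm of the
#: Nanog-mutant comparison from pooled Nanog+/+ and Nanog+/- embryos.
EARLY_BLASTOCYST_PARAMS = {"p_gata6": 0.85, "p_nanog": 0.82, "start_num_neigh": 9}
NANOG_WT_PARAMS = {"p_gata6": 0.94, "p_nanog": 0.78, "start_num_neigh": 9}


@dataclass
class SimulationParams:
    """The three parameters of the two-rule model, plus a seed."""

    p_gata6: float
    p_nanog: float
    start_num_neigh: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_gata6 <= 1 and 0 <= self.p_nanog <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.start_num_neigh < 1:
            raise ValueError("start_num_neigh must be >= 1")


def _n_positive(p: float, n: int) -> int:
    return int(round(p * n))


def simulate_populations(
    icm_degrees: np.ndarray, params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> list[PopulationLabel]:
    """Assign a population label to each ICM cell from its neighbour count.

    Rule 1 draws the G6 state independently per cell; rule 2 marks
    exactly ``round(p_nanog * n)`` cells N+, preferring cells whose
    degree is closest to ``start_num_neigh`` and breaking ties among
    equal distances uniformly at random.  The two rules draw from
    independent seeded streams so either is reproducible on its own.
    """
    degrees = np.asarray(icm_degrees, dtype=int)
    n = len(degrees)
    if n == 0:
        raise ValueError("need at least one cell")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rng_g, rng_n = (
        np.random.default_rng(rng.integers(2**31)),
        np.random.default_rng(rng.integers(2**31)),
    )
    g6_pos = rng_g.random(n) < params.p_gata6
    k = _n_positive(params.p_nanog, n)
    dist = np.abs(degrees - params.start_num_neigh)
    order = np.lexsort((rng_n.random(n), dist))  # distance asc, random within ties
    n_pos = np.zeros(n, dtype=bool)
    n_pos[order[:k]] = True
    labels = []
    for gp, np_ in zip(g6_pos, n_pos):
        if np_ and gp:
            labels.append(PopulationLabel.DP)
        elif np_:
            labels.append(PopulationLabel.EPI_PRO)
        elif gp:
            labels.append(PopulationLabel.PRE_PRO)
        else:
            labels.append(PopulationLabel.DN)
    return labels


def label_proportions(labels: list[PopulationLabel]) -> dict:
    """Proportions of the four ICM labels (sum to 1 exactly)."""
    n = len(labels)
    return {lab: sum(1 for x in labels if x is lab) / n for lab in ICM_LABELS}


def state_fractions(labels: list[PopulationLabel]) -> dict:
    """Realized G6+ and N+ fractions implied by the labels."""
    p = label_proportions(labels)
    return {
        "g6_pos": p[PopulationLabel.DP] + p[PopulationLabel.PRE_PRO],
        "n_pos": p[PopulationLabel.DP] + p[PopulationLabel.EPI_PRO],
    }


def simulate_cohort(
    geometries: dict,
    params: SimulationParams,
    n_reps: int = 200,
    seed: int | None = None,
) -> dict:
    """Replicate the simulation over a set of embryo geometries.

    ``geometries`` maps embryo id -> array of ICM neighbour counts.
    Each replicate runs :func:`simulate_populations` on every embryo;
    proportions are cell-weighted means per replicate, summarised as
    across-replicate means and SEMs.  The realized N+ fraction is
    ``round(p_nanog * n) / n`` per embryo exactly; the realized G6+
    fraction has expectation ``p_gata6``.
    """
    if not geometries:
        raise ValueError("need at least one embryo geometry")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rep_props = {lab: np.empty(n_reps) for lab in ICM_LABELS}
    rep_states = {"g6_pos": np.empty(n_reps), "n_pos": np.empty(n_reps)}
    for r in range(n_reps):
        counts = {lab: 0 for lab in ICM_LABELS}
        total = 0
        for degrees in geometries.values():
            labels = simulate_populations(degrees, params, rng)
            for lab in labels:
                counts[lab] += 1
            total += len(labels)
        for lab in ICM_LABELS:
            rep_props[lab][r] = counts[lab] / total
        rep_states["g6_pos"][r] = (
            counts[PopulationLabel.DP] + counts[PopulationLabel.PRE_PRO]
        ) / total
        rep_states["n_pos"][r] = (
            counts[PopulationLabel.DP] + counts[PopulationLabel.EPI_PRO]
        ) / total
    summary = {
        lab: {
            "mean": float(rep_props[lab].mean()),
            "sem": float(rep_props[lab].std(ddof=1) / np.sqrt(n_reps)),
        }
        for lab in ICM_LABELS
    }
    summary["states"] = {
        k: {"mean": float(v.mean()), "sem": float(v.std(ddof=1) / np.sqrt(n_reps))}
        for k, v in rep_states.items()
    }
    summary["n_reps"] = n_reps
    summary["n_cells"] = int(sum(len(d) for d in geometries.values()))
    return summary


def compare_to_observed(
    simulated_counts: dict, n_simulated: int,
    observed_counts: dict, n_observed: int,
) -> dict:
    """Per-population z-tests of simulated versus observed proportions.

    Two-proportion pooled z-test per ICM population, Bonferroni
    corrected over the four populations.  Counts are pooled cell
    counts; identical compositions give p = 1 everywhere.
    """
    if n_simulated <= 0 or n_observed <= 0:
        raise ValueError("totals must be positive")
    return {
        lab: proportion_ztest(
            simulated_counts.get(lab, 0), n_simulated,
            observed_counts.get(lab, 0), n_observed,
            m_comparisons=len(ICM_LABELS),
        )
        for lab in ICM_LABELS
    }
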