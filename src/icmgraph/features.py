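"""Positional and compositional neighbourhood features.

Local positional feature: a cell's marker level versus its number of
graph neighbours.  Global positional feature: a cell's marker level (or
degree) versus its distance to the ICM centroid, binned in 5 um
intervals — the typical radius of an ICM cell.  Neighbour composition:
for each focal ICM population, the mean proportion of neighbours of
each of the five populations (TE, DN, DP, EpiPro, PrEPro).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .cellgraph import CellGraph
from .core_io import Embryo
from .populations import ICM_LABELS, PopulationLabel, proportion_ztest

ALL_LABELS = (PopulationLabel.TE,) + ICM_LABELS


def icm_centroid(embryo: Embryo) -> np.ndarray:
    """Arithmetic mean of the ICM cell positions (TE cells excluded)."""
    icm = embryo.icm_nuclei()
    if not icm:
        raise ValueError(f"embryo {embryo.embryo_id} has no ICM cells")
    return np.mean([n.position for n in icm], axis=0)


@dataclass
class RadialProfile:
    """Per-bin mean, SEM and count of a scalar versus radial distance.

    Bins are half-open ``[k*w, (k+1)*w)``; a distance d lands in bin
    ``floor(d / w)``.  Bin counts sum to the number of contributing
    cells; empty intermediate bins are reported with n = 0.
    """

    bin_width: float
    bin_edges: np.ndarray  # length n_bins + 1
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    values_per_bin: list  # raw per-cell values, for rank tests

    @property
    def n_bins(self) -> int:
        return len(self.n)


def radial_profile(
    positions: np.ndarray,
    values: np.ndarray,
    centroid: np.ndarray,
    bin_width: float = 5.0,
) -> RadialProfile:
    """Bin a per-cell scalar by distance to a reference point.

    ``values`` may be a marker level or a neighbour count.  SEM uses
    the n-1 standard deviation and is NaN for bins with fewer than two
    cells.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(positions) == 0:
        raise ValueError("need at least one cell")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = np.linalg.norm(positions - np.asarray(centroid, dtype=float), axis=1)
    idx = np.floor(d / bin_width).astype(int)
    n_bins = int(idx.max()) + 1
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    per_bin = [values[idx == b] for b in range(n_bins)]
    for b, vals in enumerate(per_bin):
        counts[b] = len(vals)
        if len(vals) > 0:
            mean[b] = vals.mean()
        if len(vals) > 1:
            sem[b] = vals.std(ddof=1) / np.sqrt(len(vals))
    edges = bin_width * np.arange(n_bins + 1)
    return RadialProfile(
        bin_width=bin_width,
        bin_edges=edges,
        mean=mean,
        sem=sem,
        n=counts,
        values_per_bin=per_bin,
    )


def profile_bin_tests(
    profile: RadialProfile,
    pairs: list[tuple[int, int]] | None = None,
    min_n: int = 2,
) -> dict:
    """Pairwise Mann-Whitney tests between radial bins, Bonferroni-adjusted.

    By default all pairs of populated bins (n >= ``min_n``) are tested
    and the Bonferroni factor is the number of tested pairs.  Bins with
    fewer than ``min_n`` cells are skipped and reported under
    ``'skipped_bins'``.
    """
    populated = [b for b in range(profile.n_bins) if profile.n[b] >= min_n]
    skipped = [b for b in range(profile.n_bins) if 0 < profile.n[b] < min_n]
    if pairs is None:
        pairs = [
            (a, b) for i, a in enumerate(populated) for b in populated[i + 1 :]
        ]
    else:
        pairs = [p for p in pairs if p[0] in populated and p[1] in populated]
    if not pairs:
        return {"p_values": {}, "skipped_bins": skipped, "m": 0}
    m = len(pairs)
    p_values = {}
    for a, b in pairs:
        _, p = mannwhitneyu(
            profile.values_per_bin[a],
            profile.values_per_bin[b],
            alternative="two-sided",
        )
        p_values[(a, b)] = min(1.0, float(p) * m)
    return {"p_values": p_values, "skipped_bins": skipped, "m": m}


def degree_profile(degrees: np.ndarray, values: np.ndarray, min_group_n: int = 1) -> dict:
    """Mean marker level per neighbour count.

    Groups cells by degree and reports per-group mean, SEM (NaN below
    two cells) and n, plus the degree of maximal mean level
    (``argmax_degree``, ties resolved to the smallest degree).  Groups
    with fewer than ``min_group_n`` cells are listed under
    ``'flagged_degrees'`` but still reported.
    """
    degrees = np.asarray(degrees, dtype=int)
    values = np.asarray(values, dtype=float)
    if len(degrees) == 0:
        raise ValueError("need at least one cell")
    groups = {}
    for d in np.unique(degrees):
        vals = values[degrees == d]
        groups[int(d)] = {
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
            "n": int(len(vals)),
        }
    best = max(groups)
    for d in sorted(groups):
        if groups[d]["mean"] > groups[best]["mean"] or (
            groups[d]["mean"] == groups[best]["mean"] and d < best
        ):
            best = d
    return {
        "groups": groups,
        "argmax_degree": best,
        "flagged_degrees": sorted(d for d, g in groups.items() if g["n"] < min_group_n),
    }


def neighbour_composition(
    embryo: Embryo,
    graph: CellGraph,
    labels: dict,
    analysis_set: set,
) -> dict:
    """Neighbour-type composition around each focal ICM population.

    For each focal ICM cell, the proportion of its analysis-set
    neighbours belonging to each of the five populations (each focal
    cell's proportions sum to 1); entries are means over focal cells of
    one population with across-cell SEMs.  Focal cells with zero
    in-set neighbours are excluded and counted.

    Returns ``{focal_label: {'proportions': {label: {'mean','sem'}},
    'n_focal': int, 'per_cell': {label: array}},
    'n_zero_neighbour': int}``.
    """
    index = {cid: i for i, cid in enumerate(graph.node_ids)}
    sub_idx = {index[cid] for cid in analysis_set if cid in index}
    per_focal: dict[PopulationLabel, dict[PopulationLabel, list]] = {
        lab: {t: [] for t in ALL_LABELS} for lab in ICM_LABELS
    }
    n_zero = 0
    for n in embryo.icm_nuclei():
        cid = n.cell_id
        if cid not in labels or cid not in analysis_set:
            continue
        focal = labels[cid]
        if focal not in ICM_LABELS:
            continue
        neigh = [
            graph.node_ids[j]
            for j in graph.neighbor_indices(index[cid])
            if j in sub_idx and graph.node_ids[j] in labels
        ]
        if not neigh:
            n_zero += 1
            continue
        for t in ALL_LABELS:
            per_focal[focal][t].append(
                sum(1 for c in neigh if labels[c] is t) / len(neigh)
            )
    result = {"n_zero_neighbour": n_zero}
    for focal in ICM_LABELS:
        arrs = {t: np.array(v) for t, v in per_focal[focal].items()}
        n_focal = len(arrs[PopulationLabel.TE])
        props = {}
        for t, a in arrs.items():
            props[t] = {
                "mean": float(a.mean()) if n_focal else float("nan"),
                "sem": float(a.std(ddof=1) / np.sqrt(n_focal)) if n_focal > 1 else float("nan"),
            }
        result[focal] = {"proportions": props, "n_focal": n_focal, "per_cell": arrs}
    return result


def composition_tests(
    neighbour_counts: dict, m_comparisons: int | None = None
) -> dict:
    """Pairwise neighbour-type z-tests for one focal population.

    ``neighbour_counts`` maps neighbour label -> pooled count of
    neighbours of that type over all focal cells; the total pool size
    is their sum.  Each pair of neighbour types is compared by a
    two-proportion z-test on the pooled counts, Bonferroni-corrected
    over all tested pairs (or an explicit ``m_comparisons``).
    """
    total = sum(neighbour_counts.values())
    if total == 0:
        raise ValueError("empty neighbour pool")
    types = sorted(neighbour_counts, key=str)
    pairs = [(a, b) for i, a in enumerate(types) for b in types[i + 1 :]]
    m = m_comparisons if m_comparisons is not None else len(pairs)
    return {
        (a, b): proportion_ztest(
            neighbour_counts[a], total, neighbour_counts[b], total, m
        )
        for a, b in pairs
    }
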