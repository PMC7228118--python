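"""Synthetic blastocyst generator.

Produces embryos with the statistical structure the analysis pipeline
assumes, so that every stage — ingestion, graph construction,
classification, neighbourhood correlation, positional profiling and
the rule-based simulation — can be exercised and validated without any
experimental data:

* geometry: TE nuclei dart-thrown onto a spherical shell, ICM nuclei
  packed into a spherical cap attached to one pole interior (the rest
  of the cavity, the blastocoele, stays empty), with a minimum
  nucleus-to-nucleus spacing;
* NANOG: assigned after graph construction as a Gaussian bump in the
  cell's neighbour count, peaked at nine neighbours by default — the
  local positional pattern;
* GATA6: baseline plus a draw from a Gaussian random field with
  squared-exponential covariance over the ICM positions — short-range
  spatial correlation producing expression-level clusters;
* late stage only: opposing radial trends (NANOG high centrally,
  GATA6 high peripherally) emulating the sorted configuration.

All pattern parameters are recorded in the cohort metadata as ground
truth for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .cellgraph import build_embryo_graph, select_analysis_cells, subgraph_degrees
from .core_io import Cohort, Embryo, Lineage, NucleusRecord, Stage
from .preprocess import Thresholds, stage_embryo

logger = logging.getLogger(__name__)


def reference_thresholds(batch_id: str = "batch_0") -> Thresholds:
    """Positivity thresholds matched to the generator defaults.

    Calibrated so that early synthetic cohorts reproduce the measured
    positive-state fractions of early blastocysts (about 85% G6+ and
    82% N+ ICM cells): with the default expression parameters the
    NANOG threshold sits below the bump baseline-plus-signal mass and
    the GATA6 threshold in the lower tail of the centred field.
    """
    return Thresholds(batch_id=batch_id, thr_nanog=60.0, thr_gata6=25.0)

#: Cell counts per stage: total counts fall in the staging windows
#: 32-64 (early), 65-90 (mid), >90 (late); the ICM makes up roughly
#: 40% of the embryo at the early stage and proportionally less later.
STAGE_CELL_COUNTS = {
    Stage.EARLY: {"n_te": 30, "n_icm": 20},
    Stage.MID: {"n_te": 50, "n_icm": 28},
    Stage.LATE: {"n_te": 70, "n_icm": 35},
}


@dataclass
class SyntheticEmbryoConfig:
    """Geometry and expression-pattern parameters for one embryo.

    Units: micrometres for lengths, arbitrary fluorescence units for
    levels.  ``nanog_peak_degree``/``nanog_peak_width`` shape the
    neighbour-count bump; ``gata6_corr_length`` sets the spatial
    correlation range of the GATA6 field (about three cell radii by
    default).  The late-stage radial slopes are in a.u. per um and are
    applied only to late-stage embryos.
    """

    stage: Stage = Stage.EARLY
    n_te: int | None = None
    n_icm: int | None = None
    embryo_radius: float = 40.0
    cell_spacing_min: float = 8.0
    cap_half_angle_deg: float = 70.0
    nanog_peak_degree: int = 9
    nanog_peak_width: float = 2.5
    nanog_amplitude: float = 70.0
    nanog_baseline: float = 30.0
    nanog_noise_sd: float = 10.0
    gata6_corr_length: float = 15.0
    gata6_field_sd: float = 40.0
    gata6_baseline: float = 60.0
    gata6_noise_sd: float = 5.0
    late_radial_slope_nanog: float = -1.5
    late_radial_slope_gata6: float = 1.5
    graph_edge_cutoff: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        counts = STAGE_CELL_COUNTS[self.stage]
        if self.n_te is None:
            self.n_te = counts["n_te"]
        if self.n_icm is None:
            self.n_icm = counts["n_icm"]
        if self.cell_spacing_min <= 0 or self.gata6_corr_length <= 0:
            raise ValueError("spacing and correlation length must be positive")
        if self.late_radial_slope_nanog > 0 or self.late_radial_slope_gata6 < 0:
            raise ValueError(
                "late radial slopes must be <= 0 for NANOG and >= 0 for GATA6"
            )
        total = self.n_te + self.n_icm
        expected = stage_embryo(total)
        if expected is not self.stage:
            raise ValueError(
                f"{total} cells stages as {expected.value!r}, not {self.stage.value!r}"
            )


# ---------------------------------------------------------------------------
# Geometry


def _dart_throw(
    n: int,
    sampler,
    spacing: float,
    rng: np.random.Generator,
    existing: np.ndarray | None = None,
    max_tries_per_point: int = 500,
) -> np.ndarray:
    """Sequentially accept sampled points at least ``spacing`` apart."""
    accepted: list[np.ndarray] = []
    anchors = [] if existing is None else list(existing)
    for _ in range(n):
        for _ in range(max_tries_per_point):
            p = sampler(rng)
            others = accepted + anchors
            if not others or np.min(
                np.linalg.norm(np.asarray(others) - p, axis=1)
            ) >= spacing:
                accepted.append(p)
                break
        else:
            raise RuntimeError(
                "packing failed: could not place all nuclei at the requested "
                "spacing; lower the density (fewer cells, larger radius or "
                "smaller cell_spacing_min)"
            )
    return np.asarray(accepted)


def _sample_shell(radius: float):
    def sampler(rng: np.random.Generator) -> np.ndarray:
        v = rng.normal(size=3)
        return radius * v / np.linalg.norm(v)

    return sampler


def _sample_cap(radius: float, half_angle_rad: float, spacing: float):
    """Uniform sampler over the interior spherical-cap region."""
    r_out = radius - spacing / 2.0
    r_in = 0.35 * radius
    cos_min = np.cos(half_angle_rad)

    def sampler(rng: np.random.Generator) -> np.ndarray:
        r = (r_in**3 + (r_out**3 - r_in**3) * rng.random()) ** (1.0 / 3.0)
        cos_t = cos_min + (1 - cos_min) * rng.random()
        sin_t = np.sqrt(1 - cos_t**2)
        phi = 2 * np.pi * rng.random()
        return r * np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])

    return sampler


def sample_icm_ball(
    n: int, spacing: float = 8.0, seed: int = 0, packing_fraction: float = 0.2
) -> np.ndarray:
    """Pack ``n`` points in a ball at minimum spacing (isolated-ICM geometry).

    The ball radius is chosen from ``n`` and the packing fraction, so
    arbitrary ICM sizes can be generated for the rule-based simulator.
    """
    # non-overlapping spheres of radius spacing/2 at the given fill
    vol = n * (4.0 / 3.0) * np.pi * (spacing / 2) ** 3 / packing_fraction
    radius = (3 * vol / (4 * np.pi)) ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)

    def sampler(r: np.random.Generator) -> np.ndarray:
        while True:
            p = radius * (2 * r.random(3) - 1)
            if np.linalg.norm(p) <= radius:
                return p

    return _dart_throw(n, sampler, spacing, rng)


# ---------------------------------------------------------------------------
# Expression patterns


def _gaussian_random_field(
    positions: np.ndarray, corr_length: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean GRF with squared-exponential covariance, exact factorization."""
    d2 = np.sum(
        (positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1
    )
    cov = sd**2 * np.exp(-d2 / (2 * corr_length**2))
    cov[np.diag_indices_from(cov)] += 1e-8 * max(sd**2, 1.0)
    chol = np.linalg.cholesky(cov)
    draw = chol @ rng.normal(size=len(positions))
    # centre per embryo: the planted phenomenon is local clustering, not
    # embryo-to-embryo brightness variation (which batch alignment removes)
    return draw - draw.mean()


def generate_embryo(
    config: SyntheticEmbryoConfig, embryo_id: str = "synth_0", batch_id: str = "batch_0"
) -> Embryo:
    """Generate one synthetic embryo (fully seeded, bit-reproducible)."""
    rng = np.random.default_rng(config.seed)
    te_pos = _dart_throw(
        config.n_te,
        _sample_shell(config.embryo_radius),
        config.cell_spacing_min,
        rng,
    )
    icm_pos = _dart_throw(
        config.n_icm,
        _sample_cap(
            config.embryo_radius,
            np.deg2rad(config.cap_half_angle_deg),
            config.cell_spacing_min,
        ),
        config.cell_spacing_min,
        rng,
        existing=te_pos,
    )

    nuclei = []
    for i, p in enumerate(te_pos):
        nuclei.append(
            NucleusRecord(
                embryo_id=embryo_id,
                cell_id=f"te_{i}",
                position=p,
                lineage=Lineage.TE,
                level_nanog=0.0,
                level_gata6=0.0,
            )
        )
    for i, p in enumerate(icm_pos):
        nuclei.append(
            NucleusRecord(
                embryo_id=embryo_id,
                cell_id=f"icm_{i}",
                position=p,
                lineage=Lineage.ICM,
                level_nanog=0.0,
                level_gata6=0.0,
            )
        )
    embryo = Embryo(
        embryo_id=embryo_id, nuclei=nuclei, batch_id=batch_id, stage=config.stage
    )

    # NANOG depends on the graph: degree within the analysis subgraph
    graph = build_embryo_graph(embryo, config.graph_edge_cutoff)
    analysis = select_analysis_cells(embryo, graph)
    degrees = subgraph_degrees(graph, analysis)

    icm = embryo.icm_nuclei()
    icm_positions = np.array([n.position for n in icm])
    centroid = icm_positions.mean(axis=0)
    radial = np.linalg.norm(icm_positions - centroid, axis=1)
    # GATA6 is expressed in TE as well, so the spatially correlated field
    # covers every nucleus; ICM and TE differ only in baseline.
    all_positions = embryo.positions()
    field = _gaussian_random_field(
        all_positions, config.gata6_corr_length, config.gata6_field_sd, rng
    )
    field_by_id = {n.cell_id: field[j] for j, n in enumerate(embryo.nuclei)}
    late = config.stage is Stage.LATE
    for j, n in enumerate(icm):
        deg = degrees[n.cell_id]
        nanog = (
            config.nanog_baseline
            + config.nanog_amplitude
            * np.exp(
                -((deg - config.nanog_peak_degree) ** 2)
                / (2 * config.nanog_peak_width**2)
            )
            + rng.normal(0, config.nanog_noise_sd)
        )
        gata6 = (
            config.gata6_baseline
            + field_by_id[n.cell_id]
            + rng.normal(0, config.gata6_noise_sd)
        )
        if late:
            nanog += config.late_radial_slope_nanog * radial[j]
            gata6 += config.late_radial_slope_gata6 * radial[j]
        n.level_nanog = max(0.0, float(nanog))
        n.level_gata6 = max(0.0, float(gata6))
    for n in embryo.te_nuclei():
        n.level_nanog = max(
            0.0, float(rng.normal(config.nanog_baseline / 2, config.nanog_noise_sd))
        )
        n.level_gata6 = max(
            0.0,
            float(
                config.gata6_baseline / 2
                + field_by_id[n.cell_id]
                + rng.normal(0, config.gata6_noise_sd)
            ),
        )
    return embryo


def generate_cohort(
    stage_mix: dict,
    seed: int = 0,
    label: str = "synthetic",
    batch_id: str = "batch_0",
    **overrides,
) -> Cohort:
    """Generate a cohort of independent embryos.

    ``stage_mix`` maps stage -> number of embryos; per-embryo seeds are
    spawned from ``seed`` so embryos are independent and the whole
    cohort is reproducible.  Keyword overrides are applied to every
    embryo's :class:`SyntheticEmbryoConfig`.  The generating parameters
    are stored in ``cohort.metadata['ground_truth']``.
    """
    ss = np.random.SeedSequence(seed)
    total = sum(int(v) for v in stage_mix.values())
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(max(total, 1))]
    embryos = []
    configs = {}
    k = 0
    for stage, count in stage_mix.items():
        stage = Stage(stage)
        for _ in range(int(count)):
            cfg = SyntheticEmbryoConfig(stage=stage, seed=child_seeds[k], **overrides)
            eid = f"synth_{stage.value}_{k}"
            embryos.append(generate_embryo(cfg, embryo_id=eid, batch_id=batch_id))
            configs[eid] = {
                key: (v.value if isinstance(v, Stage) else v)
                for key, v in asdict(cfg).items()
            }
            k += 1
    return Cohort(
        label=label,
        embryos=embryos,
        units_note="raw",
        metadata={"ground_truth": configs, "seed": seed},
    )
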