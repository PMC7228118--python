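"""Data model and I/O for segmented-nucleus tables and processed cohorts.

The pipeline consumes tables of segmented nuclei, one row per nucleus,
as produced by nuclear-segmentation tools such as MINS: a 3D centroid,
a trophectoderm (TE) / inner-cell-mass (ICM) lineage call and the mean
immunofluorescence intensity of the two fate markers NANOG and GATA6.
Cohorts of embryos are persisted as versioned JSON documents so that
every downstream stage can be run from plain files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Default mapping of semantic fields to the column names of a MINS-style
#: export.  Column headers vary between segmentation-tool versions, so the
#: mapping is configuration, not a constant the reader hard-codes.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "embryo_id": "embryo_id",
    "cell_id": "cell_id",
    "x": "x",
    "y": "y",
    "z": "z",
    "lineage": "lineage",
    "level_nanog": "level_nanog",
    "level_gata6": "level_gata6",
    "volume": "volume",
}

REQUIRED_FIELDS = (
    "embryo_id",
    "cell_id",
    "x",
    "y",
    "z",
    "lineage",
    "level_nanog",
    "level_gata6",
)


class Lineage(str, Enum):
    TE = "TE"
    ICM = "ICM"


class Genotype(str, Enum):
    WILD_TYPE = "wild_type"
    NANOG_HET = "nanog_het"
    NANOG_NULL = "nanog_null"
    OTHER = "other"


class Stage(str, Enum):
    EARLY = "early"
    MID = "mid"
    LATE = "late"


class QCFlag(str, Enum):
    INTENSITY_OUTLIER = "intensity_outlier"
    SEGMENTATION_ARTIFACT = "segmentation_artifact"


@dataclass
class NucleusRecord:
    """One segmented nucleus.

    Parameters
    ----------
    embryo_id : str
        Identifier of the embryo the nucleus belongs to.
    cell_id : str
        Identifier unique within the embryo.
    position : ndarray, shape (3,)
        Nuclear centroid in micrometres.
    lineage : Lineage
        TE or ICM, from the (manually curated) segmentation output.
    level_nanog, level_gata6 : float
        Mean nuclear fluorescence intensities in arbitrary units; finite
        and non-negative.
    volume : float or None
        Nuclear volume in cubic micrometres, if exported.
    qc_flags : set of QCFlag
        Quality-control annotations accumulated during preprocessing.
    """

    embryo_id: str
    cell_id: str
    position: np.ndarray
    lineage: Lineage
    level_nanog: float
    level_gata6: float
    volume: float | None = None
    qc_flags: set[QCFlag] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(
                f"position of {self.embryo_id}/{self.cell_id} must be a 3-vector"
            )
        if not np.all(np.isfinite(self.position)):
            raise ValueError(
                f"non-finite position for {self.embryo_id}/{self.cell_id}"
            )
        self.lineage = Lineage(self.lineage)
        for name in ("level_nanog", "level_gata6"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"{name} of {self.embryo_id}/{self.cell_id} must be finite and >= 0"
                )
        if self.volume is not None and self.volume < 0:
            raise ValueError(
                f"volume of {self.embryo_id}/{self.cell_id} must be non-negative"
            )
        self.qc_flags = {QCFlag(f) for f in self.qc_flags}

    def copy(self) -> "NucleusRecord":
        return replace(
            self, position=self.position.copy(), qc_flags=set(self.qc_flags)
        )


@dataclass
class Embryo:
    """An embryo: its nuclei plus acquisition/genotype metadata."""

    embryo_id: str
    nuclei: list[NucleusRecord]
    batch_id: str = "batch_0"
    genotype: Genotype = Genotype.WILD_TYPE
    treatment: str = "control"
    stage: Stage | None = None

    def __post_init__(self) -> None:
        self.genotype = Genotype(self.genotype)
        if self.stage is not None:
            self.stage = Stage(self.stage)
        ids = [n.cell_id for n in self.nuclei]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate cell_id {dup!r} in embryo {self.embryo_id}")
        for n in self.nuclei:
            if n.embryo_id != self.embryo_id:
                raise ValueError(
                    f"nucleus {n.cell_id} carries embryo_id {n.embryo_id!r}, "
                    f"expected {self.embryo_id!r}"
                )

    @property
    def total_cell_count(self) -> int:
        return len(self.nuclei)

    def icm_nuclei(self) -> list[NucleusRecord]:
        return [n for n in self.nuclei if n.lineage is Lineage.ICM]

    def te_nuclei(self) -> list[NucleusRecord]:
        return [n for n in self.nuclei if n.lineage is Lineage.TE]

    def positions(self) -> np.ndarray:
        return np.array([n.position for n in self.nuclei], dtype=float)

    def copy(self) -> "Embryo":
        return Embryo(
            embryo_id=self.embryo_id,
            nuclei=[n.copy() for n in self.nuclei],
            batch_id=self.batch_id,
            genotype=self.genotype,
            treatment=self.treatment,
            stage=self.stage,
        )


@dataclass
class Cohort:
    """A labelled collection of embryos sharing one intensity convention.

    ``units_note`` records whether marker levels are raw arbitrary units
    or have been divided by their batch positivity thresholds
    (``normalized``), in which case the positive/negative boundary for
    both channels sits at 1.0.
    """

    label: str
    embryos: list[Embryo]
    units_note: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.units_note not in ("raw", "normalized"):
            raise ValueError("units_note must be 'raw' or 'normalized'")
        ids = [e.embryo_id for e in self.embryos]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate embryo_id {dup!r} in cohort {self.label}")

    def __iter__(self):
        return iter(self.embryos)

    def __len__(self) -> int:
        return len(self.embryos)

    def copy(self) -> "Cohort":
        return Cohort(
            label=self.label,
            embryos=[e.copy() for e in self.embryos],
            units_note=self.units_note,
            metadata=dict(self.metadata),
        )


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Defaults follow the published analysis conventions: a 30 um edge
    cutoff for the cell graph, 5 um radial bins (the typical ICM-cell
    radius), stage bounds 32-64 / 65-90 / >90 cells, a 2-SD intensity
    outlier rule, 100 bootstrap and null replicates, and a 108-cell
    reliability gate at 3% correlation variability.
    """

    graph_edge_cutoff: float = 30.0
    radial_bin_width: float = 5.0
    stage_bounds: tuple[int, int, int] = (32, 64, 90)  # early_min, early_max, mid_max
    outlier_sd_multiplier: float = 2.0
    bootstrap_reps: int = 100
    null_reps: int = 100
    reliability_min_cells: int = 108
    sensitivity_variability_threshold: float = 0.03
    rng_seed: int = 0

    def __post_init__(self) -> None:
        early_min, early_max, mid_max = self.stage_bounds
        if not (0 < early_min <= early_max < mid_max):
            raise ValueError("stage bounds must satisfy early_min <= early_max < mid_max")
        for name in (
            "graph_edge_cutoff",
            "radial_bin_width",
            "outlier_sd_multiplier",
            "bootstrap_reps",
            "null_reps",
            "reliability_min_cells",
            "sensitivity_variability_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# CSV ingestion


def read_nucleus_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    unit_scale: Sequence[float] = (1.0, 1.0, 1.0),
    label: str = "cohort",
    strict: bool = False,
) -> Cohort:
    """Read a segmentation table (CSV, one row per nucleus) into a Cohort.

    Parameters
    ----------
    path : path
        UTF-8 CSV with a header row.
    column_map : mapping
        Semantic field -> column name.  Defaults to
        :data:`DEFAULT_COLUMN_MAP`.  ``volume`` is optional.
    unit_scale : sequence of 3 floats
        Micrometres per coordinate unit along x, y, z.  Raw voxel-unit
        exports require an explicit scale; there is no silent default
        other than identity.
    strict : bool
        If True, invalid rows abort the read instead of being excluded.

    Returns
    -------
    Cohort
        Embryos grouped by ``embryo_id``; rows with non-finite or
        negative intensities are excluded (counted in
        ``cohort.metadata['n_excluded']``) unless ``strict``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    for fld in REQUIRED_FIELDS:
        if fld not in cmap:
            raise ValueError(f"column_map is missing required semantic field {fld!r}")
    scale = np.asarray(unit_scale, dtype=float)
    if scale.shape != (3,) or np.any(scale <= 0):
        raise ValueError("unit_scale must be three positive factors")

    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    missing = [c for f, c in cmap.items() if c not in df.columns and f != "volume"]
    if missing:
        raise ValueError(f"mapped columns not present in {path.name}: {missing}")
    has_volume = "volume" in cmap and cmap["volume"] in df.columns

    lineage_raw = df[cmap["lineage"]].astype(str).str.strip().str.upper()
    bad_lineage = sorted(set(lineage_raw) - {"TE", "ICM"})
    if bad_lineage:
        raise ValueError(f"unknown lineage labels: {bad_lineage}")

    n_excluded = 0
    by_embryo: dict[str, list[NucleusRecord]] = {}
    for i, row in df.iterrows():
        nanog = float(row[cmap["level_nanog"]])
        gata6 = float(row[cmap["level_gata6"]])
        ok = np.isfinite(nanog) and np.isfinite(gata6) and nanog >= 0 and gata6 >= 0
        if not ok:
            if strict:
                raise ValueError(f"invalid intensity in row {i} of {path.name}")
            n_excluded += 1
            continue
        pos = scale * np.array(
            [row[cmap["x"]], row[cmap["y"]], row[cmap["z"]]], dtype=float
        )
        rec = NucleusRecord(
            embryo_id=str(row[cmap["embryo_id"]]),
            cell_id=str(row[cmap["cell_id"]]),
            position=pos,
            lineage=Lineage(lineage_raw.loc[i]),
            level_nanog=nanog,
            level_gata6=gata6,
            volume=float(row[cmap["volume"]]) if has_volume else None,
        )
        by_embryo.setdefault(rec.embryo_id, []).append(rec)
    if n_excluded:
        logger.info("excluded %d invalid rows while reading %s", n_excluded, path.name)
    embryos = [Embryo(embryo_id=eid, nuclei=recs) for eid, recs in by_embryo.items()]
    return Cohort(
        label=label,
        embryos=embryos,
        units_note="raw",
        metadata={"n_excluded": n_excluded, "n_rows": int(len(df))},
    )


# ---------------------------------------------------------------------------
# Processed-cohort JSON


def _nucleus_to_dict(n: NucleusRecord) -> dict:
    d = {
        "cell_id": n.cell_id,
        "position": [float(v) for v in n.position],
        "lineage": n.lineage.value,
        "level_nanog": float(n.level_nanog),
        "level_gata6": float(n.level_gata6),
        "qc_flags": sorted(f.value for f in n.qc_flags),
    }
    if n.volume is not None:
        d["volume"] = float(n.volume)
    return d


def write_processed(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as a versioned JSON document (see ``read_processed``)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "label": cohort.label,
        "units_note": cohort.units_note,
        "metadata": cohort.metadata,
        "embryos": [
            {
                "embryo_id": e.embryo_id,
                "batch_id": e.batch_id,
                "genotype": e.genotype.value,
                "treatment": e.treatment,
                "stage": e.stage.value if e.stage is not None else None,
                "nuclei": [_nucleus_to_dict(n) for n in e.nuclei],
            }
            for e in cohort.embryos
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_processed(
    path: str | Path, stage_bounds: tuple[int, int, int] = (32, 64, 90)
) -> Cohort:
    """Load a cohort written by :func:`write_processed`, validating invariants.

    Raises on schema-version mismatch, duplicated (embryo_id, cell_id)
    and stage labels inconsistent with the cell-count staging rule.
    """
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"schema_version {version!r} not supported (expected {SCHEMA_VERSION!r})"
        )
    from .preprocess import stage_embryo  # local import to avoid a cycle

    embryos = []
    for ed in doc["embryos"]:
        nuclei = [
            NucleusRecord(
                embryo_id=ed["embryo_id"],
                cell_id=nd["cell_id"],
                position=np.array(nd["position"], dtype=float),
                lineage=Lineage(nd["lineage"]),
                level_nanog=nd["level_nanog"],
                level_gata6=nd["level_gata6"],
                volume=nd.get("volume"),
                qc_flags={QCFlag(f) for f in nd.get("qc_flags", [])},
            )
            for nd in ed["nuclei"]
        ]
        stage = ed.get("stage")
        embryo = Embryo(
            embryo_id=ed["embryo_id"],
            nuclei=nuclei,
            batch_id=ed.get("batch_id", "batch_0"),
            genotype=Genotype(ed.get("genotype", "wild_type")),
            treatment=ed.get("treatment", "control"),
            stage=Stage(stage) if stage is not None else None,
        )
        if embryo.stage is not None:
            expected = stage_embryo(embryo.total_cell_count, stage_bounds)
            if expected is not embryo.stage:
                raise ValueError(
                    f"embryo {embryo.embryo_id}: stored stage {embryo.stage.value!r} "
                    f"inconsistent with the cell-count staging rule "
                    f"({embryo.total_cell_count} cells -> {expected.value!r})"
                )
        embryos.append(embryo)
    return Cohort(
        label=doc["label"],
        embryos=embryos,
        units_note=doc.get("units_note", "raw"),
        metadata=doc.get("metadata", {}),
    )


def cohorts_equal(a: Cohort, b: Cohort) -> bool:
    """Field-for-field equality of two cohorts (positions to float precision)."""
    if (a.label, a.units_note, len(a.embryos)) != (b.label, b.units_note, len(b.embryos)):
        return False
    for ea, eb in zip(a.embryos, b.embryos):
        if (
            ea.embryo_id != eb.embryo_id
            or ea.batch_id != eb.batch_id
            or ea.genotype != eb.genotype
            or ea.treatment != eb.treatment
            or ea.stage != eb.stage
            or len(ea.nuclei) != len(eb.nuclei)
        ):
            return False
        for na, nb in zip(ea.nuclei, eb.nuclei):
            if (
                na.cell_id != nb.cell_id
                or na.lineage != nb.lineage
                or na.qc_flags != nb.qc_flags
                or not np.allclose(na.position, nb.position)
                or not np.isclose(na.level_nanog, nb.level_nanog)
                or not np.isclose(na.level_gata6, nb.level_gata6)
                or (na.volume is None) != (nb.volume is None)
                or (na.volume is not None and not np.isclose(na.volume, nb.volume))
            ):
                return False
    return True
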