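import numpy as np
import pytest

import icmgraph as ig


@pytest.fixture(scope="session")
def early_cohort():
    """Small synthetic early-stage cohort with default pattern parameters."""
    return ig.generate_cohort({"early": 10}, seed=101)


@pytest.fixture(scope="session")
def normalized_cohort(early_cohort):
    return ig.align_batches(early_cohort, [ig.reference_thresholds()])


@pytest.fixture(scope="session")
def graphs(normalized_cohort):
    return {e.embryo_id: ig.build_embryo_graph(e) for e in normalized_cohort}


@pytest.fixture(scope="session")
def labels(normalized_cohort):
    return ig.classify_cohort(normalized_cohort)


def make_embryo(positions, lineages, nanog=None, gata6=None, embryo_id="e1",
                stage=None):
    """Hand-built embryo for toy geometries."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    nanog = np.ones(n) if nanog is None else np.asarray(nanog, dtype=float)
    gata6 = np.ones(n) if gata6 is None else np.asarray(gata6, dtype=float)
    nuclei = [
        ig.NucleusRecord(
            embryo_id=embryo_id,
            cell_id=f"c{i}",
            position=positions[i],
            lineage=lineages[i],
            level_nanog=float(nanog[i]),
            level_gata6=float(gata6[i]),
        )
        for i in range(n)
    ]
    return ig.Embryo(embryo_id=embryo_id, nuclei=nuclei, stage=stage)
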