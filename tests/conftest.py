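import numpy as np
import pandas as pd
import pytest

from cerebstat.core import CellAnnotation, ExpressionMatrix, NormalizedMatrix
from cerebstat.simulate import AtlasSimConfig, ClusterSpec, simulate_atlas

N_REGIONS = 16
UNIFORM = tuple(np.full(N_REGIONS, 1.0 / N_REGIONS))


def enriched_composition(target_frac: float = 0.3, region: int = 0) -> tuple:
    comp = np.full(N_REGIONS, (1.0 - target_frac) / (N_REGIONS - 1))
    comp[region] = target_frac
    return tuple(comp)


@pytest.fixture
def tiny_counts():
    """3 genes x 2 cells toy count matrix."""
    return ExpressionMatrix(
        np.array([[0, 1], [2, 0], [5, 3]]),
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["c1", "c2"],
    )


@pytest.fixture
def region_toy():
    """4 genes x 4 cells, one cell per region, for logVMR hand checks."""
    values = np.array([
        [1.0, 2.0, 3.0, 4.0],   # region means 1,2,3,4
        [2.0, 2.0, 2.0, 2.0],   # equal nonzero means -> zero variance
        [0.0, 0.0, 0.0, 0.0],   # all-zero gene
        [1.0, 5.0, 1.0, 5.0],
    ])
    mat = NormalizedMatrix(values, [f"g{i}" for i in range(4)],
                           [f"c{i}" for i in range(4)])
    labels = np.array(["r1", "r2", "r3", "r4"])
    return mat, labels


@pytest.fixture(scope="session")
def small_atlas():
    """One enriched + one uniform granule cluster and one uniform MLI cluster."""
    cfg = AtlasSimConfig(
        n_genes=40,
        clusters=[
            ClusterSpec("granule_enr", "granule", 2000, enriched_composition()),
            ClusterSpec("granule_uni", "granule", 8000, UNIFORM),
            ClusterSpec("mli_uni", "MLI", 2000, UNIFORM),
        ],
        seed=11,
    )
    return simulate_atlas(cfg)


def annotation_from_counts(count_rows: dict, outer: dict, replicate: str = "rep_1"):
    """Expand {cluster: {lobule: n}} into an explicit CellAnnotation."""
    rows = []
    i = 0
    for cluster, lobs in count_rows.items():
        for lobule, n in lobs.items():
            for _ in range(n):
                rows.append((f"cell_{i:06d}", cluster, outer[cluster], lobule, replicate))
                i += 1
    return CellAnnotation(pd.DataFrame(
        rows, columns=["cell_id", "cluster", "outer_type", "lobule", "replicate"]
    ))
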