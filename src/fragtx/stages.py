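"""Stage-level responsiveness, gene-set Venn analysis, and sample clustering.

The mean abundance of a gene in a stage, A_stage, is related to its
abundance at the reference time point N_0, giving the relative mean
abundance R_stage; |log2 R_stage| > 1 classifies the gene as up- or
down-regulated in that stage, producing six gene sets (up/down x three
stages). Sample similarity is assessed by hierarchical clustering of
the Jensen-Shannon distance between the per-sample expression
distributions. Two small study-level phenotype formulas (cell weight,
relative volumetric lipid productivity) live here too.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import jensenshannon, squareform

from .core import (
    FC_THRESHOLD,
    FPKM_FLOOR,
    REFERENCE,
    STAGES,
    FragtxError,
)

STAGE_NAMES = tuple(STAGES)


def stage_response(
    matrix: pd.DataFrame,
    floor: float = FPKM_FLOOR,
    threshold: float = FC_THRESHOLD,
    apply_floor: bool = True,
) -> pd.DataFrame:
    """Per-locus stage means, log2 relative means, and stage classes.

    A_stage is the arithmetic mean FPKM over the stage's time points;
    R_stage = A_stage / FPKM(N_0). The FPKM reliability floor is applied
    analogously to single-time-point fold changes: log2 R_stage is NA
    when FPKM(N_0) or A_stage falls below the floor (disable with
    ``apply_floor=False``).

    Returns a frame indexed by locus with columns ``A_<stage>``,
    ``log2R_<stage>`` and ``class_<stage>`` for each stage.
    """
    ref = matrix[REFERENCE].to_numpy(dtype=float)
    out = pd.DataFrame(index=matrix.index)
    for stage, points in STAGES.items():
        a = matrix[list(points)].to_numpy(dtype=float).mean(axis=1)
        if apply_floor:
            mask = (ref < floor) | (a < floor)
        else:
            mask = (ref <= 0) | (a <= 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            log2r = np.log2(a / ref)
        log2r[mask] = np.nan
        cls = np.full(matrix.shape[0], "none", dtype=object)
        with np.errstate(invalid="ignore"):
            cls[log2r > threshold] = "up"
            cls[log2r < -threshold] = "down"
        cls[mask] = "NA"
        out[f"A_{stage}"] = a
        out[f"log2R_{stage}"] = log2r
        out[f"class_{stage}"] = cls
    return out


def stage_gene_sets(response: pd.DataFrame) -> dict[str, set[str]]:
    """The six stage gene sets, keyed ``up_<stage>`` / ``down_<stage>``."""
    sets: dict[str, set[str]] = {}
    for stage in STAGE_NAMES:
        cls = response[f"class_{stage}"]
        sets[f"up_{stage}"] = set(response.index[cls == "up"])
        sets[f"down_{stage}"] = set(response.index[cls == "down"])
    return sets


VENN_REGIONS = ("100", "010", "001", "110", "101", "011", "111")


def venn_partition(
    set_a: set[str], set_b: set[str], set_c: set[str]
) -> dict[str, set[str]]:
    """Standard 7-region partition of three sets.

    Region keys are membership bitmasks in (a, b, c) order: "100" is
    a-only, "110" is a-and-b-not-c, "111" the triple intersection.
    Regions are pairwise disjoint and union to a | b | c.
    """
    regions: dict[str, set[str]] = {key: set() for key in VENN_REGIONS}
    for element in set_a | set_b | set_c:
        key = "".join(
            "1" if element in s else "0" for s in (set_a, set_b, set_c)
        )
        regions[key].add(element)
    return regions


def js_sample_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jensen-Shannon distance between sample columns.

    Each column is normalized to a probability distribution over loci;
    the distance is the square root of the Jensen-Shannon divergence
    with base-2 logarithms, so values lie in [0, 1].
    """
    values = matrix.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise FragtxError(f"all-zero sample column {matrix.columns[zero[0]]!r}")
    probs = values / sums
    n = probs.shape[1]
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(jensenshannon(probs[:, i], probs[:, j], base=2))
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns)


def cluster_samples(distances: pd.DataFrame, method: str = "complete") -> np.ndarray:
    """Hierarchical clustering of samples from a distance matrix.

    Returns a scipy linkage matrix over the columns of ``distances``.
    """
    condensed = squareform(distances.to_numpy(dtype=float), checks=False)
    return linkage(condensed, method=method)


def cell_weight(biomass_g_per_l: float, cells_per_ml: float) -> float:
    """Cell weight in pg/cell from biomass (g/L) and cell concentration (1/mL)."""
    if cells_per_ml <= 0:
        raise FragtxError("cell concentration must be positive")
    # g/L divided by cells/mL is 1e-3 g/cell; report picograms
    return biomass_g_per_l / cells_per_ml * 1e9


def relative_volumetric_productivity(
    contents: dict[float, float]
) -> dict[float, float]:
    """Relative volumetric lipid productivities, normalized to day 1.

    ``contents`` maps cultivation day to volumetric lipid content; the
    productivity at day X is (C(X) - C(0)) / X and is reported relative
    to the day-1 productivity.
    """
    if 0 not in contents or 1 not in contents:
        raise FragtxError("contents must include day 0 and day 1")
    c0 = contents[0]
    p1 = contents[1] - c0
    if p1 == 0:
        raise FragtxError("day-1 productivity is zero; relative values undefined")
    out: dict[float, float] = {}
    for day, c in contents.items():
        if day == 0:
            continue
        out[day] = ((c - c0) / day) / p1
    return out
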