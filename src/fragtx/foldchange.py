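"""Log2 fold changes versus the pre-starvation reference N_0.

A fold change is only computed when both the reference and the
time-point FPKM are at least 1.0, the floor below which abundance
estimates are not considered reliable; such cells are masked as NA.
A gene is responsive at a time point when |log2-FC| > 1, and for
display fold changes are capped at |log2-FC| = 4 ("highly regulated").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    FC_CAP,
    FC_THRESHOLD,
    FPKM_FLOOR,
    MINUS_N_POINTS,
    NON_REFERENCE_POINTS,
    REFERENCE,
    FragtxError,
)


@dataclass
class FoldChangeResult:
    """Log2 fold changes with an explicit NA mask.

    ``log2fc`` holds finite values wherever ``na_mask`` is False and NaN
    where it is True; the mask, not the NaN, is the authoritative NA
    signal for downstream consumers.
    """

    log2fc: pd.DataFrame
    na_mask: pd.DataFrame

    @property
    def locus_ids(self) -> list[str]:
        return list(self.log2fc.index)


def log2_fold_change(fpkm_ref: float, fpkm_t: float, floor: float = FPKM_FLOOR) -> float:
    """log2(fpkm_t / fpkm_ref), or NaN when either value is below the floor."""
    if fpkm_ref < 0 or fpkm_t < 0:
        raise FragtxError(f"negative abundance: ({fpkm_ref}, {fpkm_t})")
    if fpkm_ref < floor or fpkm_t < floor:
        return float("nan")
    return float(np.log2(fpkm_t / fpkm_ref))


def fold_change_matrix(matrix: pd.DataFrame, floor: float = FPKM_FLOOR) -> FoldChangeResult:
    """Per-locus log2 fold changes of the 11 non-reference time points vs N_0."""
    values = matrix[list(NON_REFERENCE_POINTS)].to_numpy(dtype=float)
    ref = matrix[REFERENCE].to_numpy(dtype=float)[:, None]
    if (values < 0).any() or (ref < 0).any():
        raise FragtxError("negative abundance in expression matrix")
    mask = (ref < floor) | (values < floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(values / ref)
    fc[mask] = np.nan
    idx = matrix.index
    cols = list(NON_REFERENCE_POINTS)
    return FoldChangeResult(
        log2fc=pd.DataFrame(fc, index=idx, columns=cols),
        na_mask=pd.DataFrame(mask, index=idx, columns=cols),
    )


def classify_timepoint(log2fc: float, threshold: float = FC_THRESHOLD) -> str:
    """Classify one fold change: up (> 1), down (< -1), none (|fc| <= 1), NA."""
    if log2fc is None or (isinstance(log2fc, float) and np.isnan(log2fc)):
        return "NA"
    if log2fc > threshold:
        return "up"
    if log2fc < -threshold:
        return "down"
    return "none"


def classify(fc: FoldChangeResult, threshold: float = FC_THRESHOLD) -> pd.DataFrame:
    """Per-cell responsiveness classes for a whole fold-change matrix."""
    values = fc.log2fc.to_numpy(dtype=float)
    out = np.full(values.shape, "none", dtype=object)
    with np.errstate(invalid="ignore"):
        out[values > threshold] = "up"
        out[values < -threshold] = "down"
    out[fc.na_mask.to_numpy(dtype=bool)] = "NA"
    return pd.DataFrame(out, index=fc.log2fc.index, columns=fc.log2fc.columns)


def cap_for_display(
    log2fc: float | np.ndarray, cap: float = FC_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """Clamp fold changes to [-cap, cap]; flag values beyond as highly regulated.

    NaN cells pass through unclamped and unflagged.
    """
    values = np.asarray(log2fc, dtype=float)
    with np.errstate(invalid="ignore"):
        flagged = np.abs(values) > cap
    capped = np.clip(values, -cap, cap)
    return capped, flagged


def is_housekeeping_stable(
    locus_fc: pd.Series, na_mask: pd.Series | None = None, threshold: float = FC_THRESHOLD
) -> bool:
    """Stability criterion for housekeeping genes.

    True iff |log2-FC| > 1 at no more than one of the seven nitrogen-
    starvation time points (N_2..N_96). Masked (NA) points do not count
    as exceedances.
    """
    fc = locus_fc[list(MINUS_N_POINTS)].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        exceeds = np.abs(fc) > threshold
    exceeds &= ~np.isnan(fc)
    if na_mask is not None:
        exceeds &= ~na_mask[list(MINUS_N_POINTS)].to_numpy(dtype=bool)
    return int(exceeds.sum()) <= 1


def fold_change_table(fc: FoldChangeResult, cap: float = FC_CAP) -> pd.DataFrame:
    """Long-format table of fold changes, masks, classes and capped values."""
    classes = classify(fc)
    capped, flagged = cap_for_display(fc.log2fc.to_numpy(), cap=cap)
    frames = []
    for j, tp in enumerate(fc.log2fc.columns):
        frames.append(
            pd.DataFrame(
                {
                    "locus_id": fc.log2fc.index,
                    "time_point": tp,
                    "log2fc": fc.log2fc[tp].to_numpy(),
                    "na": fc.na_mask[tp].to_numpy(),
                    "class": classes[tp].to_numpy(),
                    "log2fc_capped": capped[:, j],
                    "highly_regulated": flagged[:, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
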