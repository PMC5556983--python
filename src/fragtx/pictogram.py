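"""Abundance categorization and heatmap-pictogram export.

Each gene's reference-point (N_0) abundance is binned into one of five
categories by the 50th/75th/90th/99th percentiles of the N_0 FPKM
distribution (I = below median ... V = top percentile). The pictogram
renders, per gene: its predicted localization letter, the abundance
category as a Roman numeral (bold when the gene is likely not
fragmented), and one color bar per time point from the capped log2
fold change — red up, blue down, white for the not-responsive band
(|log2-FC| <= 1), and an "NA" tag where the FPKM floor masked the value.
A companion TSV carries the same values machine-readably.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import FC_CAP, FC_THRESHOLD, REFERENCE, STAGES, FragtxError, LocusRecord
from .foldchange import FoldChangeResult, cap_for_display

CATEGORY_PERCENTILES = (50.0, 75.0, 90.0, 99.0)
CATEGORY_LABELS = ("I", "II", "III", "IV", "V")

STAGE_FRAME_COLORS = {"e-N": "#E69F00", "l-N": "#8B5A2B", "r+N": "#2E8B57"}
UP_COLOR = np.array([214, 39, 40])  # saturated red at the cap
DOWN_COLOR = np.array([31, 119, 180])  # saturated blue at the cap
WHITE = np.array([255, 255, 255])


def category_boundaries(n0_values: np.ndarray) -> np.ndarray:
    """P50/P75/P90/P99 cut points of the N_0 abundance distribution.

    Linear-interpolation quantiles; warns below 100 values (cut points
    are then poorly determined) and on a degenerate constant input.
    """
    values = np.asarray(n0_values, dtype=float)
    if values.size == 0:
        raise FragtxError("cannot compute category boundaries of an empty vector")
    if values.size < 100:
        warnings.warn(
            f"only {values.size} N_0 values; percentile boundaries are unstable",
            stacklevel=2,
        )
    cuts = np.percentile(values, CATEGORY_PERCENTILES, method="linear")
    if cuts[0] == cuts[-1]:
        warnings.warn("degenerate abundance distribution: all cut points equal", stacklevel=2)
    return cuts


def categorize(fpkm: float, boundaries: np.ndarray) -> str:
    """Assign one abundance to a category; boundary ties go to the
    higher category."""
    if fpkm < 0:
        raise FragtxError(f"negative abundance {fpkm}")
    idx = int(np.searchsorted(boundaries, fpkm, side="right"))
    return CATEGORY_LABELS[idx]


def categorize_matrix(matrix: pd.DataFrame) -> pd.Series:
    """Category of every locus from its N_0 abundance."""
    n0 = matrix[REFERENCE].to_numpy(dtype=float)
    cuts = category_boundaries(n0)
    return pd.Series(
        [categorize(v, cuts) for v in n0], index=matrix.index, name="category"
    )


def _bar_color(fc: float, cap: float, threshold: float) -> str:
    """Hex color for one capped fold change."""
    if abs(fc) <= threshold:
        rgb = WHITE
    else:
        frac = min((abs(fc) - threshold) / (cap - threshold), 1.0)
        target = UP_COLOR if fc > 0 else DOWN_COLOR
        rgb = np.round(WHITE + frac * (target - WHITE)).astype(int)
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def pictogram_table(
    fc: FoldChangeResult,
    categories: pd.Series,
    records: dict[str, LocusRecord],
    fragment_flags: dict[str, bool],
    cap: float = FC_CAP,
) -> pd.DataFrame:
    """Long-format companion table of the pictogram (one row per locus
    and time point)."""
    missing = [l for l in fc.locus_ids if l not in records or l not in categories.index]
    if missing:
        raise FragtxError(f"loci missing from records/categories: {missing[:5]}")
    capped, flagged = cap_for_display(fc.log2fc.to_numpy(), cap=cap)
    mask = fc.na_mask.to_numpy(dtype=bool)
    rows = []
    for i, locus in enumerate(fc.locus_ids):
        for j, tp in enumerate(fc.log2fc.columns):
            is_na = bool(mask[i, j])
            rows.append(
                {
                    "locus_id": locus,
                    "localization": records[locus].localization,
                    "category": categories[locus],
                    "fragmented": bool(fragment_flags.get(locus, False)),
                    "time_point": tp,
                    "log2fc_capped": np.nan if is_na else float(capped[i, j]),
                    "highly_regulated": False if is_na else bool(flagged[i, j]),
                    "na": is_na,
                    "color": "NA" if is_na else _bar_color(capped[i, j], cap, FC_THRESHOLD),
                }
            )
    return pd.DataFrame(rows)


def render_pictograms(
    fc: FoldChangeResult,
    categories: pd.Series,
    records: dict[str, LocusRecord],
    fragment_flags: dict[str, bool],
    out_svg: str | Path,
    out_tsv: str | Path,
    cap: float = FC_CAP,
) -> pd.DataFrame:
    """Render the pictogram SVG and its companion TSV; returns the table."""
    table = pictogram_table(fc, categories, records, fragment_flags, cap=cap)
    table.to_csv(out_tsv, sep="\t", index=False)

    bar_w, bar_h, row_h, gap = 14, 26, 40, 8
    label_w = 120
    stage_points = [(stage, list(points)) for stage, points in STAGES.items()]
    n_bars = sum(len(p) for _, p in stage_points)
    width = label_w + 60 + n_bars * bar_w + 3 * gap + 20
    loci = fc.locus_ids
    height = 30 + row_h * len(loci)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}">'
    ]
    by_locus = {l: g.set_index("time_point") for l, g in table.groupby("locus_id")}
    for row_i, locus in enumerate(loci):
        y = 20 + row_i * row_h
        g = by_locus[locus]
        loc_letter = records[locus].localization
        weight = "normal" if fragment_flags.get(locus, False) else "bold"
        parts.append(
            f'<text x="4" y="{y + bar_h / 2 + 4}" font-size="12">{locus}</text>'
        )
        parts.append(
            f'<text x="{label_w}" y="{y + bar_h / 2 + 4}" font-size="12">{loc_letter}</text>'
        )
        parts.append(
            f'<text x="{label_w + 20}" y="{y + bar_h / 2 + 4}" font-size="12" '
            f'font-weight="{weight}">{categories[locus]}</text>'
        )
        x = label_w + 60
        for stage, points in stage_points:
            frame_w = len(points) * bar_w
            parts.append(
                f'<rect x="{x - 1}" y="{y - 1}" width="{frame_w + 2}" height="{bar_h + 2}" '
                f'fill="none" stroke="{STAGE_FRAME_COLORS[stage]}" stroke-width="2"/>'
            )
            for tp in points:
                cell = g.loc[tp]
                if cell["na"]:
                    parts.append(
                        f'<text x="{x + 1}" y="{y + bar_h / 2 + 3}" font-size="7">NA</text>'
                    )
                else:
                    parts.append(
                        f'<rect x="{x}" y="{y}" width="{bar_w}" height="{bar_h}" '
                        f'fill="{cell["color"]}" stroke="#cccccc" stroke-width="0.5"/>'
                    )
                x += bar_w
            x += gap
    parts.append("</svg>")
    Path(out_svg).write_text("\n".join(parts), encoding="utf-8")
    return table
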