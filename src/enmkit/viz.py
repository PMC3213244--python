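"""Report rendering and molecular-viewer export.

The cumulative-overlap report follows the significance convention used
throughout the toolkit: the heatmap always shows every cell, but numeric
text appears only for entries with CO > 0.5.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .ensemble_pca import CO_SIGNIFICANCE_THRESHOLD, OverlapReport

__all__ = [
    "flag_significant",
    "render_co_table",
    "write_matrix_csv",
    "write_series_csv",
    "export_viewer_script",
]


def flag_significant(co, threshold: float = CO_SIGNIFICANCE_THRESHOLD) -> np.ndarray:
    """Boolean mask of the cumulative-overlap entries strictly above threshold."""
    return np.asarray(co, dtype=float) > threshold


def render_co_table(co, row_labels: Optional[Sequence[str]] = None,
                    col_labels: Optional[Sequence[str]] = None,
                    threshold: float = CO_SIGNIFICANCE_THRESHOLD) -> str:
    """Text heatmap of a cumulative-overlap matrix.

    Every cell is drawn, but the numeric value is printed only when
    CO > threshold; sub-threshold cells show a placeholder.
    """
    co = np.atleast_2d(np.asarray(co, dtype=float))
    flags = flag_significant(co, threshold)
    n_rows, n_cols = co.shape
    row_labels = row_labels or [f"PC{i + 1}" for i in range(n_rows)]
    col_labels = col_labels or [f"k={j + 1}" for j in range(n_cols)]

    width = max(6, max(len(c) for c in col_labels) + 1)
    lwidth = max(len(r) for r in row_labels) + 1
    lines = [" " * lwidth + "".join(f"{c:>{width}}" for c in col_labels)]
    for i in range(n_rows):
        cells = []
        for j in range(n_cols):
            cells.append(f"{co[i, j]:>{width}.3f}" if flags[i, j] else f"{'.':>{width}}")
        lines.append(f"{row_labels[i]:<{lwidth}}" + "".join(cells))
    lines.append(f"(text shown only for CO > {threshold:g})")
    return "\n".join(lines)


def write_matrix_csv(matrix, path, row_label: str = "row") -> None:
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([row_label] + [str(j) for j in range(matrix.shape[1])])
        for i, row in enumerate(matrix):
            w.writerow([i] + [f"{v:.10g}" for v in row])


def write_series_csv(values, path, header: Sequence[str] = ("index", "value")) -> None:
    values = np.asarray(values)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for i, v in enumerate(np.atleast_1d(values)):
            if np.ndim(v) == 0:
                w.writerow([i, f"{float(v):.10g}"])
            else:
                w.writerow([i] + [f"{float(x):.10g}" for x in v])


_PYMOL_TEMPLATE = """\
# PyMOL script generated by enmkit
load {path}, animation
set all_states, off
hide everything, animation
show cartoon, animation
# color and thickness by B-factor
spectrum b, blue_white_red, animation
cartoon putty, animation
set cartoon_putty_scale_min, 0.5
set cartoon_putty_scale_max, 4.0
set movie_fps, 15
mplay
"""


def export_viewer_script(animation_path, out_path, style: str = "bfactor_color") -> str:
    """Emit a fixed-template PyMOL command script that loads a multi-MODEL
    animation and applies B-factor-driven coloring/tube radius."""
    animation_path = Path(animation_path)
    if not animation_path.exists():
        raise FileNotFoundError(f"animation file not found: {animation_path}")
    if style != "bfactor_color":
        raise ValueError(f"unknown style {style!r}")
    text = _PYMOL_TEMPLATE.format(path=animation_path)
    Path(out_path).write_text(text)
    return text
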