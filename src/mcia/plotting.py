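"""Projection and pseudo-eigenvalue plots, each with a numeric coordinate TSV.

Every figure writes its plotted coordinates alongside the image (same stem,
``_coords.tsv`` suffix) so the plot content is testable numerically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import MciaResult
from .errors import InvalidArgumentError
from .io import write_matrix


def projection_coordinates(
    result: MciaResult, axes: Sequence[int] = (0, 1), normalized: bool = True
) -> pd.DataFrame:
    """Long-format coordinates: per sample one reference point plus one point per table.

    ``normalized=True`` uses D-unit-normalized table scores against the unit
    synthetic axes (identical tables collapse onto the reference);
    ``normalized=False`` keeps raw table scores against v * sqrt(lambda).
    """
    if len(axes) < 2:
        raise InvalidArgumentError("projection needs two axes")
    if max(axes) >= result.n_axes:
        raise InvalidArgumentError(f"axes {list(axes)} out of range ({result.n_axes} available)")
    d = result.D_diag
    rows = []
    for i, sample in enumerate(result.sample_ids):
        ref = []
        for h in axes:
            v = result.synthetic_scores[:, h]
            ref.append(v[i] if normalized else v[i] * np.sqrt(result.eigenvalues[h]))
        rows.append((sample, "__reference__", *ref))
        for name in result.table_names:
            pt = []
            for h in axes:
                s = result.table_scores[name][:, h]
                if normalized:
                    norm = float(np.sqrt(s @ (d * s)))
                    pt.append(s[i] / norm if norm > 0 else 0.0)
                else:
                    pt.append(s[i])
            rows.append((sample, name, *pt))
    cols = ["sample", "table"] + [f"axis{h + 1}" for h in axes]
    return pd.DataFrame(rows, columns=cols)


def plot_projection(
    result: MciaResult,
    outpath: str | Path,
    axes: Sequence[int] = (0, 1),
    labels: Mapping[str, str] | None = None,
    normalized: bool = True,
) -> Path:
    """Joint sample-space plot: each sample's K table points joined to its reference.

    Short segments mean concordant platforms.  ``labels`` optionally maps
    sample id -> group for coloring.  Returns the image path; coordinates are
    written next to it.
    """
    coords = projection_coordinates(result, axes=axes, normalized=normalized)
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    write_matrix(coords.set_index("sample"), outpath.with_name(outpath.stem + "_coords.tsv"),
                 index_label="sample")

    xcol, ycol = coords.columns[2], coords.columns[3]
    groups = sorted({labels[s] for s in result.sample_ids}) if labels else [None]
    cmap = plt.get_cmap("tab10")
    color_of = {g: cmap(i % 10) for i, g in enumerate(groups)}
    markers = ["o", "s", "^", "D", "v", "P", "X", "*"]

    fig, ax = plt.subplots(figsize=(6, 6))
    refs = coords[coords["table"] == "__reference__"].set_index("sample")
    for sample in result.sample_ids:
        rx, ry = refs.loc[sample, xcol], refs.loc[sample, ycol]
        col = color_of[labels[sample]] if labels else "0.3"
        pts = coords[(coords["sample"] == sample) & (coords["table"] != "__reference__")]
        for _, row in pts.iterrows():
            ax.plot([rx, row[xcol]], [ry, row[ycol]], color=col, lw=0.6, alpha=0.6, zorder=1)
        for m, (_, row) in zip(markers, pts.iterrows()):
            ax.scatter(row[xcol], row[ycol], color=col, marker=m, s=18, zorder=2)
        ax.scatter(rx, ry, color=col, marker=".", s=30, zorder=3)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_xlabel(xcol)
    ax.set_ylabel(ycol)
    ax.set_title("MCIA sample projection")
    fig.tight_layout()
    fig.savefig(outpath, dpi=150)
    plt.close(fig)
    return outpath


def plot_pseudo_eig(result: MciaResult, outpath: str | Path, axes: Sequence[int] = (0, 1)) -> Path:
    """Scatter of tables in pseudo-eigenvalue space (contribution per axis)."""
    if result.n_tables < 2:
        raise InvalidArgumentError("pseudo-eigenvalue plot needs at least two tables")
    if len(axes) < 2 or max(axes) >= result.n_axes:
        raise InvalidArgumentError(f"axes {list(axes)} out of range ({result.n_axes} available)")
    outpath = Path(outpath)
    outpath.parent.mkdir(parents=True, exist_ok=True)
    cols = [f"axis{h + 1}" for h in axes]
    coords = pd.DataFrame(
        result.pseudo_eigenvalues[:, list(axes)], index=result.table_names, columns=cols
    )
    write_matrix(coords, outpath.with_name(outpath.stem + "_coords.tsv"), index_label="table")

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(coords[cols[0]], coords[cols[1]], color="tab:blue")
    for name, row in coords.iterrows():
        ax.annotate(name, (row[cols[0]], row[cols[1]]), textcoords="offset points", xytext=(4, 4))
    ax.set_xlabel(f"{cols[0]} contribution")
    ax.set_ylabel(f"{cols[1]} contribution")
    ax.set_title("Pseudo-eigenvalue space")
    fig.tight_layout()
    fig.savefig(outpath, dpi=150)
    plt.close(fig)
    return outpath
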