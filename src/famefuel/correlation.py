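"""Pearson correlation of fatty-acid class totals with fuel properties.

Across a panel of cultures, the saturation classes (SFA/MUFA/PUFA) drive the
predicted fuel properties in opposite directions — more saturation means
better oxidative stability but worse cold flow.  This module quantifies that
with plain Pearson r per (class, property) pair and renders the matrix as a
heat map.  Significance stars use the two-sided t transform of r at
p < 0.05; no multiple-testing correction is applied (single exploratory
matrix).  A zero-variance vector makes r undefined: the cell is reported as
NaN and masked in the plot, never silently set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationMatrix", "correlate", "render_heatmap"]

CLASS_ROWS = ["SFA", "MUFA", "PUFA"]


@dataclass(frozen=True)
class CorrelationMatrix:
    """r, p and n per (class, property) cell."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def starred(self, alpha: float = 0.05) -> pd.DataFrame:
        """String table 'r*' marking p < alpha cells."""
        out = self.r.round(3).astype(object)
        for i in self.r.index:
            for j in self.r.columns:
                rv, pv = self.r.loc[i, j], self.p.loc[i, j]
                if np.isnan(rv):
                    out.loc[i, j] = "undefined"
                else:
                    out.loc[i, j] = f"{rv:.3f}" + ("*" if pv < alpha else "")
        return out


def correlate(class_vectors: pd.DataFrame, property_vectors: pd.DataFrame) -> CorrelationMatrix:
    """Pearson r between each class-total column and each property column.

    Both frames must share a ``sample_id`` column (or an identically ordered
    index) with >= 3 paired samples.  Class columns are SFA/MUFA/PUFA
    (case-insensitive); every numeric column of ``property_vectors`` other
    than ``sample_id`` becomes a matrix column.
    """
    cls = class_vectors.copy()
    props = property_vectors.copy()
    if "sample_id" in cls.columns and "sample_id" in props.columns:
        cls = cls.set_index("sample_id")
        props = props.set_index("sample_id")
        props = props.loc[cls.index]  # align; raises on mismatch
    if len(cls) != len(props):
        raise ValueError("class and property tables must have equal length")
    if len(cls) < 3:
        raise ValueError("need at least 3 paired samples")

    cls.columns = [c.upper() for c in cls.columns]
    rows = [c for c in CLASS_ROWS if c in cls.columns]
    if not rows:
        raise ValueError("no SFA/MUFA/PUFA columns found")
    cols = [c for c in props.columns if pd.api.types.is_numeric_dtype(props[c])]

    r = pd.DataFrame(index=rows, columns=cols, dtype=float)
    p = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for row in rows:
        x = cls[row].to_numpy(dtype=float)
        for col in cols:
            y = props[col].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                r.loc[row, col] = np.nan
                p.loc[row, col] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r.loc[row, col] = res.statistic
            p.loc[row, col] = res.pvalue
    return CorrelationMatrix(r=r, p=p, n=len(cls))


def render_heatmap(matrix: CorrelationMatrix, path: str | Path, alpha: float = 0.05) -> Path:
    """Write a labeled heat map (PNG/SVG by extension); NaN cells are masked.

    Deterministic given the matrix: fixed colormap, fixed [-1, 1] scale.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    r = matrix.r.astype(float)
    annot = r.round(2).astype(object)
    for i in r.index:
        for j in r.columns:
            if not np.isnan(r.loc[i, j]) and matrix.p.loc[i, j] < alpha:
                annot.loc[i, j] = f"{r.loc[i, j]:.2f}*"
            elif not np.isnan(r.loc[i, j]):
                annot.loc[i, j] = f"{r.loc[i, j]:.2f}"
            else:
                annot.loc[i, j] = ""
    fig, ax = plt.subplots(figsize=(1.0 + 0.9 * len(r.columns), 2.5 + 0.5 * len(r)))
    sns.heatmap(
        r,
        mask=r.isna(),
        annot=annot,
        fmt="",
        cmap="vlag",
        vmin=-1,
        vmax=1,
        cbar_kws={"label": "Pearson r"},
        linewidths=0.5,
        ax=ax,
    )
    ax.set_title(f"FA class vs fuel property (n = {matrix.n}, * p < {alpha:g})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
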