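"""Category switching between masker types and its mutual information.

A recording categorized under both maskers contributes one count to a 5 x 5
switching matrix (rows = category in stationary noise, columns = category in
chorus noise).  Shannon mutual information of this joint table (plug-in
estimate, bits) quantifies globally how predictive the stationary-noise
category is of the chorus-noise category: 0 bits for independence, up to
log2(5) ~ 2.3 bits for a perfectly diagonal equal-count matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categorize import CategoryAssignment
from .dataset import CATEGORIES

__all__ = ["SwitchingMatrix", "switching_matrix", "mutual_information",
           "switch_percentages"]


@dataclass
class SwitchingMatrix:
    counts: pd.DataFrame        # 5x5 int, rows = stationary, cols = chorus
    n_total: int

    @property
    def row_percent(self) -> pd.DataFrame:
        """Row-normalized percentages (each nonempty row sums to 100)."""
        c = self.counts.to_numpy(dtype=float)
        sums = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, 100.0 * c / sums, 0.0)
        return pd.DataFrame(pct, index=self.counts.index,
                            columns=self.counts.columns)


def switching_matrix(assignments_stationary: dict[str, CategoryAssignment],
                     assignments_chorus: dict[str, CategoryAssignment],
                     reliable_only: bool = False,
                     structure_by_id: dict[str, str] | None = None,
                     structure: str | None = None) -> SwitchingMatrix:
    """Joint 5 x 5 count table of per-masker categories.

    Recordings present under one masker only are excluded.  With
    ``reliable_only`` both assignments must be bootstrap-reliable; with
    ``structure`` set, only recordings of that structure (looked up in
    ``structure_by_id``) are counted.
    """
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    shared = assignments_stationary.keys() & assignments_chorus.keys()
    n = 0
    for rid in sorted(shared):
        a, b = assignments_stationary[rid], assignments_chorus[rid]
        if a.category not in CATEGORIES or b.category not in CATEGORIES:
            continue  # sentinel "undefined" outcomes
        if reliable_only and not (a.reliable and b.reliable):
            continue
        if structure is not None:
            if structure_by_id is None:
                raise ValueError("structure filter requires structure_by_id")
            if structure_by_id.get(rid) != structure:
                continue
        counts.loc[a.category, b.category] += 1
        n += 1
    return SwitchingMatrix(counts, n)


def mutual_information(matrix: SwitchingMatrix | pd.DataFrame | np.ndarray
                       ) -> float:
    """Plug-in Shannon mutual information of a joint count table, in bits.

    MI = sum_xy p(x,y) log2( p(x,y) / (p(x) p(y)) ) over nonzero cells; no
    bias correction is applied.  Undefined (NaN) for an empty table.
    """
    if isinstance(matrix, SwitchingMatrix):
        c = matrix.counts.to_numpy(dtype=float)
    elif isinstance(matrix, pd.DataFrame):
        c = matrix.to_numpy(dtype=float)
    else:
        c = np.asarray(matrix, dtype=float)
    total = c.sum()
    if total <= 0:
        return float("nan")
    p = c / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def switch_percentages(matrix: SwitchingMatrix,
                       assignments_stationary: dict[str, CategoryAssignment] | None = None,
                       assignments_chorus: dict[str, CategoryAssignment] | None = None,
                       structure_by_id: dict[str, str] | None = None,
                       ) -> tuple[pd.Series, pd.Series | None]:
    """Percent of recordings changing category, per category and per structure.

    Per category: 100 * (1 - diagonal / row total), NaN for empty rows.  Per
    structure (requires the assignment maps and a structure lookup): the same
    fraction computed over that structure's recordings.
    """
    c = matrix.counts.to_numpy(dtype=float)
    row_tot = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_cat = 100.0 * (1.0 - np.diag(c) / row_tot)
    per_cat = pd.Series(np.where(row_tot > 0, per_cat, np.nan),
                        index=matrix.counts.index, name="percent_switching")
    per_struct = None
    if structure_by_id is not None and assignments_stationary is not None \
            and assignments_chorus is not None:
        shared = assignments_stationary.keys() & assignments_chorus.keys()
        stayed: dict[str, list[bool]] = {}
        for rid in shared:
            a, b = assignments_stationary[rid], assignments_chorus[rid]
            if a.category not in CATEGORIES or b.category not in CATEGORIES:
                continue
            s = structure_by_id.get(rid)
            if s is None:
                continue
            stayed.setdefault(s, []).append(a.category == b.category)
        per_struct = pd.Series(
            {s: 100.0 * (1.0 - np.mean(v)) for s, v in sorted(stayed.items())},
            name="percent_switching", dtype=float)
    return per_cat, per_struct
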