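"""Grade-based scoring of microglial bead uptake.

Cells are graded by the number of fluorescent microbeads they engulfed:
1-3 beads = grade 1, 4-6 = grade 2, 7-10 = grade 3, more than 10 = grade 4
(0 beads = grade 0, non-phagocytic).  Per field of view the percentage of
phagocytic microglia and the per-grade percentages are computed over all
counted microglia; the phagocytic index is the grade-weighted sum of those
percentages, Sum_{g=1..4} g * pct[g], which equals 100 x the mean grade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["grade", "GradeProfile", "phagocytosis_summary"]

_GRADE_EDGES = (0, 3, 6, 10)  # upper bead count of grades 0..3; above -> 4


def grade(n_beads):
    """Uptake grade of one cell or an array of cells.

    0 beads -> 0; 1-3 -> 1; 4-6 -> 2; 7-10 -> 3; >10 -> 4.
    """
    arr = np.asarray(n_beads)
    if not np.issubdtype(arr.dtype, np.integer):
        as_int = np.asarray(n_beads, float)
        if np.any(as_int != np.round(as_int)):
            raise ValueError("bead counts must be integers")
        arr = as_int.astype(int)
    if np.any(arr < 0):
        raise ValueError("bead counts must be >= 0")
    g = np.digitize(arr, _GRADE_EDGES, right=True)
    return int(g) if np.isscalar(n_beads) else g


@dataclass
class GradeProfile:
    """Scores of one counting unit (a field of view by default)."""

    pct_phagocytic: float          # % of counted microglia with >= 1 bead
    pct_by_grade: dict             # grade (1..4) -> % of counted microglia
    phagocytic_index: float        # Sum g * pct_by_grade[g], in [0, 400]


def _profile(counts: np.ndarray, denominator: str) -> GradeProfile:
    g = grade(counts)
    n = len(g)
    pct_phag = 100.0 * np.count_nonzero(g) / n
    if denominator == "all":
        denom = n
    elif denominator == "phagocytic":
        denom = max(np.count_nonzero(g), 1)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    pct_by_grade = {k: 100.0 * np.count_nonzero(g == k) / denom
                    for k in (1, 2, 3, 4)}
    index = sum(k * p for k, p in pct_by_grade.items())
    return GradeProfile(pct_phag, pct_by_grade, index)


def phagocytosis_summary(
    beads: pd.DataFrame,
    unit: str = "field_id",
    denominator: str = "all",
) -> dict:
    """Score a bead-count table at three levels.

    ``beads`` needs columns ``animal_id, group, field_id, n_beads`` (one row
    per counted cell).  Returns ``{"per_unit": ..., "per_animal": ...,
    "per_group": ...}``: per counting unit the grade profile; per animal the
    mean over that animal's units; per group the mean +/- s.e.m. over
    animals.

    ``denominator="all"`` (default) expresses each grade as a percentage of
    all counted microglia, so the grade percentages sum to the phagocytic
    percentage and the index stays within [0, 400]; ``"phagocytic"``
    normalizes grades to phagocytic cells only.
    """
    required = {"animal_id", "group", unit, "n_beads"}
    if not required.issubset(beads.columns):
        raise ValueError(f"bead table needs columns {sorted(required)}")

    unit_rows = []
    for (animal, grp, u), sub in beads.groupby(["animal_id", "group", unit]):
        counts = sub["n_beads"].to_numpy()
        if len(counts) == 0:
            continue
        prof = _profile(counts, denominator)
        unit_rows.append({
            "animal_id": animal, "group": grp, unit: u,
            "n_cells": len(counts),
            "pct_phagocytic": prof.pct_phagocytic,
            **{f"pct_grade{k}": v for k, v in prof.pct_by_grade.items()},
            "phagocytic_index": prof.phagocytic_index,
        })
    per_unit = pd.DataFrame(unit_rows)
    if per_unit.empty:
        raise ValueError("no non-empty counting units in the table")

    score_cols = ["pct_phagocytic", "pct_grade1", "pct_grade2", "pct_grade3",
                  "pct_grade4", "phagocytic_index"]
    per_animal = (per_unit.groupby(["animal_id", "group"])[score_cols]
                  .mean().reset_index())
    grp = per_animal.groupby("group")[score_cols]
    per_group = grp.mean().join(grp.sem(ddof=1), rsuffix="_sem")
    per_group["n_animals"] = per_animal.groupby("group").size()
    return {"per_unit": per_unit, "per_animal": per_animal,
            "per_group": per_group.reset_index()}
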