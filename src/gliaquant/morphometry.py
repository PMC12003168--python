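"""EM axon/myelin morphometry from annotated cross-section area tables.

Diameters derive from areas by the equivalent-circle formula d = 2*sqrt(A/pi);
the g-ratio is the inner (axonal) over outer (fiber, axon + myelin sheath)
diameter and the sheath thickness their difference.  Group comparison is
nonparametric: Kruskal-Wallis across all groups with Shapiro-Wilk normality
diagnostics per group and Bonferroni-adjusted pairwise rank tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .imgops import LabelMap

__all__ = [
    "axon_metrics",
    "add_axon_metrics",
    "grid_sample_axons",
    "GroupTestResult",
    "nonparametric_group_test",
]


def axon_metrics(axon_area, fiber_area):
    """Diameters, g-ratio and sheath thickness from cross-section areas.

    d = 2*sqrt(A/pi) for both the inner (axon) and outer (fiber) area;
    g = d_in/d_out; sheath thickness = d_out - d_in.  Accepts scalars or
    arrays; areas must satisfy 0 < axon_area <= fiber_area.
    """
    a_in = np.asarray(axon_area, float)
    a_out = np.asarray(fiber_area, float)
    if np.any(a_in <= 0):
        raise ValueError("axon area must be > 0")
    if np.any(a_in > a_out):
        raise ValueError("axon area exceeds fiber area (annotation inconsistency)")
    d_in = 2.0 * np.sqrt(a_in / np.pi)
    d_out = 2.0 * np.sqrt(a_out / np.pi)
    return d_in, d_out, d_in / d_out, d_out - d_in


def add_axon_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns (diameters, g_ratio, sheath_thickness_um) to a
    table with ``axon_area_um2`` and ``fiber_area_um2`` columns."""
    d_in, d_out, g, t = axon_metrics(table["axon_area_um2"],
                                     table["fiber_area_um2"])
    out = table.copy()
    out["axon_diameter_um"] = d_in
    out["fiber_diameter_um"] = d_out
    out["g_ratio"] = g
    out["sheath_thickness_um"] = t
    return out


def grid_sample_axons(
    objects: LabelMap,
    grid_spacing_um: float,
    n_target: int = 20,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> list[int]:
    """Unbiased grid sampling of annotated objects.

    A square grid of the given spacing is overlaid on the image; objects
    whose mask covers a grid intersection point qualify.  Nodes are visited
    in row-major order and the first ``n_target`` distinct qualifying
    objects are kept, so the selection is deterministic.  Returns the
    selected label ids; fewer than ``n_target`` qualifying objects are all
    returned with a warning.
    """
    if grid_spacing_um <= 0:
        raise ValueError("grid_spacing_um must be > 0")
    ps = objects.pixel_size
    h, w = objects.labels.shape
    selected: list[int] = []
    seen = set()
    y = origin_um[0]
    while y < h * ps:
        x = origin_um[1]
        while x < w * ps:
            iy, ix = int(y / ps), int(x / ps)
            if 0 <= iy < h and 0 <= ix < w:
                lab = int(objects.labels[iy, ix])
                if lab > 0 and lab not in seen:
                    seen.add(lab)
                    selected.append(lab)
                    if len(selected) == n_target:
                        return selected
            x += grid_spacing_um
        y += grid_spacing_um
    warnings.warn(
        f"only {len(selected)} of the requested {n_target} objects touched "
        "a grid node", stacklevel=2)
    return selected


@dataclass
class GroupTestResult:
    shapiro: pd.DataFrame        # per group: W, p
    kruskal_h: float
    kruskal_p: float
    pairwise: pd.DataFrame       # group_a, group_b, p_raw, p_bonferroni


def nonparametric_group_test(values_by_group: dict) -> GroupTestResult:
    """Kruskal-Wallis across groups with normality diagnostics and
    Bonferroni-adjusted pairwise rank-sum tests.

    Shapiro-Wilk is reported per group as a diagnostic only (it motivates the
    nonparametric choice, it does not gate it).  Pairwise comparisons use the
    two-sided Mann-Whitney U test — exact for small groups (n <= 10 each),
    normal approximation with tie correction otherwise — with raw p-values
    multiplied by the number of comparisons and capped at 1.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {g: np.asarray(v, float) for g, v in values_by_group.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has < 2 observations")

    rows = []
    for g, v in arrays.items():
        if len(np.unique(v)) < 3:
            rows.append({"group": g, "W": np.nan, "p": np.nan})
        else:
            w, p = stats.shapiro(v)
            rows.append({"group": g, "W": w, "p": p})
    shapiro = pd.DataFrame(rows).set_index("group")

    h, p = stats.kruskal(*arrays.values())

    n_comp = len(groups) * (len(groups) - 1) // 2
    pw = []
    for ga, gb in combinations(groups, 2):
        a, b = arrays[ga], arrays[gb]
        method = "exact" if (len(a) <= 10 and len(b) <= 10
                             and not _has_ties(a, b)) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        pw.append({"group_a": ga, "group_b": gb, "p_raw": res.pvalue,
                   "p_bonferroni": min(1.0, res.pvalue * n_comp)})
    return GroupTestResult(shapiro, float(h), float(p), pd.DataFrame(pw))


def _has_ties(a, b) -> bool:
    merged = np.concatenate([a, b])
    return len(np.unique(merged)) < len(merged)
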