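"""Per-cell marker measurement, positivity calling, plaque proximity and
expression-profile pooling, plus the simple histological count/coverage
metrics.

Cell records are carried as a pandas DataFrame with one row per segmented
cell and columns::

    cell_id, image_id, animal_id, group,
    centroid_y_um, centroid_x_um, area_um2,
    mean_<channel> ...        (one per measured channel)
    positive_<channel> ...    (after classify_positive)
    dist_to_plaque_um, in_proximity   (after plaque_proximity)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .imgops import ChannelImage, LabelMap, otsu_threshold

__all__ = [
    "measure_cells",
    "classify_positive",
    "plaque_proximity",
    "ExpressionProfile",
    "expression_profile",
    "count_ratio",
    "cell_density",
    "mean_gray_ratio",
    "marker_metrics",
]


def measure_cells(
    nuclei: LabelMap,
    channels: list[ChannelImage],
    image_id: str = "img1",
    animal_id: str = "animal1",
    group: str = "group1",
) -> pd.DataFrame:
    """Measure every nucleus: area, centroid and per-channel mean intensity.

    Mean intensity over the segmented nuclear pixel set is the expression
    readout for each marker channel.  Centroids are intensity-unweighted and
    reported in micrometres at pixel centers.
    """
    for ch in channels:
        if ch.shape != nuclei.labels.shape or ch.pixel_size != nuclei.pixel_size:
            raise ValueError(
                f"channel {ch.name!r} does not share the nuclei grid")
    props = regionprops(nuclei.labels)
    ps = nuclei.pixel_size
    rows = {
        "cell_id": [p.label for p in props],
        "image_id": image_id,
        "animal_id": animal_id,
        "group": group,
        "centroid_y_um": [(p.centroid[0] + 0.5) * ps for p in props],
        "centroid_x_um": [(p.centroid[1] + 0.5) * ps for p in props],
        "area_um2": [p.area * ps**2 for p in props],
    }
    df = pd.DataFrame(rows)
    for ch in channels:
        sums = np.bincount(nuclei.labels.ravel(), weights=ch.pixels.ravel(),
                           minlength=nuclei.n_labels + 1)
        counts = np.bincount(nuclei.labels.ravel(), minlength=nuclei.n_labels + 1)
        with np.errstate(invalid="ignore"):
            means = sums / counts
        df[f"mean_{ch.name}"] = means[df["cell_id"].to_numpy()]
    return df


def classify_positive(records: pd.DataFrame, channel: str) -> pd.DataFrame:
    """Call marker positivity per image by Otsu on that image's cell means.

    The threshold is computed independently within each image from all its
    cell-level mean intensities and never shared across images; a cell is
    positive iff its mean is strictly above the image threshold.  Images
    with fewer than two distinct means get an indeterminate (NA) flag.
    """
    col, out_col = f"mean_{channel}", f"positive_{channel}"
    if col not in records:
        raise KeyError(f"records lack column {col!r}; run measure_cells first")
    records = records.copy()
    flags = pd.Series(pd.NA, index=records.index, dtype="boolean")
    for image_id, idx in records.groupby("image_id").groups.items():
        vals = records.loc[idx, col].to_numpy(float)
        try:
            thr = otsu_threshold(vals)
        except ValueError:
            warnings.warn(
                f"image {image_id!r}: <2 distinct {channel} means; "
                "positivity indeterminate", stacklevel=2)
            continue
        flags.loc[idx] = vals > thr
    records[out_col] = flags
    return records


def plaque_proximity(
    records: pd.DataFrame,
    plaques: LabelMap,
    radius_um: float = 30.0,
    positive_channel: str = "iba1",
) -> pd.DataFrame:
    """Distance from each cell centroid to the nearest plaque pixel and the
    proximity selection flag.

    A centroid lying inside a plaque has distance 0.  ``in_proximity`` marks
    cells that are both marker-positive (``positive_<positive_channel>``)
    and within ``radius_um`` of a plaque boundary — the "within 30 um around
    plaques" band by default.  With no plaques all distances are infinite.
    """
    records = records.copy()
    mask = plaques.labels > 0
    ps = plaques.pixel_size
    cent = records[["centroid_y_um", "centroid_x_um"]].to_numpy(float)
    if not mask.any():
        warnings.warn("no plaques in image; all distances infinite", stacklevel=2)
        records["dist_to_plaque_um"] = np.inf
    else:
        tree = cKDTree((np.argwhere(mask) + 0.5) * ps)
        d, _ = tree.query(cent)
        iy = np.clip((cent[:, 0] / ps).astype(int), 0, mask.shape[0] - 1)
        ix = np.clip((cent[:, 1] / ps).astype(int), 0, mask.shape[1] - 1)
        records["dist_to_plaque_um"] = np.where(mask[iy, ix], 0.0, d)
    pos_col = f"positive_{positive_channel}"
    positive = (records[pos_col].fillna(False).to_numpy(bool)
                if pos_col in records else np.ones(len(records), bool))
    records["in_proximity"] = positive & (
        records["dist_to_plaque_um"].to_numpy() <= radius_um)
    return records


@dataclass
class ExpressionProfile:
    """Pooled, integral-normalized expression histograms.

    ``per_image`` rows each sum to 1; ``per_animal`` is the element-wise
    median of that animal's image profiles; ``group_mean``/``group_sem`` are
    taken across animals within each group (s.e.m. with n-1 in the standard
    deviation, n = number of animals).
    """

    bin_edges: np.ndarray
    per_image: pd.DataFrame    # index image_id, one column per bin
    per_animal: pd.DataFrame   # index animal_id
    group_mean: pd.DataFrame   # index group
    group_sem: pd.DataFrame


def expression_profile(
    records: pd.DataFrame,
    channel: str,
    bins: int | np.ndarray = 20,
    group_map: dict | pd.Series | None = None,
) -> ExpressionProfile:
    """Bin cell-level expression image-wise, normalize each histogram by its
    own integral, pool per animal by the element-wise median, then average
    across animals per group.

    ``bins`` is either a bin count (edges span the pooled min-max of the
    supplied records, fixed across all images for comparability) or explicit
    edges.  Callers are expected to pass only the eligible cells (e.g. the
    plaque-proximal marker-positive subset).
    """
    col = f"mean_{channel}"
    vals = records[col].to_numpy(float)
    if len(vals) == 0:
        raise ValueError("no records to profile")
    if np.isscalar(bins):
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, float)
    if len(edges) < 3:
        raise ValueError("need at least 2 bins")

    per_image = {}
    animal_of_image = {}
    for (image_id, animal_id), sub in records.groupby(["image_id", "animal_id"]):
        h, _ = np.histogram(sub[col].to_numpy(float), bins=edges)
        total = h.sum()
        if total == 0:
            warnings.warn(f"image {image_id!r} has no eligible cells; excluded",
                          stacklevel=2)
            continue
        per_image[image_id] = h / total
        animal_of_image[image_id] = animal_id
    per_image = pd.DataFrame.from_dict(per_image, orient="index")
    per_image.index.name = "image_id"

    per_animal = per_image.groupby(
        per_image.index.map(animal_of_image)).median()
    per_animal.index.name = "animal_id"

    if group_map is None:
        group_map = records.drop_duplicates("animal_id").set_index(
            "animal_id")["group"]
    group_of = pd.Series(group_map)
    grp = per_animal.groupby(per_animal.index.map(group_of))
    group_mean = grp.mean()
    group_sem = grp.sem(ddof=1)
    return ExpressionProfile(edges, per_image, per_animal, group_mean, group_sem)


def count_ratio(n_marker: int, n_reference: int) -> float:
    """Marker-positive count normalized to a reference count (e.g. Olig2+
    over DAPI+, or CC1+ over Olig2+)."""
    if n_reference <= 0:
        raise ValueError("reference count must be > 0")
    return n_marker / n_reference


def cell_density(n_cells: int, roi_area_um2: float) -> float:
    """Cells per um^2 within a region of interest of stated area (e.g. PV+
    interneurons within 2 x 10^4 um^2 of CA1)."""
    if roi_area_um2 <= 0:
        raise ValueError("ROI area must be > 0")
    return n_cells / roi_area_um2


def mean_gray_ratio(marker_mean: float, dapi_mean: float) -> float:
    """Mean gray value of a marker (e.g. MBP in the corpus callosum)
    normalized to the DAPI mean gray value of the same ROI."""
    if dapi_mean <= 0:
        raise ValueError("DAPI mean gray value must be > 0")
    return marker_mean / dapi_mean


def marker_metrics(mode: str, **kwargs) -> float:
    """Dispatch to :func:`count_ratio` (``mode='count_ratio'``),
    :func:`cell_density` (``'density'``) or :func:`mean_gray_ratio`
    (``'mean_gray_ratio'``)."""
    funcs = {"count_ratio": count_ratio, "density": cell_density,
             "mean_gray_ratio": mean_gray_ratio}
    if mode not in funcs:
        raise ValueError(f"unknown mode {mode!r}")
    return funcs[mode](**kwargs)
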