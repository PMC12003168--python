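"""Ground-truth scoring of segmentation outputs on synthetic scenes.

Matching is a one-to-one Hungarian assignment between truth object centers
and predicted centroids; a pair counts as a match when the predicted
centroid falls within the truth object's radius.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from skimage.measure import regionprops

from .imgops import LabelMap

__all__ = ["match_instances", "score_nuclei_segmentation"]


def match_instances(
    truth_centers_um: np.ndarray,
    truth_radii_um: np.ndarray,
    predicted_centroids_um: np.ndarray,
) -> dict:
    """Hungarian one-to-one matching of predictions to truth objects.

    Returns the matched fraction of truth objects (recall), the fraction of
    predictions left unmatched (spurious rate) and the index pairs of the
    accepted matches.
    """
    truth = np.atleast_2d(np.asarray(truth_centers_um, float))
    pred = np.atleast_2d(np.asarray(predicted_centroids_um, float))
    n_truth, n_pred = len(truth), len(pred)
    if n_truth == 0 or n_pred == 0:
        return {"matched_fraction": 0.0 if n_truth else np.nan,
                "spurious_fraction": 1.0 if n_pred else 0.0,
                "n_truth": n_truth, "n_pred": n_pred, "pairs": []}
    d = cdist(truth, pred)
    rows, cols = linear_sum_assignment(d)
    radii = np.asarray(truth_radii_um, float)
    ok = d[rows, cols] <= radii[rows]
    pairs = list(zip(rows[ok].tolist(), cols[ok].tolist()))
    n_match = int(ok.sum())
    return {
        "matched_fraction": n_match / n_truth,
        "spurious_fraction": (n_pred - n_match) / n_pred,
        "n_truth": n_truth,
        "n_pred": n_pred,
        "pairs": pairs,
    }


def score_nuclei_segmentation(truth_nuclei: pd.DataFrame,
                              labels: LabelMap) -> dict:
    """Score a nuclei LabelMap against a scene's truth table."""
    ps = labels.pixel_size
    cents = np.array([[(p.centroid[0] + 0.5) * ps, (p.centroid[1] + 0.5) * ps]
                      for p in regionprops(labels.labels)])
    if cents.size == 0:
        cents = np.empty((0, 2))
    return match_instances(
        truth_nuclei[["center_y_um", "center_x_um"]].to_numpy(),
        truth_nuclei["radius_um"].to_numpy(),
        cents,
    )
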