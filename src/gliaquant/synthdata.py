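"""Ground-truthed synthetic data emulating every input the pipelines consume.

The generators produce (a) multichannel fluorescence scenes with disk-like
nuclei, a marker-positive microglial subset, irregular amyloid-like plaques
and a planted distance-dependent marker gradient; (b) electron-microscopy
axon area tables with group-specific g-ratio distributions; (c) zero-inflated
bead-uptake counts; (d) multinomial cell-type composition counts; and
(e) paired differential-expression tables with a controlled significant-set
overlap.  Every generator records its ground truth so downstream stages can
be scored against it.

Reproducibility: each generator draws from ``numpy.random.default_rng([seed,
STREAM_ID])`` where ``STREAM_ID`` is a fixed per-generator constant, so the
same seed yields byte-identical output for each generator regardless of which
other generators are called.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .imgops import ChannelImage

__all__ = [
    "SimulationParams",
    "SyntheticScene",
    "PlacementError",
    "generate_scene",
    "generate_axon_table",
    "generate_bead_counts",
    "generate_composition",
    "generate_deg_tables",
]

# fixed sub-stream ids: adding a generator must not renumber existing ones
_STREAM_SCENE = 1
_STREAM_AXONS = 2
_STREAM_BEADS = 3
_STREAM_COMPOSITION = 4
_STREAM_DEGS = 5

class PlacementError(RuntimeError):
    """Raised when the requested objects cannot be placed in the image."""


@dataclass
class SimulationParams:
    """Parameters of all synthetic generators, physical units in micrometres.

    Scene geometry defaults emulate a 512x512 confocal field at 0.3 um/px
    (153.6 um across) with 50 nuclei and 3 plaques; intensity conventions
    (means, noise) are declared here, not inferred from any instrument.
    """

    rng_seed: int = 0
    # --- imaging scene ---
    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.3
    n_nuclei: int = 50
    nucleus_radius_range: tuple[float, float] = (2.5, 4.0)
    n_plaques: int = 3
    plaque_radius_range: tuple[float, float] = (7.0, 12.0)
    marker_gradient: tuple[float, float] = (200.0, -1.5)  # baseline, slope/um
    noise_sd: float = 5.0
    background_amplitude: float = 10.0
    noise_model: str = "gaussian"  # or "poisson"
    iba1_positive_frac: float = 0.5
    dapi_mean: float = 120.0
    iba1_positive_mean: float = 150.0
    iba1_negative_mean: float = 20.0
    clec7a_negative_mean: float = 15.0
    plaque_mean: float = 180.0
    marker_floor: float = 0.0
    marker_disk_scale: float = 1.2  # soma/nucleus radius ratio for markers
    # --- EM axon tables ---
    n_axons: int = 20  # per image
    n_images_per_animal: int = 1
    n_animals_per_group: int = 3
    gratio_mean_by_group: dict = field(
        default_factory=lambda: {"WT": 0.75, "APPPS1": 0.85}
    )
    gratio_sd: float = 0.05
    axon_diameter_logmean: float = np.log(0.8)
    axon_diameter_logsd: float = 0.3
    # --- bead counts ---
    bead_rate_by_group: dict = field(
        default_factory=lambda: {"WT": 3.0, "APPPS1": 1.5}
    )
    zero_inflation: float = 0.3
    n_fields_per_animal: int = 5
    n_cells_per_field: int = 20
    # --- composition ---
    composition_by_group: dict = field(
        default_factory=lambda: {
            "WT": (0.35, 0.25, 0.2, 0.1, 0.1),
            "APPPS1": (0.3, 0.25, 0.2, 0.15, 0.1),
        }
    )
    n_cells_per_sample: int = 1000
    n_samples_per_group: int = 3
    # --- DEG tables ---
    deg_set_sizes: tuple[int, int, int] = (461, 488, 96)
    n_decoy_genes: int = 500

    def __post_init__(self):
        for name, vec_by_group in (("composition_by_group", self.composition_by_group),):
            for g, p in vec_by_group.items():
                p = np.asarray(p, float)
                if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                    raise ValueError(f"{name}[{g!r}] is not a probability vector")
        for g, m in self.gratio_mean_by_group.items():
            if not 0 < m < 1:
                raise ValueError(f"g-ratio mean for {g!r} must be in (0,1)")
        for g, r in self.bead_rate_by_group.items():
            if r < 0:
                raise ValueError(f"bead rate for {g!r} must be >= 0")
        if not 0 <= self.zero_inflation <= 1:
            raise ValueError("zero_inflation must be in [0,1]")
        a, b, shared = self.deg_set_sizes
        if shared > min(a, b):
            raise ValueError("shared DEG set larger than one of the sets")
        for name in ("pixel_size", "noise_sd", "background_amplitude"):
            if getattr(self, name) < 0 or (name == "pixel_size" and self.pixel_size <= 0):
                raise ValueError(f"{name} must be positive")
        for lo, hi in (self.nucleus_radius_range, self.plaque_radius_range):
            if not 0 < lo <= hi:
                raise ValueError("radius ranges must satisfy 0 < lo <= hi")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.rng_seed), stream])


@dataclass
class SyntheticScene:
    """A rendered multichannel field of view plus its complete ground truth."""

    channels: dict  # name -> ChannelImage
    truth_nuclei: pd.DataFrame  # center/radius/true means/iba1_positive
    truth_plaque_mask: np.ndarray  # bool grid
    truth_distances: np.ndarray  # um, per nucleus; inf if no plaque
    params: SimulationParams


def _place_disks(rng, n, radius_lo, radius_hi, field_h, field_w, margin,
                 min_gap_factor=1.0, max_tries=20000):
    """Rejection-sample disk centers so no two disks overlap.

    Centers are kept at least ``min_gap_factor * (r_i + r_j)`` apart.
    """
    centers, radii = [], []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(centers)}/{n} objects after {max_tries} tries; "
                "image too small for the requested density"
            )
        tries += 1
        r = rng.uniform(radius_lo, radius_hi)
        if r + margin >= field_h - r - margin or \
                r + margin >= field_w - r - margin:
            raise PlacementError(
                f"an object of radius {r:.1f} um does not fit a "
                f"{field_h:.1f} x {field_w:.1f} um field")
        y = rng.uniform(r + margin, field_h - r - margin)
        x = rng.uniform(r + margin, field_w - r - margin)
        ok = all(
            (y - cy) ** 2 + (x - cx) ** 2 >= (min_gap_factor * (r + cr)) ** 2
            for (cy, cx), cr in zip(centers, radii)
        )
        if ok:
            centers.append((y, x))
            radii.append(r)
    return np.array(centers), np.array(radii)


def render_gaussian_disk(canvas: np.ndarray, center_um, radius_um, mean_intensity,
                         pixel_size: float, profile: str = "gaussian") -> None:
    """Add one cell disk to ``canvas``.

    ``profile="gaussian"``: Gaussian intensity falloff with sigma = r/2,
    truncated at 2 sigma (the disk edge), normalized so the mean over the
    pixels whose centers lie in the truth disk equals ``mean_intensity``
    exactly — used for the nuclear (DAPI) channel.
    ``profile="flat"``: uniform ``mean_intensity`` over the disk — used for
    marker channels, so the mean over any sub-region an imperfect
    segmentation captures is still the planted mean.
    """
    cy, cx = center_um
    sigma = radius_um / 2.0
    if profile not in ("flat", "gaussian"):
        raise ValueError(f"unknown profile {profile!r}")
    r_px = int(np.ceil(radius_um / pixel_size)) + 1
    cy_px, cx_px = cy / pixel_size, cx / pixel_size
    y0 = max(0, int(cy_px) - r_px)
    y1 = min(canvas.shape[0], int(cy_px) + r_px + 1)
    x0 = max(0, int(cx_px) - r_px)
    x1 = min(canvas.shape[1], int(cx_px) + r_px + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    # pixel centers in um
    d2 = ((yy + 0.5) * pixel_size - cy) ** 2 + ((xx + 0.5) * pixel_size - cx) ** 2
    mask = d2 <= radius_um**2
    patch = np.zeros(mask.shape)
    if profile == "flat":
        patch[mask] = mean_intensity
    else:
        prof = np.exp(-d2[mask] / (2.0 * sigma**2))
        # normalize on the discrete pixel grid so the mean over the truth
        # disk equals the declared mean exactly, whatever the pixel size
        patch[mask] = prof * (mean_intensity / prof.mean())
    canvas[y0:y1, x0:x1] += patch


def _render_plaque(mask: np.ndarray, canvas: np.ndarray, center_um, radius_um,
                   intensity, pixel_size, rng) -> None:
    """Union of 3-6 jittered hard disks: irregular outline, exact truth mask."""
    n_lobes = rng.integers(3, 7)
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    ypix = (yy + 0.5) * pixel_size
    xpix = (xx + 0.5) * pixel_size
    for _ in range(n_lobes):
        jitter = rng.uniform(-0.4, 0.4, size=2) * radius_um
        r = radius_um * rng.uniform(0.6, 1.0)
        cy, cx = center_um[0] + jitter[0], center_um[1] + jitter[1]
        lobe = (ypix - cy) ** 2 + (xpix - cx) ** 2 <= r**2
        mask |= lobe
        canvas[lobe] = intensity


def generate_scene(params: SimulationParams) -> SyntheticScene:
    """Render a ground-truthed multichannel scene.

    Channels: ``nuclei`` (all nuclei), ``iba1`` (microglial marker, bimodal
    across cells), ``clec7a`` (planted linear gradient in plaque distance for
    Iba1-positive cells), ``plaque`` (amyloid-like deposits).  True Clec7a
    means below ``marker_floor`` are clipped with a warning, since rendered
    intensities cannot be negative.
    """
    rng = params._rng(_STREAM_SCENE)
    h, w = params.image_shape
    field_h, field_w = h * params.pixel_size, w * params.pixel_size
    baseline, slope = params.marker_gradient

    plaque_mask = np.zeros((h, w), bool)
    plaque_canvas = np.zeros((h, w))
    if params.n_plaques > 0:
        p_centers, p_radii = _place_disks(
            rng, params.n_plaques, *params.plaque_radius_range,
            field_h, field_w, margin=2.0, min_gap_factor=1.2)
        for c, r in zip(p_centers, p_radii):
            _render_plaque(plaque_mask, plaque_canvas, c, r,
                           params.plaque_mean, params.pixel_size, rng)

    if params.n_nuclei > 0:
        n_centers, n_radii = _place_disks(
            rng, params.n_nuclei, *params.nucleus_radius_range,
            field_h, field_w, margin=1.0,
            min_gap_factor=max(1.0, 1.1 * params.marker_disk_scale))
    else:
        n_centers, n_radii = np.empty((0, 2)), np.empty(0)

    # exact distance from nucleus center to nearest plaque pixel center
    if plaque_mask.any() and len(n_centers):
        pk_yx = (np.argwhere(plaque_mask) + 0.5) * params.pixel_size
        tree = cKDTree(pk_yx)
        dists, _ = tree.query(n_centers)
        inside = plaque_mask[
            np.clip((n_centers[:, 0] / params.pixel_size).astype(int), 0, h - 1),
            np.clip((n_centers[:, 1] / params.pixel_size).astype(int), 0, w - 1),
        ]
        dists = np.where(inside, 0.0, dists)
    else:
        dists = np.full(len(n_centers), np.inf)

    n_pos = int(round(params.iba1_positive_frac * params.n_nuclei))
    pos_flags = np.zeros(params.n_nuclei, bool)
    pos_flags[rng.permutation(params.n_nuclei)[:n_pos]] = True

    dapi_true = np.full(params.n_nuclei, params.dapi_mean)
    iba1_true = np.where(pos_flags, params.iba1_positive_mean,
                         params.iba1_negative_mean)
    clec7a_true = np.where(
        pos_flags,
        baseline + slope * np.where(np.isfinite(dists), dists, 0.0),
        params.clec7a_negative_mean,
    )
    if (clec7a_true < params.marker_floor).any():
        warnings.warn(
            "planted marker gradient clipped at the intensity floor for "
            f"{int((clec7a_true < params.marker_floor).sum())} nuclei; "
            "the truth-table slope is no longer exactly linear",
            stacklevel=2,
        )
        clec7a_true = np.maximum(clec7a_true, params.marker_floor)

    canvases = {name: np.zeros((h, w)) for name in ("nuclei", "iba1", "clec7a")}
    # markers (Iba1, Clec7a) are cytoplasmic: rendered as flat soma disks
    # slightly larger than the nucleus, so the nuclear segmentation always
    # measures a region of uniform marker intensity
    for i in range(params.n_nuclei):
        render_gaussian_disk(canvases["nuclei"], n_centers[i], n_radii[i],
                             dapi_true[i], params.pixel_size,
                             profile="gaussian")
        soma_r = params.marker_disk_scale * n_radii[i]
        for name, true_means in (("iba1", iba1_true),
                                 ("clec7a", clec7a_true)):
            render_gaussian_disk(canvases[name], n_centers[i], soma_r,
                                 true_means[i], params.pixel_size,
                                 profile="flat")
    canvases["plaque"] = plaque_canvas

    # smooth additive background: one broad 2D cosine bump per channel
    yy, xx = np.mgrid[0:h, 0:w]
    channels = {}
    for name, canvas in canvases.items():
        img = canvas.copy()
        if params.background_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi, size=2)
            img += params.background_amplitude * 0.5 * (
                1 + np.cos(2 * np.pi * yy / h + phase[0])
                * np.cos(2 * np.pi * xx / w + phase[1])
            )
        if params.noise_sd > 0:
            if params.noise_model == "gaussian":
                img = img + rng.normal(0, params.noise_sd, size=img.shape)
            elif params.noise_model == "poisson":
                img = rng.poisson(np.maximum(img, 0)).astype(float)
            else:
                raise ValueError(f"unknown noise model {params.noise_model!r}")
        channels[name] = ChannelImage(np.maximum(img, 0.0), params.pixel_size, name)

    truth = pd.DataFrame({
        "center_y_um": n_centers[:, 0],
        "center_x_um": n_centers[:, 1],
        "radius_um": n_radii,
        "true_mean_nuclei": dapi_true,
        "true_mean_iba1": iba1_true,
        "true_mean_clec7a": clec7a_true,
        "iba1_positive": pos_flags,
    })
    return SyntheticScene(channels, truth, plaque_mask, dists, params)


def generate_axon_table(params: SimulationParams) -> pd.DataFrame:
    """EM axon morphometry input table with group-specific g-ratios.

    Per axon the inner (axonal) diameter is lognormal and the g-ratio is a
    truncated normal around the group mean; inner and outer cross-section
    areas are emitted consistently with those diameters, alongside the
    sampled true g-ratio for parameter-recovery tests.
    """
    rng = params._rng(_STREAM_AXONS)
    rows = []
    for group, g_mean in params.gratio_mean_by_group.items():
        for a in range(params.n_animals_per_group):
            animal = f"{group}_m{a + 1}"
            for im in range(params.n_images_per_animal):
                d_in = rng.lognormal(params.axon_diameter_logmean,
                                     params.axon_diameter_logsd,
                                     size=params.n_axons)
                if params.gratio_sd == 0:
                    g = np.full(params.n_axons, g_mean)
                else:
                    lo, hi = 0.05, 0.99
                    g = stats.truncnorm.rvs(
                        (lo - g_mean) / params.gratio_sd,
                        (hi - g_mean) / params.gratio_sd,
                        loc=g_mean, scale=params.gratio_sd,
                        size=params.n_axons, random_state=rng)
                d_out = d_in / g
                rows.append(pd.DataFrame({
                    "image_id": f"{animal}_img{im + 1}",
                    "animal_id": animal,
                    "group": group,
                    "axon_area_um2": np.pi * (d_in / 2) ** 2,
                    "fiber_area_um2": np.pi * (d_out / 2) ** 2,
                    "true_g_ratio": g,
                }))
    return pd.concat(rows, ignore_index=True)


def generate_bead_counts(params: SimulationParams) -> pd.DataFrame:
    """Zero-inflated Poisson bead-uptake counts per microglial cell.

    A cell is a structural zero (never phagocytic in the assay window) with
    probability ``zero_inflation``; otherwise its bead count is Poisson with
    the group rate.
    """
    rng = params._rng(_STREAM_BEADS)
    rows = []
    for group, rate in params.bead_rate_by_group.items():
        for a in range(params.n_animals_per_group):
            animal = f"{group}_m{a + 1}"
            for f in range(params.n_fields_per_animal):
                n = params.n_cells_per_field
                structural = rng.random(n) < params.zero_inflation
                counts = rng.poisson(rate, size=n)
                counts[structural] = 0
                rows.append(pd.DataFrame({
                    "animal_id": animal,
                    "group": group,
                    "field_id": f"{animal}_f{f + 1}",
                    "cell_id": np.arange(n),
                    "n_beads": counts,
                }))
    return pd.concat(rows, ignore_index=True)


def generate_composition(params: SimulationParams):
    """Multinomial cell-type counts per sample with a planted genotype effect.

    Returns a samples x cell-types count table and a sample -> genotype map,
    the input of the proportion ANOVA.
    """
    rng = params._rng(_STREAM_COMPOSITION)
    n_types = {len(v) for v in params.composition_by_group.values()}
    if len(n_types) != 1:
        raise ValueError("all groups must declare the same number of cell types")
    k = n_types.pop()
    cell_types = [f"type{i + 1}" for i in range(k)]
    counts, genotypes, sample_ids = [], [], []
    for group, probs in params.composition_by_group.items():
        for s in range(params.n_samples_per_group):
            counts.append(rng.multinomial(params.n_cells_per_sample, probs))
            genotypes.append(group)
            sample_ids.append(f"{group}_s{s + 1}")
    table = pd.DataFrame(counts, index=sample_ids, columns=cell_types)
    genotype_map = pd.Series(genotypes, index=sample_ids, name="genotype")
    return table, genotype_map


def generate_deg_tables(params: SimulationParams):
    """Two DEG tables whose significant sets have controlled sizes and overlap.

    Significance follows the downstream filter (log2FC > 0.25 and FDR < 0.01
    strictly).  ``deg_set_sizes = (|A|, |B|, |A n B|)`` fixes the reference
    set, the study set and their intersection; both tables also carry decoy
    genes that fail the filter, including boundary decoys sitting exactly at
    the thresholds.
    """
    rng = params._rng(_STREAM_DEGS)
    n_ref, n_study, n_shared = params.deg_set_sizes

    shared = [f"SHARED{i:04d}" for i in range(n_shared)]
    ref_only = [f"REFONLY{i:04d}" for i in range(n_ref - n_shared)]
    study_only = [f"STUDYONLY{i:04d}" for i in range(n_study - n_shared)]
    decoys = [f"DECOY{i:04d}" for i in range(params.n_decoy_genes)]

    def sig_row(rng):
        return rng.uniform(0.3, 3.0), rng.uniform(0.0, 0.009)

    def nonsig_row(rng):
        if rng.random() < 0.5:  # fails the fold-change filter
            return rng.uniform(-0.5, 0.25), rng.uniform(0.0, 1.0)
        return rng.uniform(0.3, 3.0), rng.uniform(0.02, 1.0)  # fails FDR

    def build(sig_genes, nonsig_genes):
        genes, lfc, fdr = [], [], []
        for g in sig_genes:
            l, f = sig_row(rng)
            genes.append(g); lfc.append(l); fdr.append(f)
        for g in nonsig_genes:
            l, f = nonsig_row(rng)
            genes.append(g); lfc.append(l); fdr.append(f)
        # boundary decoys: exactly at the strict thresholds, must be excluded
        genes += ["BOUNDARY_LFC", "BOUNDARY_FDR"]
        lfc += [0.25, 1.0]
        fdr += [0.001, 0.01]
        return pd.DataFrame({"gene": genes, "log2fc": lfc, "fdr": fdr})

    reference = build(shared + ref_only, study_only + decoys)
    study = build(shared + study_only, ref_only + decoys)
    return reference, study
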