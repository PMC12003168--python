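"""File round-trips for the formats the pipelines exchange.

Images travel as single-channel TIFF with the pixel size stored in the TIFF
resolution tags and mirrored in a JSON sidecar; count matrices as Matrix
Market plus TSV feature/barcode/label files; everything else as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import tifffile

from .imgops import ChannelImage, LabelMap

__all__ = [
    "write_channel_tiff", "read_channel_tiff",
    "write_labels_tiff", "read_labels_tiff",
    "write_counts_mtx", "read_counts_mtx",
]


def write_channel_tiff(path, img: ChannelImage, dtype=np.uint16) -> None:
    """Write one channel as TIFF; pixel size goes into the resolution tags
    (pixels per centimetre) and a `<path>.json` sidecar in micrometres."""
    path = Path(path)
    px = img.pixels
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        px = np.clip(np.round(px), info.min, info.max).astype(dtype)
    else:
        px = px.astype(dtype)
    px_per_cm = 1e4 / img.pixel_size
    tifffile.imwrite(path, px, resolution=(px_per_cm, px_per_cm),
                     resolutionunit="CENTIMETER")
    sidecar = {"pixel_size_um": img.pixel_size, "name": img.name}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def _pixel_size_from(path: Path, pixel_size: float | None) -> float:
    sidecar = Path(str(path) + ".json")
    if pixel_size is not None:
        return pixel_size
    if sidecar.exists():
        return float(json.loads(sidecar.read_text())["pixel_size_um"])
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            if num:
                return 1e4 * den / num
    raise ValueError(f"{path}: no pixel size in sidecar or TIFF tags; "
                     "pass pixel_size explicitly")


def read_channel_tiff(path, pixel_size: float | None = None,
                      name: str | None = None) -> ChannelImage:
    """Read a channel TIFF; an explicit ``pixel_size`` wins over metadata."""
    path = Path(path)
    px = tifffile.imread(path).astype(float)
    ps = _pixel_size_from(path, pixel_size)
    if name is None:
        sidecar = Path(str(path) + ".json")
        name = (json.loads(sidecar.read_text()).get("name", path.stem)
                if sidecar.exists() else path.stem)
    return ChannelImage(px, ps, name)


def write_labels_tiff(path, labels: LabelMap) -> None:
    if labels.n_labels > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels do not fit 16-bit TIFF")
    write_channel_tiff(path, ChannelImage(labels.labels.astype(float),
                                          labels.pixel_size, "labels"))


def read_labels_tiff(path, pixel_size: float | None = None) -> LabelMap:
    img = read_channel_tiff(path, pixel_size)
    return LabelMap(img.pixels.astype(np.int32), img.pixel_size)


def write_counts_mtx(outdir, adata: ad.AnnData) -> None:
    """Write genes x cells Matrix Market plus features/barcodes/obs TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = adata.X
    x = sp.csc_matrix(x.T if sp.issparse(x) else np.asarray(x).T)
    scipy.io.mmwrite(outdir / "matrix.mtx", x)
    adata.var.to_csv(outdir / "features.tsv", sep="\t")
    adata.obs.to_csv(outdir / "barcodes.tsv", sep="\t")


def read_counts_mtx(indir) -> ad.AnnData:
    indir = Path(indir)
    x = sp.csr_matrix(scipy.io.mmread(indir / "matrix.mtx")).T
    var = pd.read_csv(indir / "features.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(indir / "barcodes.tsv", sep="\t", index_col=0)
    if "mito" in var:
        var["mito"] = var["mito"].astype(bool)
    if "doublet" in obs:
        obs["doublet"] = obs["doublet"].astype(bool)
    return ad.AnnData(X=x, obs=obs, var=var)
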