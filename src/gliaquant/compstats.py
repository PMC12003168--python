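"""Single-nucleus compositional and signature statistics.

Operates on an :class:`anndata.AnnData` of cells x genes with per-cell
``obs`` columns (``sample_id``, ``genotype``, ``cluster_id``, ``doublet``)
and a per-gene boolean ``var['mito']`` flag.  Covers quality-control
filtering, doublet-cluster removal, cell-type proportion ANOVA with
Holm-Bonferroni adjustment, the kNN/KL neighborhood-variability statistic
with shuffled-label controls, and significance filtering / overlap of
differential-expression tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "qc_filter",
    "doublet_cluster_filter",
    "proportion_anova_holm",
    "KLResult",
    "knn_kl_variability",
    "deg_filter_overlap",
]


def _counts(adata: ad.AnnData) -> np.ndarray:
    x = adata.X
    return x.toarray() if sp.issparse(x) else np.asarray(x)


def qc_filter(
    adata: ad.AnnData,
    min_cells_per_gene: int = 3,
    min_genes: int = 200,
    min_umi: int = 500,
    max_umi: int = 30000,
    max_mito_frac: float = 0.05,
) -> tuple[ad.AnnData, dict]:
    """Standard droplet QC with the strict-inequality conventions.

    Removes genes detected (count > 0) in fewer than ``min_cells_per_gene``
    cells, then — on the gene-reduced matrix — cells expressing fewer than
    ``min_genes`` genes, with fewer than ``min_umi`` or more than
    ``max_umi`` total UMIs, or with a mitochondrial read fraction strictly
    above ``max_mito_frac``.  Returns the filtered AnnData and a report of
    removals per criterion.
    """
    x = _counts(adata)
    detected_in = (x > 0).sum(axis=0)
    gene_keep = detected_in >= min_cells_per_gene
    report = {"genes_removed_low_detection": int((~gene_keep).sum())}

    x2 = x[:, gene_keep]
    mito = adata.var["mito"].to_numpy()[gene_keep] if "mito" in adata.var else \
        np.zeros(x2.shape[1], bool)
    genes_per_cell = (x2 > 0).sum(axis=1)
    umi = x2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, x2[:, mito].sum(axis=1) / np.maximum(umi, 1), 1.0)

    low_genes = genes_per_cell < min_genes
    low_umi = umi < min_umi
    high_umi = umi > max_umi
    high_mito = mito_frac > max_mito_frac
    cell_keep = ~(low_genes | low_umi | high_umi | high_mito)
    report.update(
        cells_removed_low_genes=int(low_genes.sum()),
        cells_removed_low_umi=int(low_umi.sum()),
        cells_removed_high_umi=int(high_umi.sum()),
        cells_removed_high_mito=int(high_mito.sum()),
        cells_removed_total=int((~cell_keep).sum()),
        cells_retained=int(cell_keep.sum()),
        genes_retained=int(gene_keep.sum()),
    )
    if report["cells_retained"] == 0 or report["genes_retained"] == 0:
        raise ValueError(f"QC filtering removed everything: {report}")
    out = adata[cell_keep, gene_keep].copy()
    return out, report


def doublet_cluster_filter(
    obs: pd.DataFrame, threshold: float = 0.5
) -> tuple[pd.DataFrame, list]:
    """Remove whole clusters dominated by flagged doublets.

    A cluster is a doublet cluster if strictly more than ``threshold`` of
    its cells carry the doublet flag; such clusters are dropped entirely,
    all other clusters are kept including their individually flagged cells
    (the rule operates at cluster level, not cell level).
    """
    if not {"cluster_id", "doublet"}.issubset(obs.columns):
        raise ValueError("obs needs 'cluster_id' and 'doublet' columns")
    frac = obs.groupby("cluster_id")["doublet"].mean()
    removed = sorted(frac.index[frac > threshold].tolist())
    retained = obs[~obs["cluster_id"].isin(removed)].copy()
    return retained, removed


def proportion_anova_holm(
    composition: pd.DataFrame, genotype_map: pd.Series
) -> pd.DataFrame:
    """One-way ANOVA of per-sample cell-type proportions across genotypes.

    Per sample, counts are converted to proportions of that sample's total;
    per cell type an F statistic is computed across the genotype groups and
    the family of raw p-values (one per cell type in this call) is adjusted
    by the Holm step-down procedure.  Bartlett (variance homogeneity across
    genotypes) and Shapiro-Wilk (normality of residuals) are reported as
    diagnostics and do not gate the test.
    """
    genotype = genotype_map.loc[composition.index]
    counts_per_group = genotype.value_counts()
    if len(counts_per_group) < 2:
        raise ValueError("need >= 2 genotypes")
    if (counts_per_group < 2).any():
        bad = counts_per_group[counts_per_group < 2].index.tolist()
        raise ValueError(f"genotype(s) {bad} have fewer than 2 samples")
    totals = composition.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive total count")
    props = composition.div(totals, axis=0)

    rows = []
    for cell_type in props.columns:
        by_group = [props.loc[genotype == g, cell_type].to_numpy()
                    for g in counts_per_group.index]
        if np.ptp(np.concatenate(by_group)) == 0:
            f, p = 0.0, 1.0  # no variation at all: no group effect
        else:
            f, p = stats.f_oneway(*by_group)
        try:
            with np.errstate(divide="ignore", invalid="ignore"):
                bart_p = stats.bartlett(*by_group).pvalue
        except ValueError:
            bart_p = np.nan
        resid = np.concatenate([v - v.mean() for v in by_group])
        shapiro_p = stats.shapiro(resid).pvalue if len(np.unique(resid)) > 2 \
            else np.nan
        rows.append({"cell_type": cell_type, "F": f, "p_raw": p,
                     "bartlett_p": bart_p, "shapiro_p": shapiro_p})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out[["cell_type", "F", "p_raw", "p_holm", "bartlett_p", "shapiro_p"]]


@dataclass
class KLResult:
    """Per-cell neighborhood KL divergences and their shuffled controls."""

    kl: np.ndarray                 # nats, per cell
    k: int
    labels: np.ndarray
    control_kl: np.ndarray         # (n_permutations, n_cells)
    n_permutations: int
    seed: int

    @property
    def mean_per_class(self) -> pd.Series:
        return pd.Series(self.kl).groupby(pd.Series(self.labels)).mean()

    @property
    def control_means(self) -> np.ndarray:
        """Mean KL of each shuffled control."""
        return self.control_kl.mean(axis=1) if self.n_permutations else \
            np.empty(0)


def _neighbor_kl(neighbor_labels: np.ndarray, codes: np.ndarray,
                 n_classes: int, q: np.ndarray) -> np.ndarray:
    """KL(p_hat || q) per cell from a (n_cells, k) neighbor-label matrix."""
    n, k = neighbor_labels.shape
    counts = np.zeros((n, n_classes))
    rows = np.repeat(np.arange(n), k)
    np.add.at(counts, (rows, neighbor_labels.ravel()), 1.0)
    p = counts / k
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p / q), 0.0)
    return terms.sum(axis=1)


def knn_kl_variability(
    embedding: np.ndarray,
    labels,
    k: int = 30,
    n_permutations: int = 100,
    seed: int = 0,
) -> KLResult:
    """Entropy-based neighborhood variability of sample mixing.

    For each cell, the label distribution p_hat over its ``k`` Euclidean
    nearest neighbors (self excluded) is compared to the global label
    distribution q by the Kullback-Leibler divergence
    ``KL = Sum_c p_hat_c * ln(p_hat_c / q_c)`` in nats (0*ln 0 := 0).  Cells
    sitting in well-mixed neighborhoods score near zero; cells in
    sample-segregated neighborhoods score up to ``ln(1/q_c)``.  Controls
    recompute the statistic on the same kNN graph after uniformly permuting
    the labels ``n_permutations`` times.
    """
    x = np.asarray(embedding, float)
    labels = np.asarray(labels)
    n = len(x)
    if x.ndim != 2 or len(labels) != n:
        raise ValueError("embedding must be (n_cells, n_dims) matching labels")
    if not k < n:
        raise ValueError("k must be smaller than the number of cells")
    classes, codes = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 label classes")
    q = np.bincount(codes).astype(float) / n

    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    idx = nn.kneighbors(x, return_distance=False)
    # drop self wherever it appears among the k+1 (ties may reorder it)
    neigh = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i][idx[i] != i][:k]
        if len(row) < k:  # self absent (duplicated points): take first k
            row = idx[i][:k]
        neigh[i] = row

    kl = _neighbor_kl(codes[neigh], codes, len(classes), q)

    rng = np.random.default_rng(seed)
    control = np.empty((n_permutations, n), float)
    for p_i in range(n_permutations):
        perm = rng.permutation(codes)
        control[p_i] = _neighbor_kl(perm[neigh], perm, len(classes), q)
    return KLResult(kl, k, labels, control, n_permutations, seed)


def canonicalize_genes(genes) -> pd.Series:
    """Trim surrounding whitespace; gene symbol case is preserved."""
    return pd.Series(genes, dtype=str).str.strip()


def deg_filter_overlap(
    study: pd.DataFrame,
    reference,
    logfc_min: float = 0.25,
    fdr_max: float = 0.01,
) -> dict:
    """Significance-filter DEG tables and intersect their gene sets.

    A gene is significant iff ``log2fc > logfc_min`` and ``fdr < fdr_max``,
    both strictly.  ``reference`` may be a second DEG table (filtered the
    same way) or an already-filtered gene collection.  Matching is by exact
    symbol after whitespace trimming; duplicated symbols raise.  Returns the
    three overlap counts and the sorted gene lists.
    """
    def filter_table(tab: pd.DataFrame) -> set:
        genes = canonicalize_genes(tab["gene"])
        dup = genes[genes.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene symbols: {sorted(set(dup))[:10]}")
        sig = (tab["log2fc"].to_numpy() > logfc_min) & \
              (tab["fdr"].to_numpy() < fdr_max)
        return set(genes[sig])

    study_set = filter_table(study)
    if isinstance(reference, pd.DataFrame):
        ref_set = filter_table(reference)
    else:
        ref = canonicalize_genes(list(reference))
        if ref.duplicated().any():
            raise ValueError("duplicate gene symbols in reference set")
        ref_set = set(ref)

    shared = study_set & ref_set
    return {
        "n_shared": len(shared),
        "n_ref_only": len(ref_set - shared),
        "n_study_only": len(study_set - shared),
        "shared_genes": sorted(shared),
        "ref_only_genes": sorted(ref_set - shared),
        "study_only_genes": sorted(study_set - shared),
    }
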