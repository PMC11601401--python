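"""Spot-level QC, normalization, feature selection and layer clustering.

The stages mirror a standard Visium workflow: section- and spot-level
count-based QC, library-size log-normalization, highly-variable-gene
selection intersected with layer markers, PCA with per-section batch
centering, and a Potts-regularized iterated-conditional-modes clustering
of the hex lattice into six cortical layers plus white matter.  The batch
step aligns section means on every principal component; the clustering
couples each spot to its hexagonal neighbours with smoothing strength
gamma, which regularises the layer bands spatially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .config import LAYER_NAMES

MIN_SECTION_MEDIAN_UMI = 2000.0
MIN_SECTION_MEDIAN_GENES = 1000.0
MIN_SECTION_SPOTS = 1000
MIN_SPOT_GENES = 500
MIN_SPOT_UMI = 1000
HEX_NEIGHBOR_TOLERANCE = 1.2  # neighbours at distance <= 1.2 x pitch


@dataclass
class QCReport:
    """Per-section QC medians and the retain/remove bookkeeping."""

    section_stats: pd.DataFrame
    retained_sections: list[str] = field(default_factory=list)
    removed_sections: dict[str, str] = field(default_factory=dict)


def _section_counts(section: ad.AnnData) -> np.ndarray:
    X = section.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def filter_sections(
    sections: list[ad.AnnData],
    min_median_umi: float = MIN_SECTION_MEDIAN_UMI,
    min_median_genes: float = MIN_SECTION_MEDIAN_GENES,
    min_spots: int = MIN_SECTION_SPOTS,
) -> tuple[list[ad.AnnData], QCReport]:
    """Drop low-quality sections (median UMI, median genes, spot count)."""
    retained, stats_rows = [], []
    report = QCReport(section_stats=pd.DataFrame())
    for section in sections:
        X = _section_counts(section)
        in_tissue = section.obs.get("in_tissue", pd.Series(True, index=section.obs_names))
        n_spots = int(np.asarray(in_tissue, dtype=bool).sum())
        med_umi = float(np.median(X.sum(axis=1))) if len(X) else 0.0
        med_genes = float(np.median((X > 0).sum(axis=1))) if len(X) else 0.0
        sid = str(section.obs["section_id"].iloc[0]) if len(section.obs) else "empty"
        reasons = []
        if med_umi < min_median_umi:
            reasons.append(f"median UMI {med_umi:g} < {min_median_umi:g}")
        if med_genes < min_median_genes:
            reasons.append(f"median genes {med_genes:g} < {min_median_genes:g}")
        if n_spots < min_spots:
            reasons.append(f"{n_spots} tissue spots < {min_spots}")
        stats_rows.append(
            {
                "section_id": sid,
                "median_umi": med_umi,
                "median_genes": med_genes,
                "n_spots": n_spots,
                "retained": not reasons,
                "reason": "; ".join(reasons),
            }
        )
        if reasons:
            report.removed_sections[sid] = "; ".join(reasons)
        else:
            report.retained_sections.append(sid)
            retained.append(section)
    report.section_stats = pd.DataFrame(stats_rows)
    return retained, report


def filter_spots(
    section: ad.AnnData,
    min_genes: int = MIN_SPOT_GENES,
    min_umi: int = MIN_SPOT_UMI,
) -> ad.AnnData:
    """Flag and drop spots with too few detected genes or UMIs."""
    X = _section_counts(section)
    genes = (X > 0).sum(axis=1)
    umis = X.sum(axis=1)
    keep = (genes >= min_genes) & (umis >= min_umi)
    out = section[np.asarray(keep)].copy()
    out.obs["n_genes_detected"] = genes[np.asarray(keep)]
    out.obs["n_umis"] = umis[np.asarray(keep)]
    return out


def lognormalize(adata: ad.AnnData, layer: str = "lognorm") -> ad.AnnData:
    """log2(count / size_factor + 1) with size factors scaled to mean 1."""
    X = _section_counts(adata).astype(float)
    lib = X.sum(axis=1)
    if (lib <= 0).any():
        raise AssertionError("zero-library spot present; run spot QC first")
    sf = lib / lib.mean()
    adata.layers[layer] = np.log2(X / sf[:, None] + 1.0)
    return adata


def select_features(
    adata: ad.AnnData,
    markers: list[str],
    n_hvg: int = 10000,
    layer: str = "lognorm",
) -> list[str]:
    """Top-``n_hvg`` genes by excess variance, intersected with markers.

    The mean-variance trend is a quadratic least-squares fit of per-gene
    variance on mean of the normalized values; genes are ranked by the
    residual from that trend.
    """
    values = np.asarray(adata.layers[layer])
    mean = values.mean(axis=0)
    var = values.var(axis=0)
    design = np.column_stack([np.ones_like(mean), mean, mean**2])
    coef, *_ = np.linalg.lstsq(design, var, rcond=None)
    residual = var - design @ coef
    order = np.argsort(residual)[::-1]
    hvg = set(adata.var_names[order[: min(n_hvg, len(order))]])
    selected = [g for g in dict.fromkeys(markers) if g in hvg]
    if not selected:
        raise ValueError(
            "no overlap between highly variable genes and the marker list; "
            "check that the marker names match the count matrix"
        )
    return selected


def reduce_batch_correct(
    adata: ad.AnnData,
    genes: list[str],
    n_pcs: int = 50,
    layer: str = "lognorm",
    key: str = "X_pca_corrected",
) -> np.ndarray:
    """PCA on the selected genes followed by per-section mean-centering.

    The centering aligns the per-section means of every component (the
    batch contract of Harmony-style correction, in its simplest form).
    """
    values = np.asarray(adata[:, genes].layers[layer])
    n_pcs_eff = min(n_pcs, min(values.shape) - 1)
    if n_pcs_eff < n_pcs:
        import warnings

        warnings.warn(f"requested {n_pcs} PCs, data supports {n_pcs_eff}")
    pcs = PCA(n_components=n_pcs_eff, random_state=0).fit_transform(
        values - values.mean(axis=0)
    )
    sections = adata.obs["section_id"].to_numpy()
    for sid in np.unique(sections):
        mask = sections == sid
        pcs[mask] -= pcs[mask].mean(axis=0)
    adata.obsm[key] = pcs
    return pcs


def hex_adjacency(coords: np.ndarray, pitch: float | None = None) -> list[np.ndarray]:
    """Neighbour lists for a hex lattice (distance <= 1.2 x pitch)."""
    tree = cKDTree(coords)
    if pitch is None:
        d, _ = tree.query(coords, k=2)
        pitch = float(np.median(d[:, 1]))
    pairs = tree.query_pairs(r=HEX_NEIGHBOR_TOLERANCE * pitch, output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in range(len(coords))]
    for i, j in pairs:
        neighbors[i].append(j)
        neighbors[j].append(i)
    return [np.array(sorted(n), dtype=int) for n in neighbors]


def potts_objective(
    x: np.ndarray, labels: np.ndarray, mu: np.ndarray, neighbors, gamma: float
) -> float:
    quad = float(((x - mu[labels]) ** 2).sum())
    same = 0
    for i, nb in enumerate(neighbors):
        same += int((labels[nb[nb > i]] == labels[i]).sum())
    return quad - gamma * same


def spatial_cluster(
    pcs: np.ndarray,
    coords: np.ndarray,
    k: int = 7,
    gamma: float = 2.0,
    n_use: int = 35,
    seed: int = 0,
    max_sweeps: int = 60,
) -> np.ndarray:
    """Potts-regularized ICM clustering on the first ``n_use`` components.

    Minimises  sum_i ||x_i - mu_{z_i}||^2  -  gamma * sum_{i~j} 1[z_i = z_j]
    by sequential label updates (which never increase the objective for
    fixed centroids) alternated with centroid re-estimation, from a k-means
    initialisation.  Components are globally rescaled to unit average
    variance so that gamma acts on a data-independent scale.
    """
    if k > len(pcs):
        raise ValueError(f"k={k} exceeds the number of spots ({len(pcs)})")
    x = np.asarray(pcs[:, : min(n_use, pcs.shape[1])], dtype=float)
    centered = x - x.mean(axis=0)
    scale = np.sqrt((centered**2).sum(axis=1).mean() / x.shape[1])
    x = centered / max(scale, 1e-12)

    neighbors = hex_adjacency(np.asarray(coords, dtype=float))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    labels = km.labels_.copy()
    mu = km.cluster_centers_.copy()

    prev_obj = np.inf
    for _ in range(max_sweeps):
        dist2 = ((x[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
        changed = 0
        for i in range(len(x)):
            nb_labels = labels[neighbors[i]]
            bonus = np.bincount(nb_labels, minlength=k).astype(float)
            cost = dist2[i] - gamma * bonus
            new = int(np.argmin(cost))
            if new != labels[i]:
                labels[i] = new
                changed += 1
        for c in range(k):
            mask = labels == c
            if mask.any():
                mu[c] = x[mask].mean(axis=0)
        obj = potts_objective(x, labels, mu, neighbors, gamma)
        assert obj <= prev_obj + 1e-6, "ICM objective increased"
        if changed == 0:
            break
        prev_obj = obj
    return labels


def map_clusters_to_layers(
    labels: np.ndarray,
    adata: ad.AnnData,
    layer_signatures: pd.DataFrame,
    layer: str = "lognorm",
) -> dict[int, str]:
    """Name clusters by Hungarian matching on signature correlations.

    ``layer_signatures`` is genes x named-layers; each cluster is assigned
    the layer whose signature best correlates with the cluster's mean
    normalized profile, one-to-one.
    """
    clusters = np.unique(labels)
    if len(clusters) != layer_signatures.shape[1]:
        raise ValueError(
            f"{len(clusters)} clusters cannot be matched one-to-one to "
            f"{layer_signatures.shape[1]} layer signatures"
        )
    genes = [g for g in layer_signatures.index if g in set(adata.var_names)]
    sig = layer_signatures.loc[genes]
    values = np.asarray(adata[:, genes].layers[layer])
    profiles = np.vstack([values[labels == c].mean(axis=0) for c in clusters])
    corr = np.corrcoef(np.vstack([profiles, sig.to_numpy().T]))[
        : len(clusters), len(clusters):
    ]
    if not np.isfinite(corr).all():
        raise ValueError("degenerate correlation matrix in cluster naming")
    row, col = linear_sum_assignment(-corr)
    return {int(clusters[r]): str(sig.columns[c]) for r, c in zip(row, col)}


def layer_signatures_from_labels(
    adata: ad.AnnData, label_col: str = "true_layer", layer: str = "lognorm"
) -> pd.DataFrame:
    """Mean normalized profile per labelled layer (genes x layers)."""
    values = np.asarray(adata.layers[layer])
    out = {}
    for name in LAYER_NAMES:
        mask = (adata.obs[label_col] == name).to_numpy()
        if mask.any():
            out[name] = values[mask].mean(axis=0)
    return pd.DataFrame(out, index=adata.var_names)


def preprocess_pipeline(
    sections: list[ad.AnnData],
    markers: list[str],
    n_hvg: int = 10000,
    n_pcs: int = 50,
    n_use: int = 35,
    k: int = 7,
    gamma: float = 2.0,
    seed: int = 0,
    section_qc: dict | None = None,
    spot_qc: dict | None = None,
    layer_signatures: pd.DataFrame | None = None,
) -> ad.AnnData:
    """QC -> normalize -> features -> PCs -> spatial clustering -> naming.

    Returns the pooled AnnData with ``obs['cluster']`` and, when layer
    signatures are given (or a ``true_layer`` column exists to derive them
    from), ``obs['layer']``.  Pass ``section_qc``/``spot_qc`` keyword dicts
    to override the count thresholds for down-scaled data.
    """
    if section_qc is not None:
        sections, _ = filter_sections(sections, **section_qc)
    if spot_qc is not None:
        sections = [filter_spots(s, **spot_qc) for s in sections]
    adata = ad.concat(sections, merge="same", uns_merge=None, index_unique=None)
    adata.obs_names_make_unique()
    lognormalize(adata)
    genes = select_features(adata, markers, n_hvg=n_hvg)
    pcs = reduce_batch_correct(adata, genes, n_pcs=n_pcs)
    coords = adata.obs[["x_um", "y_um"]].to_numpy()
    # cluster per-section jointly: neighbours only exist within a section, so
    # offset section coordinates to keep lattices disjoint
    offsets = pd.factorize(adata.obs["section_id"])[0] * (np.ptp(coords[:, 0]) + 1e5)
    shifted = coords.copy()
    shifted[:, 0] = shifted[:, 0] + offsets
    labels = spatial_cluster(pcs, shifted, k=k, gamma=gamma, n_use=n_use, seed=seed)
    adata.obs["cluster"] = labels
    if layer_signatures is None and "true_layer" in adata.obs:
        layer_signatures = layer_signatures_from_labels(adata)
    if layer_signatures is not None and layer_signatures.shape[1] == len(
        np.unique(labels)
    ):
        mapping = map_clusters_to_layers(labels, adata, layer_signatures)
        adata.obs["layer"] = [mapping[int(c)] for c in labels]
    return adata
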