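"""Response-pattern analytics over the gene x condition fold-change matrix.

Builds the response profile (per-condition log2 FC vectors per gene) and the
global summaries around it: Spearman correlation between condition
responses, hierarchical clustering of conditions (distance 1 - rho) and
genes (Euclidean, average linkage), principal-component response vectors
(control group mean -> cytokine group mean in PC1/PC2), medoid
representative selection, Chernoff-face parameter mapping for 15
representative genes, and Mahalanobis coverage ellipses for bivariate FC
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .de import cpm

#: feature order and color groups of the 15-gene face mapping
FACE_FEATURES = (
    "face_height", "face_width", "face_structure", "mouth_height",
    "mouth_width", "smiling", "eye_height", "eye_width", "hair_height",
    "hair_width", "hair_style", "nose_height", "nose_width", "ear_width",
    "ear_height",
)
FACE_COLOR_GROUPS = {
    "face": ("face_height", "face_width"),
    "lips": ("face_height", "face_width", "face_structure"),
    "eyes": ("eye_height", "eye_width"),
    "hair": ("hair_height", "hair_width", "hair_style"),
    "nose": ("nose_height", "nose_width"),
    "ears": ("ear_width", "ear_height"),
}


def build_response_profile(de_tables: dict, gene_filter=None,
                           filter_p=0.05, filter_fc_min=1.50,
                           filter_fc_max=0.67, apply_filter=False):
    """Assemble the gene x condition log2 FC matrix from per-condition DE
    tables.

    ``de_tables`` maps condition label -> DE table (gene_id index, columns
    log2fc / p / q). All conditions must share the gene universe. With
    ``apply_filter`` the matrix is restricted to genes passing
    (p < filter_p and FC > filter_fc_min or FC < filter_fc_max) in at least
    one condition; ``gene_filter`` restricts to an explicit gene list
    instead.
    """
    labels = list(de_tables)
    if not labels:
        raise ValueError("no DE tables supplied")
    universe = de_tables[labels[0]].index
    for lab in labels[1:]:
        other = de_tables[lab].index
        if len(other) != len(universe) or set(other) != set(universe):
            extra = set(other).symmetric_difference(universe)
            raise ValueError(
                f"gene universes differ (condition {lab!r}; e.g. "
                f"{sorted(extra)[:5]})"
            )
    profile = pd.DataFrame(
        {lab: de_tables[lab]["log2fc"].reindex(universe) for lab in labels},
        index=universe,
    )
    if gene_filter is not None:
        profile = profile.loc[[g for g in universe if g in set(gene_filter)]]
    elif apply_filter:
        keep = np.zeros(len(universe), dtype=bool)
        for lab in labels:
            t = de_tables[lab].reindex(universe)
            fc = 2.0 ** t["log2fc"].to_numpy()
            keep |= (t["p"].to_numpy() < filter_p) & (
                (fc > filter_fc_min) | (fc < filter_fc_max)
            )
        profile = profile.loc[keep]
    return profile


def response_correlation(profile: pd.DataFrame):
    """Condition x condition Spearman correlation (average ranks for ties).

    Constant columns yield missing correlations.
    """
    if len(profile) < 3:
        raise ValueError("need at least 3 genes")
    cols = list(profile.columns)
    n = len(cols)
    out = pd.DataFrame(np.eye(n), index=cols, columns=cols)
    const = {c: profile[c].nunique() <= 1 for c in cols}
    for i in range(n):
        for j in range(i + 1, n):
            if const[cols[i]] or const[cols[j]]:
                rho = np.nan
            else:
                rho = sps.spearmanr(profile[cols[i]], profile[cols[j]])[0]
            out.iloc[i, j] = out.iloc[j, i] = rho
    for c in cols:
        if const[c]:
            out.loc[c, c] = np.nan
    return out


def cluster_conditions(correlations: pd.DataFrame):
    """Average-linkage dendrogram on distance 1 - Spearman rho.

    Returns the scipy linkage matrix; leaf order follows the correlation
    matrix columns.
    """
    if correlations.isna().any().any():
        raise ValueError("correlation matrix contains missing values")
    d = 1.0 - correlations.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.maximum((d + d.T) / 2.0, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def cluster_genes(profile: pd.DataFrame, k, linkage="average",
                  metric="euclidean"):
    """Agglomerative gene clustering cut at ``k`` clusters.

    Returns a Series gene -> cluster id (1..k).
    """
    n = len(profile)
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    Z = hierarchy.linkage(profile.to_numpy(dtype=float), method=linkage,
                          metric=metric)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=profile.index, name="cluster")


def pc_response_vectors(expression: pd.DataFrame, design: pd.DataFrame,
                        control="CTL", n_components=2):
    """Per-(treatment, time) arrows in PC space.

    PCs are computed over samples from the centered log-scale expression
    matrix (genes x samples; samples are observations). Each arrow starts at
    the control group's bivariate PC mean at that time and ends at the
    cytokine group's mean.
    """
    design = design.set_index("sample_id", drop=False).loc[
        list(expression.columns)
    ]
    X = expression.to_numpy(dtype=float).T          # samples x genes
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    pc = pd.DataFrame(scores, index=expression.columns,
                      columns=[f"PC{i + 1}" for i in range(n_components)])
    rows = []
    for tm in design["time"].astype(str).unique():
        d_t = design[design["time"].astype(str) == tm]
        ctl_ids = d_t.loc[d_t["treatment"] == control, "sample_id"]
        if len(ctl_ids) == 0:
            raise ValueError(f"no control samples at time {tm!r}")
        start = pc.loc[ctl_ids].mean()
        for trt in d_t["treatment"].unique():
            if trt == control:
                continue
            ids = d_t.loc[d_t["treatment"] == trt, "sample_id"]
            if len(ids) == 0:
                raise ValueError(f"group {trt!r} absent at time {tm!r}")
            end = pc.loc[ids].mean()
            rows.append({"treatment": trt, "time": tm,
                         "start_pc1": start.iloc[0], "start_pc2": start.iloc[1],
                         "end_pc1": end.iloc[0], "end_pc2": end.iloc[1]})
    return pd.DataFrame(rows), pc


def select_representatives(profile: pd.DataFrame, clusters: pd.Series):
    """Exact medoid per cluster under Euclidean distance.

    The representative minimizes the average distance to all other cluster
    members; ties break to the lexicographically smallest gene id.
    """
    reps = {}
    for cl, members in clusters.groupby(clusters):
        genes = sorted(members.index)
        X = profile.loc[genes].to_numpy(dtype=float)
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
        avg = d.sum(axis=1) / max(len(genes) - 1, 1)
        best = int(np.argmin(avg))          # argmin takes the first = lexic. smallest
        reps[cl] = genes[best]
    return pd.Series(reps, name="representative")


@dataclass
class FaceSpec:
    """Chernoff-face parameters in [0, 1] for one condition."""

    condition: str
    parameters: dict          # feature -> value in [0, 1]
    colors: dict              # color group -> mean mapped value
    gene_map: dict            # feature -> gene id

    def as_series(self):
        return pd.Series(self.parameters, name=self.condition)


def chernoff_mapping(profile: pd.DataFrame, condition, gene_map=None,
                     clip=3.0):
    """Map 15 representative genes' log2 FCs to face parameters.

    log2 FC is clipped to [-clip, clip] then mapped affinely to [0, 1];
    feature-group colors are the mean mapped value of each group's genes.
    ``gene_map`` maps each of the 15 feature names to a gene id; by default
    the first 15 profile rows are used in feature order.
    """
    if gene_map is None:
        if len(profile) < 15:
            raise ValueError("need 15 genes for the face mapping")
        gene_map = dict(zip(FACE_FEATURES, profile.index[:15]))
    missing = [g for g in gene_map.values() if g not in profile.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} missing from profile")
    params = {}
    for feat in FACE_FEATURES:
        v = float(np.clip(profile.at[gene_map[feat], condition], -clip, clip))
        params[feat] = (v + clip) / (2.0 * clip)
    colors = {
        grp: float(np.mean([params[f] for f in feats]))
        for grp, feats in FACE_COLOR_GROUPS.items()
    }
    return FaceSpec(condition=str(condition), parameters=params,
                    colors=colors, gene_map=dict(gene_map))


@dataclass
class Ellipse:
    center: np.ndarray
    axes: np.ndarray          # semi-axis lengths
    angle: float              # radians, first axis vs x-axis
    radius2: float            # squared Mahalanobis radius
    n_inside: int


def mahalanobis_ellipse(x, y, coverage=0.75):
    """Mahalanobis-distance ellipse covering the closest ``coverage``
    fraction of points.

    The squared radius is the floor(coverage*n)-th smallest squared
    Mahalanobis distance from the bivariate mean, so exactly that many
    points lie inside or on the boundary (more under ties). Raises on a
    singular covariance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    pts = np.column_stack([x, y])
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or det <= 1e-300:
        raise ValueError("singular covariance; ellipse undefined")
    inv = np.linalg.inv(cov)
    diff = pts - center
    d2 = np.einsum("ni,ij,nj->n", diff, inv, diff)
    k = int(np.floor(coverage * x.size))
    k = max(k, 1)
    radius2 = float(np.sort(d2)[k - 1])
    evals, evecs = np.linalg.eigh(cov)
    axes = np.sqrt(np.maximum(evals, 0.0) * radius2)
    angle = float(np.arctan2(evecs[1, 1], evecs[0, 1]))
    n_inside = int(np.sum(d2 <= radius2 + 1e-12))
    return Ellipse(center=center, axes=axes[::-1], angle=angle,
                   radius2=radius2, n_inside=n_inside)


def expression_for_patterns(counts, norm_factors=None, detected=None):
    """log2(cpm + 1) matrix used for PCA and variance summaries."""
    mat = np.log2(cpm(counts, norm_factors=norm_factors) + 1.0)
    if detected is not None:
        mat = mat.loc[detected[detected].index]
    return mat
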