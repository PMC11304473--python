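"""Hydrologic clustering of fields from their 17 descriptors.

Fields are grouped with K-means (Lloyd, best of many seeded restarts) on
standardized descriptors, the number of clusters is chosen by mean
silhouette subject to a minimum cluster size, and cluster labels are
renumbered driest (1) to wettest (k) by the centroid's share of the
season flooded (descriptor A1). Diagnostics cover a pseudo-R²
(1 − WCSS/TSS), permutation-based descriptor importance for cluster
membership, ANOVA with Fisher-LSD letters for between-cluster emission
differences, and plain descriptor–emission correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

DEFAULT_RESTARTS = 50
DEFAULT_MIN_SIZE = 3


@dataclass
class Scaling:
    """Per-descriptor mean and sd (ddof=1) used for standardization."""

    mean: pd.Series
    sd: pd.Series

    def inverse(self, Z: pd.DataFrame) -> pd.DataFrame:
        return Z * self.sd + self.mean


@dataclass
class ClusterModel:
    k: int
    centroids: pd.DataFrame            # k x 17, standardized space, index 1..k
    assignments: pd.Series             # field_id -> label 1..k (1 = driest)
    mean_silhouette: float
    pseudo_r2: float
    scaling: Scaling
    inertia: float
    feature_importance: Optional[pd.Series] = None

    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, Scaling]:
    """Zero-mean unit-sd columns (sd with ddof=1); constant columns -> 0."""
    if len(X) < 2:
        raise ValueError("need at least 2 fields to standardize")
    if X.isna().any().any():
        bad = X.index[X.isna().any(axis=1)].tolist()
        raise ValueError(f"missing descriptor values for fields: {bad}")
    mean = X.mean()
    sd = X.std(ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"constant descriptors left at 0: {list(sd.index[zero])}")
    safe_sd = sd.replace(0.0, 1.0)
    Z = (X - mean) / safe_sd
    return Z, Scaling(mean=mean, sd=sd)


def _order_labels_by_wetness(
    raw_labels: np.ndarray, centers_z: np.ndarray, Xz: pd.DataFrame, scaling: Scaling
) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters 1..k ascending in the centroid's unstandardized A1."""
    centers = pd.DataFrame(centers_z, columns=Xz.columns)
    wet_col = "A1" if "A1" in Xz.columns else Xz.columns[0]
    a1 = centers[wet_col] * scaling.sd[wet_col] + scaling.mean[wet_col]
    order = np.argsort(a1.values, kind="stable")  # driest first
    relabel = np.empty(len(order), dtype=int)
    relabel[order] = np.arange(1, len(order) + 1)
    return relabel[raw_labels], centers_z[order]


def kmeans_fit(
    Xz: pd.DataFrame,
    k: int,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    scaling: Optional[Scaling] = None,
) -> ClusterModel:
    """Best-of-restarts Lloyd K-means on standardized descriptors.

    ``scaling`` (from :func:`standardize`) is used to express centroid
    wetness in original units for the driest→wettest label ordering; if
    omitted, an identity scaling is assumed.
    """
    n = len(Xz)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} infeasible for n={n}")
    if scaling is None:
        scaling = Scaling(
            mean=pd.Series(0.0, index=Xz.columns), sd=pd.Series(1.0, index=Xz.columns)
        )
    km = KMeans(
        n_clusters=k, n_init=restarts, max_iter=300, tol=1e-8, random_state=seed
    ).fit(Xz.values)
    labels, centers = _order_labels_by_wetness(km.labels_, km.cluster_centers_, Xz, scaling)
    tss = float(((Xz.values - Xz.values.mean(axis=0)) ** 2).sum())
    pseudo_r2 = 1.0 - km.inertia_ / tss if tss > 0 else 0.0
    if 2 <= k < n:
        sil = float(silhouette_score(Xz.values, labels, metric="euclidean"))
    else:
        sil = float("nan")
    return ClusterModel(
        k=k,
        centroids=pd.DataFrame(centers, index=range(1, k + 1), columns=Xz.columns),
        assignments=pd.Series(labels, index=Xz.index, name="cluster"),
        mean_silhouette=sil,
        pseudo_r2=float(np.clip(pseudo_r2, 0.0, 1.0)),
        scaling=scaling,
        inertia=float(km.inertia_),
    )


def select_k(
    Xz: pd.DataFrame,
    k_range: Sequence[int] = range(2, 9),
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    min_size: int = DEFAULT_MIN_SIZE,
    scaling: Optional[Scaling] = None,
) -> tuple[int, pd.Series]:
    """Choose k maximizing mean silhouette among solutions whose every
    cluster has at least ``min_size`` members; ties go to the smallest k.

    Returns the chosen k and the per-k mean silhouettes (NaN where the
    min-size constraint ruled a solution out).
    """
    sils = {}
    feasible = {}
    for k in k_range:
        if k < 2 or k > len(Xz) // 1:
            continue
        model = kmeans_fit(Xz, k, restarts=restarts, seed=seed, scaling=scaling)
        ok = model.cluster_sizes().min() >= min_size
        sils[k] = model.mean_silhouette if ok else float("nan")
        if ok:
            feasible[k] = model.mean_silhouette
    if not feasible:
        raise ValueError("no feasible k: every solution violates the minimum cluster size")
    best = max(feasible.values())
    chosen = min(k for k, s in feasible.items() if s >= best - 1e-12)
    return chosen, pd.Series(sils, name="mean_silhouette")


def feature_importance(
    model: ClusterModel,
    Xz: pd.DataFrame,
    permutations: int = 200,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance of each descriptor for cluster membership.

    Importance of a descriptor is the mean (over permutations) fraction
    of fields whose nearest-centroid assignment changes when that column
    is randomly permuted, as in misclassification-based cluster feature
    importance.
    """
    rng = np.random.default_rng(seed)
    X = Xz.values
    centers = model.centroids.values  # rows ordered by label 1..k
    base = np.argmin(
        ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    imps = pd.Series(0.0, index=Xz.columns)
    for _ in range(permutations):
        perm = rng.permutation(len(X))
        for j, col in enumerate(Xz.columns):
            Xp = X.copy()
            Xp[:, j] = X[perm, j]
            new = np.argmin(
                ((Xp[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
            )
            imps[col] += np.mean(new != base)
    imps /= permutations
    model.feature_importance = imps
    return imps


@dataclass
class AnovaLsdResult:
    f_stat: float
    p_value: float
    means: pd.Series            # cluster -> mean, descending
    letters: pd.Series          # cluster -> compact letter display
    mse: float
    alpha: float


def anova_lsd(
    values: pd.Series,
    assignments: pd.Series,
    alpha: float = 0.05,
) -> AnovaLsdResult:
    """One-way ANOVA plus Fisher's (protected) LSD compact letter display.

    Pairwise LSD tests use the pooled error mean square and are applied
    only when the ANOVA is significant at ``alpha``; otherwise all
    clusters share one letter. Clusters sharing no letter differ at
    ``alpha``. Letters are assigned in order of descending mean.
    """
    df = pd.DataFrame({"y": values, "g": assignments}).dropna()
    sizes = df.groupby("g").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"clusters with a single member excluded from ANOVA/LSD: {small}")
        df = df[~df["g"].isin(small)]
        sizes = df.groupby("g").size()
    if len(sizes) < 2:
        raise ValueError("need at least 2 clusters with >= 2 members")

    groups = [g["y"].values for _, g in df.groupby("g")]
    grand = df["y"].mean()
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    df_b, df_w = len(groups) - 1, len(df) - len(groups)
    mse = sse / df_w
    if sse == 0 and ssb == 0:
        f_stat, p_value = 0.0, 1.0
    elif mse == 0:
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat = (ssb / df_b) / mse
        p_value = float(stats.f.sf(f_stat, df_b, df_w))

    means = df.groupby("g")["y"].mean().sort_values(ascending=False)
    labels = list(means.index)

    def differs(a, b) -> bool:
        if p_value >= alpha:
            return False
        se = np.sqrt(mse * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            return means[a] != means[b]
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df_w)
        return abs(means[a] - means[b]) > tcrit * se

    # insert-and-absorb compact letter display on the desc-sorted means
    groups_cld: list[set] = []
    for g in labels:
        placed = False
        for s in groups_cld:
            if all(not differs(g, h) for h in s):
                s.add(g)
                placed = True
        if not placed:
            new = {g}
            # absorb earlier non-different members to keep letters contiguous
            for h in labels[: labels.index(g)]:
                if not differs(g, h):
                    new.add(h)
            groups_cld.append(new)
    # drop letter-groups that are subsets of others
    groups_cld = [
        s for i, s in enumerate(groups_cld)
        if not any(s < t for j, t in enumerate(groups_cld) if i != j)
    ]
    letters = {g: "" for g in labels}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", groups_cld):
        for g in labels:
            if g in s:
                letters[g] += letter
    return AnovaLsdResult(
        f_stat=float(f_stat),
        p_value=float(p_value),
        means=means,
        letters=pd.Series(letters).loc[labels],
        mse=float(mse),
        alpha=alpha,
    )


def descriptor_emission_correlations(
    descriptors: pd.DataFrame,
    emissions: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson correlation of each descriptor with seasonal CH4 and N2O.

    Constant descriptors yield NaN (undefined, not zero). Requires at
    least 3 matched fields after listwise dropping.
    """
    em = emissions.set_index("field_id") if "field_id" in emissions.columns else emissions
    merged = descriptors.join(em[["ch4_kg_ha", "n2o_g_ha"]], how="inner").dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 matched fields")
    out = {}
    for col in descriptors.columns:
        x = merged[col].values
        row = {}
        for gas in ("ch4_kg_ha", "n2o_g_ha"):
            y = merged[gas].values
            if np.std(x) == 0 or np.std(y) == 0:
                row[gas] = float("nan")
            else:
                row[gas] = float(stats.pearsonr(x, y)[0])
        out[col] = row
    return pd.DataFrame.from_dict(out, orient="index").rename(
        columns={"ch4_kg_ha": "ch4", "n2o_g_ha": "n2o"}
    )
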