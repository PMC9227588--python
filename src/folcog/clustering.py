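"""K-means subgrouping of folate/B12 status with stability assessment.

The four biomarkers (RBC folate, serum total folate, 5MeTHF, vitamin B12)
are min-max normalised to [0, 1], partitioned by K-means (Lloyd's
algorithm, k-means++ seeding, many independent restarts keeping the best
within-cluster sum of squares), with K chosen by the Calinski-Harabasz
score over a candidate range. Cluster reproducibility is assessed
clusterboot-style: bootstrap resamples are re-scaled and re-clustered at
the same K, and each original cluster is scored by its maximum Jaccard
similarity against the resample clusters (restricted to records present
in the resample); a cluster "dissolves" in a resample when that Jaccard
falls below 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

CLUSTER_FEATURES = ("rbc_folate", "serum_total_folate", "five_methyl_thf", "vitamin_b12")

#: Paper-scale restart count; desk-scale analyses pass a smaller value.
DEFAULT_RESTARTS = 10_000
DEFAULT_BOOTSTRAP = 2_000
DISSOLUTION_THRESHOLD = 0.5


@dataclass(frozen=True)
class ScalerParams:
    value_min: np.ndarray
    value_max: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.value_min) / (self.value_max - self.value_min)


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray  # in normalized space
    assignments: np.ndarray  # 1..K
    wcss: float
    ch_score: float
    restarts: int
    seed: int


@dataclass
class StabilityReport:
    b: int
    mean_jaccard: np.ndarray  # per original cluster (1..K order)
    dissolution_counts: np.ndarray
    seed: int


def minmax_fit_transform(values) -> tuple[ScalerParams, np.ndarray]:
    """Scale each column to [0, 1]: (value - min) / (max - min)."""
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[:, None]
    vmin = v.min(axis=0)
    vmax = v.max(axis=0)
    if np.any(vmax <= vmin):
        flat = np.where(vmax <= vmin)[0]
        raise ValueError(f"constant feature(s) cannot be min-max scaled: columns {flat}")
    params = ScalerParams(value_min=vmin, value_max=vmax)
    return params, params.transform(v)


def kmeans_fit(matrix, k: int, restarts: int = DEFAULT_RESTARTS, seed: int = 0) -> ClusterModel:
    """Best-of-``restarts`` K-means partition (Lloyd, k-means++ seeding).

    Deterministic given ``seed``. Lloyd iterations are capped at 300 with
    tolerance 1e-6; empty clusters are re-seeded internally by the solver.
    """
    X = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} records, got {X.shape[0]}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=300,
        tol=1e-6,
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    labels = km.labels_.astype(int) + 1
    ch = calinski_harabasz(X, labels)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        assignments=labels,
        wcss=float(km.inertia_),
        ch_score=ch,
        restarts=restarts,
        seed=seed,
    )


def calinski_harabasz(matrix, assignments) -> float:
    """Calinski-Harabasz score: [B/(K-1)] / [W/(n-K)].

    B and W are the between- and within-cluster sums of squares. A perfect
    partition (W = 0) returns +inf.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Calinski-Harabasz requires at least 2 clusters")
    wcss = 0.0
    for u in uniq:
        sub = X[labels == u]
        wcss += float(((sub - sub.mean(axis=0)) ** 2).sum())
    if wcss <= 0.0:
        return float("inf")
    return float(calinski_harabasz_score(X, labels))


def select_k(
    matrix,
    k_range=range(2, 9),
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Fit each K and return the CH-maximising K with the full score table.

    Ties break to the smaller K.
    """
    rows = []
    models = {}
    for k in k_range:
        m = kmeans_fit(matrix, k, restarts=restarts, seed=seed)
        models[k] = m
        rows.append({"k": k, "ch_score": m.ch_score, "wcss": m.wcss})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["ch_score"].idxmax(), "k"])  # idxmax takes first max
    return best, table


def jaccard(set_a, set_b) -> float:
    """|A intersect B| / |A union B|; undefined (error) when both are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ValueError("Jaccard similarity of two empty sets is undefined")
    return len(a & b) / len(union)


def bootstrap_stability(
    matrix,
    model: ClusterModel,
    b: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    restarts: int = 10,
    rescale: bool = True,
) -> StabilityReport:
    """Clusterboot-style bootstrap Jaccard stability of an existing partition.

    Each of ``b`` resamples (cases drawn with replacement at full n) is
    min-max re-scaled (``rescale=True``, the per-dataset normalisation
    definition) and re-clustered at ``model.k``; every original cluster is
    scored by its maximum Jaccard against the resample clusters over the
    record ids present in the resample.
    """
    if b < 1:
        raise ValueError("b must be >= 1")
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    orig_sets = [set(np.where(model.assignments == k)[0]) for k in range(1, model.k + 1)]
    sums = np.zeros(model.k)
    dissolved = np.zeros(model.k, dtype=int)
    for rep in range(b):
        idx = rng.integers(0, n, size=n)
        present = set(idx.tolist())
        Xb = X[idx]
        if rescale:
            _, Xb = minmax_fit_transform(Xb)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        mb = kmeans_fit(Xb, model.k, restarts=restarts, seed=sub_seed)
        boot_sets = [
            set(np.unique(idx[mb.assignments == k]).tolist()) for k in range(1, model.k + 1)
        ]
        for i, orig in enumerate(orig_sets):
            o = orig & present
            if not o:
                continue
            best = max(jaccard(o, bs) for bs in boot_sets if bs)
            sums[i] += best
            if best < DISSOLUTION_THRESHOLD:
                dissolved[i] += 1
    return StabilityReport(
        b=b, mean_jaccard=sums / b, dissolution_counts=dissolved, seed=seed
    )


def cluster_phenotype(
    cohort_df: pd.DataFrame,
    assignments,
    continuous=None,
    categorical=None,
) -> dict:
    """Per-cluster phenotype tables with ANOVA / chi-square p-values.

    Continuous variables get per-cluster mean (SD, n) and a one-way ANOVA
    p; categoricals get count (%) and a Pearson chi-square p. Clusters too
    small for a variance (< 2 complete values) report missing cells.
    """
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if continuous is None:
        continuous = [
            c for c in (
                "rbc_folate", "serum_total_folate", "five_methyl_thf", "vitamin_b12",
                "mma", "umfa", "age", "bmi",
                "cerad_wl", "cerad_dr", "af", "dsst",
            ) if c in cohort_df.columns
        ]
    if categorical is None:
        categorical = [
            c for c in ("sex", "race_ethnicity", "marital", "education",
                        "smoking", "drinking", "hypertension", "hyperlipidemia",
                        "diabetes") if c in cohort_df.columns
        ]

    cont_rows = []
    for var in continuous:
        row = {"variable": var}
        groups = []
        for u in uniq:
            vals = cohort_df.loc[labels == u, var].dropna().to_numpy(dtype=float)
            if vals.size >= 2:
                row[f"mean_{u}"] = vals.mean()
                row[f"sd_{u}"] = vals.std(ddof=1)
                groups.append(vals)
            else:
                row[f"mean_{u}"] = np.nan
                row[f"sd_{u}"] = np.nan
            row[f"n_{u}"] = vals.size
        if len(groups) >= 2:
            f, p = stats.f_oneway(*groups)
            row["statistic"], row["pvalue"], row["test"] = float(f), float(p), "anova"
        else:
            row["statistic"], row["pvalue"], row["test"] = np.nan, np.nan, "anova"
        cont_rows.append(row)

    cat_rows = []
    for var in categorical:
        tab = pd.crosstab(cohort_df[var], pd.Series(labels, index=cohort_df.index))
        if tab.shape[0] >= 2 and tab.shape[1] >= 2 and (tab.sum(axis=1) > 0).all():
            chi2, p, dof, _ = stats.chi2_contingency(tab, correction=False)
        else:
            chi2, p = np.nan, np.nan
        for level in tab.index:
            row = {"variable": var, "level": level}
            for u in uniq:
                cnt = int(tab.loc[level, u]) if u in tab.columns else 0
                tot = int(tab[u].sum()) if u in tab.columns else 0
                row[f"count_{u}"] = cnt
                row[f"pct_{u}"] = round(100.0 * cnt / tot, 1) if tot else np.nan
            row["statistic"], row["pvalue"], row["test"] = chi2, p, "chi-square"
            cat_rows.append(row)

    return {
        "continuous": pd.DataFrame(cont_rows),
        "categorical": pd.DataFrame(cat_rows),
    }
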