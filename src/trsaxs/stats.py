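"""Downstream ensemble statistics.

Three stages: (1) ensemble-weighted domain-distance means per time point,
(2) hierarchical clustering (Ward linkage, Euclidean distance on
standardized Rg / Ree / fraction features, flat cut at a cophenetic distance
threshold) of selected conformers across conditions and times, and (3) a
condition-comparison battery — Kruskal-Wallis across conditions, pairwise
Dunn post-hoc tests with Benjamini-Hochberg correction, and Hedges' g effect
sizes with the small-sample correction J = 1 - 3/(4(n1+n2)-9).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .eom import EnsembleFitResult
from .pool import ConformerPool, DomainScheme

CLUSTER_THRESHOLD = 2.5
FEATURES = ("rg", "ree", "fraction")


def weighted_domain_distances(
    res: EnsembleFitResult,
    pool: ConformerPool,
    scheme: DomainScheme | None = None,
) -> pd.DataFrame:
    """Ensemble-weighted mean and SD of each domain-pair distance.

    Weights are the selected conformers' fractions within the ensemble.
    Returns a one-row-per-pair frame with columns ``pair, mean_A, sd_A``.
    """
    if res.pool_seed != -1 and res.pool_seed != pool.seed:
        raise ValueError("provenance mismatch between fit result and pool")
    scheme = scheme or DomainScheme()
    w = res.weight_vector(len(pool))
    sel = w > 0
    rows = []
    for name in scheme.pairs:
        d = pool.metrics[name].to_numpy()
        mean = float(np.sum(w[sel] * d[sel]))
        var = float(np.sum(w[sel] * (d[sel] - mean) ** 2))
        rows.append({"pair": name, "mean_A": mean, "sd_A": np.sqrt(var)})
    return pd.DataFrame(rows)


def feature_table(
    results: dict,
    pool: ConformerPool,
) -> pd.DataFrame:
    """Stack selected conformers of many fits into one feature table.

    ``results`` maps ``(condition, time_s)`` to an EnsembleFitResult. One row
    per selected conformer with columns ``condition, time_s, conformer_id,
    rg, ree, fraction``; fractions sum to 1 within each (condition, time).
    """
    rg = pool.metrics.set_index("id")["rg"]
    ree = pool.metrics.set_index("id")["ree"]
    rows = []
    for (cond, t), res in results.items():
        for cid, frac in sorted(res.fractions.items()):
            rows.append({
                "condition": cond, "time_s": float(t), "conformer_id": cid,
                "rg": float(rg.loc[cid]), "ree": float(ree.loc[cid]),
                "fraction": float(frac),
            })
    return pd.DataFrame(rows)


@dataclass
class ClusterModel:
    """Ward-linkage clustering of standardized ensemble features."""

    features: pd.DataFrame          # input rows (unstandardized)
    standardized: np.ndarray        # z-scored feature matrix used for linkage
    linkage: np.ndarray             # scipy linkage matrix
    threshold: float
    assignments: np.ndarray         # 1-based cluster id per row
    k: int
    silhouette: float               # nan when k < 2
    summaries: pd.DataFrame = field(default=None)
    flags: tuple = ()


def cluster_ensembles(
    features: pd.DataFrame,
    t: float = CLUSTER_THRESHOLD,
    weight_mode: str = "fraction-weighted",
    feature_cols=FEATURES,
) -> ClusterModel:
    """Cluster conformer rows by standardized (rg, ree, fraction).

    Ward linkage on Euclidean distances; flat clusters cut the dendrogram at
    cophenetic distance ``t``. Cluster summaries (mean Rg/Ree, per-condition
    occupancy) use fraction weights when ``weight_mode="fraction-weighted"``.
    """
    if len(features) < 10:
        raise ValueError("need >= 10 rows to cluster")
    if weight_mode not in ("raw", "fraction-weighted"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    X = features.loc[:, list(feature_cols)].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    flags = ()
    constant = sd <= 1e-12 * (np.abs(mu) + 1.0)
    if np.all(constant):
        assignments = np.ones(len(X), dtype=int)
        return ClusterModel(
            features=features, standardized=np.zeros_like(X),
            linkage=np.empty((0, 4)), threshold=t,
            assignments=assignments, k=1, silhouette=np.nan,
            summaries=_summarize(features, assignments, weight_mode),
            flags=("all-rows-identical",),
        )
    Z = (X - mu) / np.where(constant, 1.0, sd)
    link = hierarchy.linkage(Z, method="ward", metric="euclidean")
    assignments = hierarchy.fcluster(link, t=t, criterion="distance")
    k = int(assignments.max())
    if k >= 2 and k < len(X):
        sil = float(silhouette_score(Z, assignments))
    else:
        sil = np.nan
        flags += ("silhouette-undefined",)
    return ClusterModel(
        features=features, standardized=Z, linkage=link, threshold=t,
        assignments=assignments, k=k, silhouette=sil,
        summaries=_summarize(features, assignments, weight_mode), flags=flags,
    )


def _summarize(features, assignments, weight_mode):
    df = features.reset_index(drop=True).copy()
    df["cluster"] = assignments
    w = df["fraction"].to_numpy() if weight_mode == "fraction-weighted" else np.ones(len(df))
    rows = []
    for cid, grp in df.groupby("cluster"):
        gw = w[grp.index.to_numpy()]
        gw = gw / gw.sum()
        row = {
            "cluster": int(cid),
            "n_rows": len(grp),
            "mean_rg_A": float(np.sum(gw * grp["rg"])),
            "mean_ree_A": float(np.sum(gw * grp["ree"])),
        }
        if "condition" in df.columns:
            for cond, sub in df.groupby("condition"):
                in_cluster = sub["cluster"] == cid
                wc = sub["fraction"] if weight_mode == "fraction-weighted" else pd.Series(1.0, index=sub.index)
                row[f"occupancy_{cond}"] = float(wc[in_cluster].sum() / wc.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def dunn_test(groups: dict) -> pd.DataFrame:
    """Pairwise Dunn z-tests on pooled ranks with tie correction.

    ``groups`` maps label -> 1-D sample. Returns rows
    ``(group1, group2, z, p)`` with two-sided p-values (unadjusted).
    """
    labels = list(groups)
    all_vals = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    n = len(all_vals)
    ranks = sps.rankdata(all_vals)
    # tie correction term: sum over tie groups of (t^3 - t)
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    pos = 0
    mean_ranks, sizes = {}, {}
    for g in labels:
        m = len(groups[g])
        mean_ranks[g] = float(ranks[pos : pos + m].mean())
        sizes[g] = m
        pos += m
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        n1, n2 = sizes[g1], sizes[g2]
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))) * (1.0 / n1 + 1.0 / n2)
        )
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": float(z), "p": float(p)})
    return pd.DataFrame(rows)


def hedges_g(x, y) -> float:
    """Hedges' g with small-sample correction J = 1 - 3/(4(n1+n2)-9)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    s_pooled = np.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        return 0.0
    d = (x.mean() - y.mean()) / s_pooled
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(J * d)


@dataclass
class StatReport:
    """Condition-comparison battery for each feature family."""

    kruskal: pd.DataFrame    # feature, H, p
    pairwise: pd.DataFrame   # feature, group1, group2, p, q, g, significant
    alpha: float = 0.05
    effect_threshold: float = 0.8


def condition_stats(
    features: pd.DataFrame,
    alpha: float = 0.05,
    effect_threshold: float = 0.8,
    feature_cols=FEATURES,
    min_group: int = 3,
) -> StatReport:
    """Kruskal-Wallis across conditions per feature, Dunn post-hoc pairs with
    BH adjustment per feature family, and Hedges' g for every pair.

    Pairs are flagged significant when q < alpha and |g| > effect_threshold.
    Conditions with fewer than ``min_group`` rows are excluded with a warning.
    """
    import warnings

    conds = {}
    for cond, grp in features.groupby("condition"):
        if len(grp) < min_group:
            warnings.warn(f"condition {cond!r} has < {min_group} rows; excluded")
            continue
        conds[cond] = grp
    if len(conds) < 2:
        raise ValueError("need >= 2 conditions with enough rows")
    kw_rows, pair_rows = [], []
    for feat in feature_cols:
        samples = {c: g[feat].to_numpy(dtype=float) for c, g in conds.items()}
        H, p = sps.kruskal(*samples.values())
        kw_rows.append({"feature": feat, "H": float(H), "p": float(p)})
        dunn = dunn_test(samples) if p < alpha else None
        for g1, g2 in itertools.combinations(samples, 2):
            if dunn is not None:
                sel = (dunn["group1"] == g1) & (dunn["group2"] == g2)
                p_pair = float(dunn.loc[sel, "p"].iloc[0])
            else:
                p_pair = np.nan
            pair_rows.append({
                "feature": feat, "group1": g1, "group2": g2, "p": p_pair,
                "g": hedges_g(samples[g1], samples[g2]),
            })
    pairwise = pd.DataFrame(pair_rows)
    # BH per feature family over the pairs actually tested
    pairwise["q"] = np.nan
    for feat in feature_cols:
        m = (pairwise["feature"] == feat) & pairwise["p"].notna()
        if m.sum() > 0:
            _, q, _, _ = multipletests(pairwise.loc[m, "p"], alpha=alpha, method="fdr_bh")
            pairwise.loc[m, "q"] = q
    pairwise["significant"] = (
        (pairwise["q"] < alpha) & (pairwise["g"].abs() > effect_threshold)
    ).fillna(False)
    return StatReport(
        kruskal=pd.DataFrame(kw_rows), pairwise=pairwise,
        alpha=alpha, effect_threshold=effect_threshold,
    )
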