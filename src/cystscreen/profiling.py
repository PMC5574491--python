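"""Z'-gated feature selection, 3-component PCA phenotype space, classification.

Features are admitted to the phenotype space when their replicate-adjusted
Z'-factor between the forskolin-stimulated and reference-inhibitor control
groups is better than a cutoff (default -1.0): the gate keeps descriptors
whose control separation carries signal and drops pure noise.  The selected
features are standardized and condensed to three principal components (PC0,
PC1, PC2); compound-dose conditions are classified against the control
centroids in that space:

* restored  — near the unstimulated-control centroid (swelling reverted),
* unchanged — near the stimulated-control centroid (compound inactive),
* novel     — away from both, or with a collapsed nuclei count (cytotoxic
  phenotype flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .features import feature_columns
from .normalization import ZPrimeInputs, zprime

__all__ = ["PhenotypeSpace", "ProfilingParams", "rank_features_by_zprime",
           "fit_phenotype_space", "project", "classify_phenotype"]

PC_NAMES = ("PC0", "PC1", "PC2")


@dataclass
class ProfilingParams:
    zprime_cutoff: float = -1.0
    n_components: int = 3
    mahalanobis_radius: float = 3.5
    nuclei_fraction_cutoff: float = 0.5
    group_a_role: str = "stimulated"
    group_b_role: str = "reference_inhibitor"


@dataclass
class PhenotypeSpace:
    """A fitted 3-component phenotype space with its reference geometry."""

    selected_features: list[str]
    loadings: pd.DataFrame  # features x components
    explained_variance_fraction: np.ndarray
    center: np.ndarray  # per-feature standardization mean
    scale: np.ndarray  # per-feature standardization SD
    centroids: dict  # control role -> (n_components,) score centroid
    control_scales: np.ndarray  # pooled within-control-group SD per component
    n_components: int = 3


def rank_features_by_zprime(table, params: ProfilingParams | None = None,
                            n: int | None = None):
    """Rank features by control-group Z' and gate at the cutoff.

    For every feature, the replicate-adjusted Z' is computed between the two
    control groups with max/min roles assigned per feature by the group
    means.  Features with Z' above the cutoff are retained, ranked by
    descending Z' (ties broken alphabetically); features constant in both
    groups are excluded.

    Returns ``(selected_feature_names, ranking_frame)``.
    """
    params = params or ProfilingParams()
    df = table.data if hasattr(table, "data") else table
    ga = df[df["role"] == params.group_a_role]
    gb = df[df["role"] == params.group_b_role]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("both control groups need at least 2 wells")
    if n is None:
        n = int(min(len(ga), len(gb)))
    rows = []
    for col in feature_columns(df):
        a = ga[col].to_numpy(dtype=float)
        b = gb[col].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if a.size < 2 or b.size < 2:
            continue
        ma, mb = float(a.mean()), float(b.mean())
        if ma == mb:  # constant / non-separating: undefined Z'
            continue
        hi, lo = (a, b) if ma > mb else (b, a)
        z = zprime(ZPrimeInputs(avg_max=float(hi.mean()),
                                sd_max=float(hi.std(ddof=1)),
                                avg_min=float(lo.mean()),
                                sd_min=float(lo.std(ddof=1)), n=n))
        rows.append({"feature": col, "zprime": z,
                     "selected": z > params.zprime_cutoff})
    ranking = pd.DataFrame(rows).sort_values(
        ["zprime", "feature"], ascending=[False, True]).reset_index(drop=True)
    selected = ranking.loc[ranking["selected"], "feature"].tolist()
    return selected, ranking


def fit_phenotype_space(table, selected_features: list[str],
                        params: ProfilingParams | None = None) -> PhenotypeSpace:
    """Standardize the selected features and fit the PCA phenotype space.

    Component signs follow a fixed convention (the largest-magnitude loading
    of each component is positive), so the decomposition is fully
    deterministic.  Control centroids and pooled within-control-group score
    SDs are stored for later classification.
    """
    params = params or ProfilingParams()
    df = table.data if hasattr(table, "data") else table
    k = params.n_components
    if len(selected_features) < k:
        raise ValueError(f"need at least {k} features, got {len(selected_features)}")
    X = df[selected_features].to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1)
    X = X[ok]
    if X.shape[0] < k + 1:
        raise ValueError("too few complete wells to fit the phenotype space")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    if np.any(scale == 0):
        bad = [f for f, s in zip(selected_features, scale) if s == 0]
        raise ValueError(f"constant features cannot be standardized: {bad}")
    Z = (X - center) / scale
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Z)
    comps = pca.components_.copy()  # (k, n_features)
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    loadings = pd.DataFrame(comps.T, index=selected_features,
                            columns=list(PC_NAMES[:k]))
    space = PhenotypeSpace(
        selected_features=list(selected_features), loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        center=center, scale=scale, centroids={},
        control_scales=np.ones(k), n_components=k)

    sub = df.loc[ok].reset_index(drop=True)
    score_df = pd.DataFrame(scores, columns=list(PC_NAMES[:k]))
    pooled = []
    for role in ("unstimulated", "stimulated"):
        m = (sub["role"] == role).to_numpy()
        if m.sum() >= 1:
            grp = score_df[m].to_numpy()
            space.centroids[role] = grp.mean(axis=0)
            if m.sum() >= 2:
                pooled.append(grp - grp.mean(axis=0))
    if pooled:
        resid = np.vstack(pooled)
        sd = resid.std(axis=0, ddof=min(len(pooled), resid.shape[0] - 1))
        space.control_scales = np.maximum(sd, 1e-9)
    return space


def project(space: PhenotypeSpace, table) -> pd.DataFrame:
    """Score wells in the phenotype space.

    Wells missing any selected feature are flagged (``projected = False``)
    and get NaN scores rather than being dropped.
    """
    df = table.data if hasattr(table, "data") else table
    X = df[space.selected_features].to_numpy(dtype=float)
    ok = np.isfinite(X).all(axis=1)
    k = space.n_components
    scores = np.full((len(df), k), np.nan)
    if ok.any():
        Z = (X[ok] - space.center) / space.scale
        scores[ok] = Z @ space.loadings.to_numpy()
    out = df[[c for c in ("well_id", "plate", "treatment", "concentration_um",
                          "role") if c in df.columns]].copy()
    for i, name in enumerate(PC_NAMES[:k]):
        out[name] = scores[:, i]
    out["projected"] = ok
    return out


def _mahalanobis(point: np.ndarray, centroid: np.ndarray,
                 scales: np.ndarray) -> float:
    return float(np.sqrt(np.sum(((point - centroid) / scales) ** 2)))


def classify_phenotype(scores: pd.DataFrame, space: PhenotypeSpace,
                       nuclei_counts: pd.DataFrame,
                       params: ProfilingParams | None = None) -> pd.DataFrame:
    """Label each compound-dose condition as restored / unchanged / novel.

    Labels are decided on replicate-mean PC scores: within the Mahalanobis
    radius (diagonal, pooled control scales) of the unstimulated centroid ->
    ``restored``; of the stimulated centroid -> ``unchanged``; outside both
    -> ``novel``.  Conditions whose mean nuclei count falls below the
    configured fraction of the unstimulated-control median are ``novel``
    regardless of geometry (low-cell-count cytotoxicity flag).  Conditions
    with no projected wells and no nuclei signal are ``unlabeled``.
    """
    params = params or ProfilingParams()
    for role in ("unstimulated", "stimulated"):
        if role not in space.centroids:
            raise ValueError(f"space lacks the {role!r} centroid")
    nuc = nuclei_counts.set_index("well_id")["nuclei_count"]
    unstim_wells = scores[scores["role"] == "unstimulated"]["well_id"]
    unstim_nuc_med = float(nuc.reindex(unstim_wells).median())
    k = space.n_components
    pcs = list(PC_NAMES[:k])
    rows = []
    tests = scores[scores["role"].isin(["test", "reference_inhibitor"])]
    for (treat, dose), grp in tests.groupby(["treatment", "concentration_um"],
                                            sort=True):
        mean_nuc = float(nuc.reindex(grp["well_id"]).mean())
        proj = grp[grp["projected"]]
        mean_scores = proj[pcs].mean().to_numpy() if len(proj) else None
        d_un = d_st = np.nan
        low_nuclei = (np.isfinite(mean_nuc) and np.isfinite(unstim_nuc_med)
                      and mean_nuc < params.nuclei_fraction_cutoff * unstim_nuc_med)
        if mean_scores is not None and np.isfinite(mean_scores).all():
            d_un = _mahalanobis(mean_scores, space.centroids["unstimulated"],
                                space.control_scales)
            d_st = _mahalanobis(mean_scores, space.centroids["stimulated"],
                                space.control_scales)
        if low_nuclei:
            label = "novel"
        elif not np.isfinite(d_un):
            label = "unlabeled"
        elif d_un <= params.mahalanobis_radius and d_un <= d_st:
            label = "restored"
        elif d_st <= params.mahalanobis_radius:
            label = "unchanged"
        else:
            label = "novel"
        rows.append({"treatment": treat, "concentration_um": dose,
                     "n_wells": int(len(grp)), "n_projected": int(len(proj)),
                     "mean_nuclei_count": mean_nuc,
                     "dist_unstimulated": d_un, "dist_stimulated": d_st,
                     "label": label})
    return pd.DataFrame(rows).sort_values(
        ["treatment", "concentration_um"]).reset_index(drop=True)
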