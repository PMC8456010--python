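"""Quantitative-trait analysis: discriminant trait selection, variance
summaries, and ecotype clustering.

The most population-discriminating traits are selected by stepwise linear
discriminant analysis on partial Wilks' lambda (F-to-enter / F-to-stay),
run separately per sex.  Populations are then reduced to standardized
trait means, the number of clusters is chosen by the average-silhouette
method, and populations are grouped into ecotypes by Ward hierarchical
clustering; least-squares means per ecotype summarize the resulting trait
variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from .niche_clustering import (LINKAGES, Dendrogram, assign_niches,
                               hcluster)

ID_COLS = ("population_id", "sex", "individual")


def trait_columns(traits: pd.DataFrame) -> list[str]:
    """Numeric trait columns of an individual-level table."""
    return [c for c in traits.columns
            if c not in ID_COLS and pd.api.types.is_numeric_dtype(traits[c])]


def population_means(traits: pd.DataFrame, cols: list[str] | None = None,
                     sex: str | None = None,
                     standardize: bool = True) -> pd.DataFrame:
    """Population x trait mean matrix, optionally sex-restricted and
    z-scored per trait (mean 0, SD 1 over populations)."""
    cols = cols or trait_columns(traits)
    df = traits if sex is None else traits[traits["sex"] == sex]
    M = df.groupby("population_id")[cols].mean()
    if standardize:
        sd = M.std(ddof=1).replace(0.0, 1.0)
        M = (M - M.mean()) / sd
    return M


# ---------------------------------------------------------------------------
# Stepwise discriminant selection (partial Wilks' lambda)
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    """Entry order with partial R-square, F and p per selected trait."""

    entries: pd.DataFrame        # trait, partial_rsq, F, p, step
    sle: float
    sls: float
    n: int
    n_groups: int

    @property
    def selected(self) -> list[str]:
        return list(self.entries["trait"])


def _scatter(X: np.ndarray, groups: np.ndarray):
    """Within-group and total scatter matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(groups):
        sub = X[groups == g]
        sc = sub - sub.mean(axis=0)
        W += sc.T @ sc
    return W, T


def _wilks(X: np.ndarray, groups: np.ndarray, cols: list[int]) -> float:
    """Wilks' lambda det(W)/det(T) for a column subset (1.0 for empty)."""
    if not cols:
        return 1.0
    W, T = _scatter(X[:, cols], groups)
    sign_w, ld_w = np.linalg.slogdet(W)
    sign_t, ld_t = np.linalg.slogdet(T)
    if sign_t <= 0:
        raise np.linalg.LinAlgError("singular total scatter")
    if sign_w <= 0:
        return 0.0
    return float(np.exp(ld_w - ld_t))


def stepwise_discriminant(traits: pd.DataFrame, cols: list[str],
                          group_col: str = "population_id",
                          sle: float = 0.15, sls: float = 0.15,
                          max_steps: int = 100) -> StepwiseResult:
    """Stepwise selection of discriminating traits on partial Wilks' lambda.

    At each step the candidate minimizing the partial lambda
    ``L(t|S) = L(S+t)/L(S)`` enters if its F-test
    ``F = ((n-g-s)/(g-1)) (1-L)/L`` has ``p <= sle`` (s = |S| before
    entry); entered traits whose removal F has ``p > sls`` then leave.
    Ties break on larger partial R-square, then column order.  The first
    entry step is exactly a one-way ANOVA across groups.
    """
    X = traits[cols].to_numpy(dtype=float)
    groups = traits[group_col].to_numpy()
    n = len(X)
    g = len(np.unique(groups))
    if g < 2:
        raise ValueError("need at least two groups")
    if n <= g + len(cols):
        warnings.warn("few observations relative to groups + traits; "
                      "F tests are weak")
    try:
        _wilks(X, groups, list(range(len(cols))))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular within/total scatter over traits {cols}") from exc

    S: list[int] = []
    records: list[dict] = []
    lam_S = 1.0
    for step in range(1, max_steps + 1):
        changed = False
        # --- entry scan
        best = None
        s = len(S)
        df2 = n - g - s
        if df2 > 0:
            for j in range(len(cols)):
                if j in S:
                    continue
                lam_new = _wilks(X, groups, S + [j])
                lam_p = lam_new / lam_S if lam_S > 0 else 0.0
                lam_p = min(max(lam_p, 1e-12), 1.0)
                F = (df2 / (g - 1)) * (1.0 - lam_p) / lam_p
                p = float(stats.f.sf(F, g - 1, df2))
                cand = (p, -(1.0 - lam_p), j, F, lam_new)
                if best is None or cand < best:
                    best = cand
            if best is not None and best[0] <= sle:
                p, neg_rsq, j, F, lam_new = best
                S.append(j)
                records.append({"trait": cols[j],
                                "partial_rsq": -neg_rsq, "F": F,
                                "p": p, "step": step})
                lam_S = lam_new
                changed = True
        # --- removal scan
        if len(S) > 1:
            worst = None
            s = len(S)
            df2r = n - g - s + 1
            for j in S:
                lam_wo = _wilks(X, groups, [i for i in S if i != j])
                lam_p = lam_S / lam_wo if lam_wo > 0 else 1.0
                lam_p = min(max(lam_p, 1e-12), 1.0)
                F = (df2r / (g - 1)) * (1.0 - lam_p) / lam_p
                p = float(stats.f.sf(F, g - 1, df2r))
                if worst is None or p > worst[0]:
                    worst = (p, j)
            if worst is not None and worst[0] > sls:
                p, j = worst
                S.remove(j)
                records = [r for r in records if r["trait"] != cols[j]]
                lam_S = _wilks(X, groups, S)
                changed = True
        if not changed:
            break
    entries = pd.DataFrame(records,
                           columns=["trait", "partial_rsq", "F", "p",
                                    "step"])
    return StepwiseResult(entries, sle, sls, n, g)


def stepwise_by_sex(traits: pd.DataFrame, cols: list[str] | None = None,
                    sle: float = 0.15, sls: float = 0.15
                    ) -> dict[str, StepwiseResult]:
    """Run the stepwise selection separately for hens and cocks."""
    cols = cols or trait_columns(traits)
    out = {}
    for sex in ("hen", "cock"):
        sub = traits[traits["sex"] == sex]
        if sub.empty:
            continue
        out[sex] = stepwise_discriminant(sub, cols, sle=sle, sls=sls)
    return out


# ---------------------------------------------------------------------------
# PCA variance summary
# ---------------------------------------------------------------------------

def pca_variance(traits: pd.DataFrame,
                 cols: list[str] | None = None) -> pd.DataFrame:
    """Variance proportions of the principal components of the trait
    correlation matrix (constant traits dropped with a warning)."""
    cols = cols or trait_columns(traits)
    X = traits[cols].to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >=3 rows and >=2 traits")
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        warnings.warn(f"constant traits dropped from PCA: {dropped}")
        X = X[:, keep]
    corr = np.corrcoef(X, rowvar=False)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)
    prop = eig / eig.sum()
    return pd.DataFrame({
        "component": np.arange(1, len(prop) + 1),
        "proportion": prop,
        "cumulative": np.cumsum(prop),
    })


# ---------------------------------------------------------------------------
# Silhouette scan and ecotype clustering
# ---------------------------------------------------------------------------

def silhouette_scan(M: pd.DataFrame, k_range=range(2, 11)
                    ) -> tuple[int, pd.DataFrame]:
    """Mean silhouette of Ward-tree cuts over candidate k; best k is the
    argmax.  ``M`` is a population x trait (mean) matrix."""
    from sklearn.metrics import silhouette_score
    n = len(M)
    if n < 3:
        raise ValueError("need at least three populations")
    X = M.to_numpy(dtype=float)
    Z = sch.linkage(X, method="ward")
    rows = []
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        lab = sch.fcluster(Z, t=k, criterion="maxclust")
        rows.append({"k": k,
                     "mean_silhouette": float(silhouette_score(X, lab))})
    if not rows:
        raise ValueError("k_range contains no feasible k")
    curve = pd.DataFrame(rows)
    best = int(curve.loc[curve["mean_silhouette"].idxmax(), "k"])
    return best, curve


def silhouette_widths(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-observation silhouette widths s(i) = (b-a)/max(a,b) with
    Euclidean distances (singleton clusters get 0)."""
    D = squareform(pdist(X))
    labels = np.asarray(labels)
    out = np.zeros(len(X))
    for i in range(len(X)):
        same = (labels == labels[i])
        same[i] = False
        if not same.any():
            out[i] = 0.0
            continue
        a = D[i, same].mean()
        b = min(D[i, labels == c].mean()
                for c in np.unique(labels) if c != labels[i])
        out[i] = (b - a) / max(a, b)
    return out


@dataclass
class EcotypeAssignment:
    labels: pd.Series                 # population -> ecotype 1..k
    k: int
    dendrogram: Dendrogram
    ac_by_method: dict[str, float] = field(default_factory=dict)
    silhouette_curve: pd.DataFrame | None = None


def cluster_ecotypes(M: pd.DataFrame, k: int = 3,
                     scan_k: bool = False,
                     k_range=range(2, 11)) -> EcotypeAssignment:
    """Ward clustering of standardized population trait means into
    ecotypes, with the agglomerative coefficient of each linkage for
    comparison.  With ``scan_k`` the silhouette method chooses k."""
    if M.empty:
        raise ValueError("empty population-mean matrix")
    if k > len(M):
        raise ValueError("k exceeds the number of populations")
    sd = M.std(ddof=1).replace(0.0, 1.0)
    Ms = (M - M.mean()) / sd
    curve = None
    if scan_k:
        k, curve = silhouette_scan(Ms, k_range)
    D = pd.DataFrame(squareform(pdist(Ms.to_numpy())),
                     index=M.index, columns=M.index)
    dend = hcluster(D, method="ward")
    acs = {m: hcluster(D, method=m).ac for m in LINKAGES}
    labels = assign_niches(dend, k=k).rename("ecotype")
    labels.index.name = "population_id"
    return EcotypeAssignment(labels, k, dend, acs, curve)


# ---------------------------------------------------------------------------
# Least-squares means
# ---------------------------------------------------------------------------

def _letter_groups(levels: list, pairwise_p: pd.DataFrame,
                   alpha: float = 0.05) -> dict:
    """Compact letter display: levels not significantly different share a
    letter (letters = maximal cliques of the non-significance graph)."""
    import networkx as nx
    G = nx.Graph()
    G.add_nodes_from(levels)
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            if pairwise_p.loc[a, b] >= alpha:
                G.add_edge(a, b)
    cliques = sorted(nx.find_cliques(G),
                     key=lambda c: min(levels.index(x) for x in c))
    letters = {lv: "" for lv in levels}
    for ci, clique in enumerate(cliques):
        ch = chr(ord("a") + ci)
        for lv in clique:
            letters[lv] += ch
    return letters


def lsmeans(traits: pd.DataFrame, trait: str, ecotypes: pd.Series,
            sex: str | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Least-squares (model-implied) means of a trait per ecotype.

    Ordinary least squares of the trait on the ecotype factor (within one
    sex when given); in a balanced one-factor design these equal the raw
    group means.  Pairwise t-tests produce letter groupings at ``alpha``.
    """
    import statsmodels.formula.api as smf
    df = traits if sex is None else traits[traits["sex"] == sex]
    df = df.copy()
    df["ecotype"] = df["population_id"].map(ecotypes)
    df = df.dropna(subset=["ecotype", trait])
    levels = sorted(df["ecotype"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two ecotypes")
    fit = smf.ols(f"Q('{trait}') ~ C(ecotype)", data=df).fit()
    sigma2 = fit.mse_resid
    rows = []
    pairp = pd.DataFrame(1.0, index=levels, columns=levels)
    means, ses, counts = {}, {}, {}
    for lv in levels:
        sub = df[df["ecotype"] == lv][trait]
        means[lv] = sub.mean()
        counts[lv] = len(sub)
        ses[lv] = np.sqrt(sigma2 / len(sub))
    dof = fit.df_resid
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            se_d = np.sqrt(sigma2 * (1 / counts[a] + 1 / counts[b]))
            t = (means[a] - means[b]) / se_d
            p = 2 * stats.t.sf(abs(t), dof)
            pairp.loc[a, b] = pairp.loc[b, a] = p
    letters = _letter_groups(levels, pairp, alpha)
    for lv in levels:
        rows.append({"ecotype": lv, "trait": trait, "n": counts[lv],
                     "lsmean": means[lv], "se": ses[lv],
                     "letters": letters[lv]})
    out = pd.DataFrame(rows)
    out.attrs["pairwise_p"] = pairp
    out.attrs["anova_p"] = float(fit.f_pvalue) if len(levels) > 1 else np.nan
    return out


def lsmeans_table(traits: pd.DataFrame, trait_cols: list[str],
                  ecotypes: pd.Series, sexes=("hen", "cock")
                  ) -> pd.DataFrame:
    """LS-mean (SE) table across traits and sexes, one row per ecotype x
    sex x trait."""
    parts = []
    for sex in sexes:
        if traits[traits["sex"] == sex].empty:
            continue
        for tr in trait_cols:
            t = lsmeans(traits, tr, ecotypes, sex=sex)
            t.insert(0, "sex", sex)
            t.attrs = {}          # drop per-fit attrs before concat
            parts.append(t)
    return pd.concat(parts, ignore_index=True)
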