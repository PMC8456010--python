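"""Presence-background maximum-entropy species distribution modelling.

The model estimates a probability distribution over background cells whose
expectation of each feature matches the presence sample, subject to an L1
penalty that shrinks coefficients toward zero (the regularization
multiplier RM scales the penalty).  Fitting maximizes

    (1/m) sum_presences lambda.f(x_i)  -  ln Z_background
                                        -  sum_j beta_j |lambda_j|

by cyclic coordinate descent with soft-thresholding, where
``beta_j = RM * s_j / sqrt(m)`` and ``s_j`` is feature j's standard
deviation over presences (floored at a small positive constant).  The raw
output is the normalized distribution over background; the logistic output
maps the uniform model to 0.5 via the fitted distribution's entropy H:
``logistic = e^H raw / (1 + e^H raw)``.

Model tuning follows the standard feature-class x regularization-multiplier
grid with small-sample AICc; variable importance is reported both as
percent contribution (objective gain credited to the updated feature's
source variable during fitting) and as jackknife training gains.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("L", "Q", "P", "H", "T")
DEFAULT_COMBOS = ("H", "LQH", "HQP", "HQC", "LQHP", "LQHPT")
DEFAULT_RMS = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)

_S_FLOOR = 0.05          # floor on per-feature presence SD in the penalty
_MAX_CYCLES = 500
_TOL = 1e-7


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    name: str
    layer: str            # source variable (second layer for products)
    kind: str             # L, Q, P, H (fwd/rev), T
    partner: str | None = None
    knot: float | None = None
    reverse: bool = False


@dataclass
class FeatureSet:
    """Feature definitions plus the min/max normalizers of each layer.

    Normalizers come from the reference (background) sample, so every
    feature maps covariate values to [0, 1] on that sample; hinge and
    threshold knots are placed strictly inside the background range.
    """

    layers: list[str]
    mins: dict[str, float]
    maxs: dict[str, float]
    features: list[Feature]

    def scaled(self, X: pd.DataFrame, layer: str) -> np.ndarray:
        lo, hi = self.mins[layer], self.maxs[layer]
        z = (X[layer].to_numpy(dtype=float) - lo) / (hi - lo)
        return np.clip(z, 0.0, 1.0)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Design matrix (n x n_features), every column in [0, 1]."""
        cols = []
        for f in self.features:
            z = self.scaled(X, f.layer)
            if f.kind == "L":
                cols.append(z)
            elif f.kind == "Q":
                cols.append(z * z)
            elif f.kind == "P":
                cols.append(z * self.scaled(X, f.partner))
            elif f.kind == "T":
                lo, hi = self.mins[f.layer], self.maxs[f.layer]
                x = X[f.layer].to_numpy(dtype=float)
                cols.append((x > f.knot).astype(float))
            elif f.kind == "H":
                lo, hi = self.mins[f.layer], self.maxs[f.layer]
                x = X[f.layer].to_numpy(dtype=float)
                t = f.knot
                if f.reverse:
                    v = (t - x) / (t - lo)
                else:
                    v = (x - t) / (hi - t)
                cols.append(np.clip(v, 0.0, 1.0))
            else:
                raise ValueError(f"unknown feature kind {f.kind!r}")
        return np.column_stack(cols) if cols else np.empty((len(X), 0))

    @property
    def source_layers(self) -> list[str]:
        return [f.layer for f in self.features]


def build_features(background: pd.DataFrame, layers: list[str],
                   classes: str = "LQH", n_knots: int = 10) -> FeatureSet:
    """Construct a :class:`FeatureSet` for the given feature-class combo.

    ``classes`` is a string over {L, Q, P, H, T} (C, categorical, is
    accepted and ignored: no categorical layers are supported).  Constant
    layers are dropped with a warning; degenerate hinge/threshold knots at
    the range limits are pruned.
    """
    classes = classes.upper()
    usable = []
    mins, maxs = {}, {}
    for lay in layers:
        x = background[lay].to_numpy(dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            warnings.warn(f"layer {lay!r} is constant over background; "
                          "dropped from features")
            continue
        usable.append(lay)
        mins[lay], maxs[lay] = lo, hi
    feats: list[Feature] = []
    for lay in usable:
        if "L" in classes:
            feats.append(Feature(f"L({lay})", lay, "L"))
        if "Q" in classes:
            feats.append(Feature(f"Q({lay})", lay, "Q"))
    if "P" in classes:
        for a, b in itertools.combinations(usable, 2):
            feats.append(Feature(f"P({a}*{b})", a, "P", partner=b))
    for lay in usable:
        lo, hi = mins[lay], maxs[lay]
        knots = np.linspace(lo, hi, n_knots + 2)[1:-1]
        if "T" in classes:
            for t in knots:
                feats.append(Feature(f"T({lay}>{t:.4g})", lay, "T",
                                     knot=float(t)))
        if "H" in classes:
            for t in knots:
                if hi - t > 1e-12:
                    feats.append(Feature(f"H({lay},{t:.4g})", lay, "H",
                                         knot=float(t)))
                if t - lo > 1e-12:
                    feats.append(Feature(f"H'({lay},{t:.4g})", lay, "H",
                                         knot=float(t), reverse=True))
    return FeatureSet(usable, mins, maxs, feats)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

@dataclass
class MaxEntModel:
    feature_set: FeatureSet
    lam: np.ndarray                 # coefficients per feature
    rm: float
    beta_reg: np.ndarray            # per-feature L1 penalty
    ln_z: float                     # ln sum_bg exp(lambda.f)
    entropy: float                  # H of the raw distribution
    n_background: int
    converged: bool
    contrib: dict = field(default_factory=dict)   # per-layer gain credit
    objective_trace: list = field(default_factory=list)

    @property
    def k(self) -> int:
        """Number of nonzero coefficients."""
        return int(np.sum(self.lam != 0.0))

    def raw(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        F = X if isinstance(X, np.ndarray) else self.feature_set.transform(X)
        return np.exp(F @ self.lam - self.ln_z)

    def predict(self, X, output: str = "logistic") -> np.ndarray:
        """Suitability: ``raw``, ``logistic`` or ``cloglog``."""
        F = X if isinstance(X, np.ndarray) else self.feature_set.transform(X)
        if output == "raw":
            return np.exp(F @ self.lam - self.ln_z)
        # computed in log space so the uniform model gives exactly 0.5
        e_h_r = np.exp(self.entropy + F @ self.lam - self.ln_z)
        if output == "logistic":
            return e_h_r / (1.0 + e_h_r)
        if output == "cloglog":
            return 1.0 - np.exp(-e_h_r)
        raise ValueError(f"unknown output {output!r}")


def fit_maxent(presence_design: np.ndarray, background_design: np.ndarray,
               rm: float = 1.0, feature_set: FeatureSet | None = None,
               max_cycles: int = _MAX_CYCLES, tol: float = _TOL
               ) -> MaxEntModel:
    """Fit the L1-penalized maximum-entropy model.

    Cyclic coordinate descent with soft-thresholded Newton steps; each step
    is backtracked until the penalized objective does not decrease, so the
    objective is non-decreasing across cycles.  Non-convergence within
    ``max_cycles`` sets ``converged=False`` (with a warning) rather than
    raising.
    """
    Fp = np.asarray(presence_design, dtype=float)
    Fb = np.asarray(background_design, dtype=float)
    m, J = Fp.shape
    N = Fb.shape[0]
    if m < 1 or N < 2:
        raise ValueError("need >=1 presence and >=2 background points")
    s = Fp.std(axis=0) if m > 1 else np.zeros(J)
    beta = rm * np.maximum(s, _S_FLOOR) / np.sqrt(m)
    fbar = Fp.mean(axis=0) if J else np.zeros(0)

    lam = np.zeros(J)
    s_bg = np.zeros(N)                      # lambda . f over background
    w = np.ones(N)                          # exp(s_bg - smax)
    contrib: dict[str, float] = {}
    sources = feature_set.source_layers if feature_set else [
        f"f{j}" for j in range(J)]

    def objective(s_bg_vec, lam_vec):
        smax = s_bg_vec.max() if N else 0.0
        ln_z = smax + np.log(np.exp(s_bg_vec - smax).sum())
        return float(fbar @ lam_vec - ln_z - beta @ np.abs(lam_vec)), ln_z

    obj, ln_z = objective(s_bg, lam)
    trace = [obj]
    converged = False
    for cycle in range(max_cycles):
        obj_start = obj
        # refresh to limit drift
        if J:
            s_bg = Fb @ lam
        smax = s_bg.max()
        w = np.exp(s_bg - smax)
        Z = w.sum()
        for j in range(J):
            fj_b = Fb[:, j]
            mu = (w @ fj_b) / Z
            var = (w @ (fj_b * fj_b)) / Z - mu * mu
            g = fbar[j] - mu
            h = max(var, 1e-10)
            a = lam[j] * h + g
            new = np.sign(a) * max(abs(a) - beta[j], 0.0) / h
            d = np.clip(new - lam[j], -2.0, 2.0)
            if d == 0.0:
                continue
            accepted = False
            for _ in range(20):
                cand = lam[j] + d
                # snap tiny crossings to exactly zero
                if lam[j] != 0.0 and np.sign(cand) not in (0, np.sign(lam[j])) \
                        and abs(cand) < 1e-12:
                    cand = 0.0
                s_new = s_bg + d * fj_b
                lam_try = lam.copy()
                lam_try[j] = cand
                obj_new, ln_z_new = objective(s_new, lam_try)
                if obj_new >= obj - 1e-13:
                    key = sources[j]
                    contrib[key] = contrib.get(key, 0.0) + (obj_new - obj)
                    lam[j] = cand
                    s_bg = s_new
                    smax = s_bg.max()
                    w = np.exp(s_bg - smax)
                    Z = w.sum()
                    obj, ln_z = obj_new, ln_z_new
                    accepted = True
                    break
                d *= 0.5
            if not accepted:
                continue
        trace.append(obj)
        if obj - obj_start < tol:
            converged = True
            break
    if not converged:
        warnings.warn("coordinate descent did not converge within "
                      f"{max_cycles} cycles")
    # H = ln Z - E_p[lambda.f]; equals -sum p ln p but is exact for the
    # uniform model (H = ln N), which the logistic identity relies on
    p = w / w.sum() if N else np.empty(0)
    entropy = float(ln_z - p @ s_bg)
    fs = feature_set if feature_set is not None else FeatureSet([], {}, {}, [])
    return MaxEntModel(fs, lam, rm, beta, ln_z, entropy, N, converged,
                       contrib, trace)


def gain(model: MaxEntModel, presence_design: np.ndarray) -> float:
    """Mean log-suitability improvement over the uniform model (>= 0 at the
    training optimum; the uniform model's gain is exactly 0)."""
    Fp = np.asarray(presence_design, dtype=float)
    if Fp.shape[0] == 0:
        raise ValueError("empty presence set")
    return float((Fp @ model.lam).sum() / Fp.shape[0] - model.ln_z
                 + np.log(model.n_background))


def aicc(model: MaxEntModel, occurrence_design: np.ndarray,
         cell_design: np.ndarray) -> tuple[int, float, float]:
    """(k, logLik, AICc) with the raw distribution standardized over all
    valid cells (not background only).

    ``k`` counts nonzero coefficients; AICc is +inf when n <= k + 1.
    """
    k = model.k
    occ = np.asarray(occurrence_design, dtype=float)
    cells = np.asarray(cell_design, dtype=float)
    n = occ.shape[0]
    eta_cells = cells @ model.lam
    emax = eta_cells.max()
    ln_z_cells = emax + np.log(np.exp(eta_cells - emax).sum())
    log_lik = float((occ @ model.lam - ln_z_cells).sum())
    if n <= k + 1:
        return k, log_lik, float("inf")
    val = 2 * k - 2 * log_lik + 2 * k * (k + 1) / (n - k - 1)
    return k, log_lik, float(val)


# ---------------------------------------------------------------------------
# Tuning
# ---------------------------------------------------------------------------

@dataclass
class TuneResult:
    table: pd.DataFrame           # combo, rm, k, logLik, AICc, deltaAICc
    selected: pd.Series
    best_model: MaxEntModel


def tune(presences: pd.DataFrame, background: pd.DataFrame,
         layers: list[str], cells: pd.DataFrame | None = None,
         combos=DEFAULT_COMBOS, rm_values=DEFAULT_RMS,
         n_knots: int = 10) -> TuneResult:
    """Fit every feature-combo x RM cell and rank by deltaAICc.

    The default grid is 6 combos x 8 multipliers = 48 model runs.  A failed
    fit is recorded with NaN statistics rather than aborting the sweep.
    ``cells`` is the all-valid-cells environment table used to standardize
    the AICc likelihood (defaults to the background table).
    """
    if not len(combos) or not len(rm_values):
        raise ValueError("empty tuning grid")
    if cells is None:
        cells = background
    rows = []
    best = None
    for combo in combos:
        fs = build_features(background, layers, combo, n_knots)
        Fp = fs.transform(presences)
        Fb = fs.transform(background)
        Fc = fs.transform(cells)
        for rm in rm_values:
            try:
                model = fit_maxent(Fp, Fb, rm, fs)
                k, ll, val = aicc(model, Fp, Fc)
                rows.append({"combo": combo, "rm": rm, "k": k,
                             "logLik": ll, "AICc": val, "failed": False})
                if best is None or (np.isfinite(val)
                                    and val < best[0]):
                    best = (val if np.isfinite(val) else np.inf, model)
            except Exception as exc:   # record, do not abort the sweep
                warnings.warn(f"fit failed for {combo}, rm={rm}: {exc}")
                rows.append({"combo": combo, "rm": rm, "k": np.nan,
                             "logLik": np.nan, "AICc": np.nan,
                             "failed": True})
    table = pd.DataFrame(rows)
    finite = table["AICc"].replace(np.inf, np.nan)
    table["deltaAICc"] = table["AICc"] - np.nanmin(finite)
    table = table.sort_values(
        "deltaAICc", na_position="last").reset_index(drop=True)
    return TuneResult(table, table.iloc[0], best[1])


def block_partition(coords: pd.DataFrame, k: int = 4) -> np.ndarray:
    """Spatial-block fold labels (1..k) by lon/lat median splits.

    ``k=2`` splits once on longitude; ``k=4`` additionally splits each half
    on latitude (2x2 blocks).  Degenerate geometry (all records at one
    point) is an error.
    """
    if k not in (2, 4):
        raise ValueError("k must be 2 or 4")
    lon = coords["lon"].to_numpy(dtype=float)
    lat = coords["lat"].to_numpy(dtype=float)
    if len(lon) < k:
        raise ValueError("fewer occurrences than folds")
    if np.ptp(lon) == 0 and np.ptp(lat) == 0:
        raise ValueError("all occurrences share one coordinate")
    east = lon > np.median(lon)
    labels = np.ones(len(lon), dtype=int)
    if k == 2:
        labels[east] = 2
        return labels
    for half, base in ((~east, 1), (east, 3)):
        if half.sum() == 0:
            continue
        lat_half = lat[half]
        north = lat_half > np.median(lat_half)
        sub = np.where(north, base + 1, base)
        labels[half] = sub
    return labels


# ---------------------------------------------------------------------------
# Variable importance
# ---------------------------------------------------------------------------

def percent_contribution(model: MaxEntModel) -> pd.Series:
    """Percent of the penalized objective gain credited to each source
    variable during coordinate descent (negatives floored at 0; sums to
    100 unless the model gained nothing)."""
    credits = pd.Series(model.contrib, dtype=float)
    all_layers = pd.Series(0.0, index=model.feature_set.layers or
                           credits.index)
    all_layers.update(credits.clip(lower=0.0))
    total = all_layers.sum()
    if total <= 0:
        warnings.warn("model has zero total gain; contributions undefined")
        return all_layers
    return 100.0 * all_layers / total


def jackknife(layers: list[str], presences: pd.DataFrame,
              background: pd.DataFrame, combo: str = "LQH",
              rm: float = 1.0, n_knots: int = 10) -> pd.DataFrame:
    """Training gain with each variable alone, without it, and with all.

    ``gain_full`` is identical across rows; a variable whose isolated model
    carries the most information tops ``gain_only``.
    """
    if len(layers) < 2:
        raise ValueError("jackknife needs at least two variables")

    def _fit_gain(subset):
        fs = build_features(background, subset, combo, n_knots)
        Fp, Fb = fs.transform(presences), fs.transform(background)
        model = fit_maxent(Fp, Fb, rm, fs)
        return gain(model, Fp)

    g_full = _fit_gain(layers)
    rows = []
    for v in layers:
        rows.append({
            "variable": v,
            "gain_only": _fit_gain([v]),
            "gain_without": _fit_gain([x for x in layers if x != v]),
            "gain_full": g_full,
        })
    return pd.DataFrame(rows).set_index("variable")


def select_variables(presences: pd.DataFrame, background: pd.DataFrame,
                     layers: list[str], corr_thresh: float = 0.6,
                     contrib_thresh: float = 4.0, combo: str = "LQH",
                     rm: float = 1.0, n_knots: int = 6,
                     max_iter: int = 10) -> list[str]:
    """Iterative selection of an uncorrelated, high-contribution subset.

    Each round fits the model, removes variables contributing less than
    ``contrib_thresh`` percent, and among background-correlated pairs
    (|Pearson r| > ``corr_thresh``) removes the lower-contribution member,
    until the set is stable.  Returns the retained names in contribution
    order.
    """
    current = list(layers)
    for _ in range(max_iter):
        fs = build_features(background, current, combo, n_knots)
        Fp, Fb = fs.transform(presences), fs.transform(background)
        model = fit_maxent(Fp, Fb, rm, fs)
        pct = percent_contribution(model).reindex(current).fillna(0.0)
        drop = set(pct.index[pct < contrib_thresh])
        corr = background[current].corr().to_numpy()
        for i, a in enumerate(current):
            for jj in range(i + 1, len(current)):
                b = current[jj]
                if abs(corr[i, jj]) > corr_thresh:
                    loser = a if pct[a] < pct[b] else b
                    drop.add(loser)
        keep = [v for v in current if v not in drop]
        if not keep:
            raise ValueError(
                "all variables eliminated; relax corr_thresh or "
                "contrib_thresh")
        if keep == current:
            return sorted(current, key=lambda v: -pct[v])
        current = keep
    fs = build_features(background, current, combo, n_knots)
    model = fit_maxent(fs.transform(presences), fs.transform(background),
                       rm, fs)
    pct = percent_contribution(model).reindex(current).fillna(0.0)
    return sorted(current, key=lambda v: -pct[v])
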