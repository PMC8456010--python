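"""Synthetic study landscape: rasters, sites, ground truth, and traits.

The generator emulates the structure of a gradient-sampling field study of
scavenging chickens: four elevational gradients, each crossing three
elevation bands (lowland 400-1800, mid-altitude 1800-2400, highland
2400-3500 m.a.s.l.), two populations per gradient-band cluster plus two
extra populations (26 in all), 15 hens and 5 cocks phenotyped per
population, 19 quantitative traits of which 8 carry ecotype signal, and 34
environmental layers (elevation, bioclimatic, soil, vegetation) including
deliberately correlated pairs.  Every stochastic element is driven by one
seed, and with zero noise every generated quantity equals its closed-form
generating function, so downstream recovery can be tested against known
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .geodata import EnvRasterStack, write_stack

DEFAULT_BANDS = ((400.0, 1800.0), (1800.0, 2400.0), (2400.0, 3500.0))

#: baseline (intercept) and measurement scale for the signal trait codes;
#: magnitudes follow common adult-bird morphometrics (mm except BW in kg).
SIGNAL_TRAIT_BASELINES = {
    "BW": 1.1, "BL": 36.0, "WS": 40.0, "CL": 24.0,
    "CW": 9.0, "EW": 9.5, "WW": 17.5, "KL": 16.4,
}
SIGNAL_TRAITS = tuple(SIGNAL_TRAIT_BASELINES)

# ecotype shift patterns (SD units, scaled per trait) cycled over signal
# traits so the three ecotypes separate along several directions at once
_ECOTYPE_PATTERNS = ((0.0, 1.0, 2.0), (0.0, 1.0, -1.0),
                     (1.0, -1.0, 0.0), (0.0, 2.0, 1.0))


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic study design (defaults = study layout)."""

    grid_shape: tuple[int, int] = (120, 120)
    cell_size: float = 0.01          # degrees per cell
    origin: tuple[float, float] = (36.0, 6.0)   # xmin, ymin (lon/lat)
    n_gradients: int = 4
    bands: tuple = DEFAULT_BANDS     # m.a.s.l., ordered, non-overlapping
    pops_per_band: int = 2
    n_extra_pops: int = 2            # clusters that contributed a 3rd pop
    hens_per_pop: int = 15
    cocks_per_pop: int = 5
    n_layers: int = 34
    n_traits: int = 19
    n_signal_traits: int = 8
    effect_sizes: tuple = (2.0, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2)
    noise_sd: float = 1.0            # residual trait SD (SD units)
    smooth_amplitude: float = 0.4    # env-smooth contribution (SD units)
    layer_noise_sd: float = 0.3      # layer field noise, relative to signal
    noise_smooth_sigma: float = 3.0  # Gaussian-field smoothing radius, cells
    correlated_pairs: tuple = (("bio01", "bio02", 0.85),
                               ("bio05", "bio06", 0.90),
                               ("soil01", "soil02", 0.75),
                               ("bio10", "bio11", -0.70))
    gradient_gap_cells: int = 4      # data gap between gradient strips
    min_pop_sep_cells: int = 3
    edge_margin_cells: int = 2       # keep sites off strip/grid borders
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError("grid_shape must be positive")
        for (a, b) in self.bands:
            if b <= a:
                raise ValueError("bands must be ordered intervals")
        for (a, _), (c, _) in zip(self.bands, self.bands[1:]):
            if c < a:
                raise ValueError("bands must be ascending")
        for lo, hi in zip(self.bands, self.bands[1:]):
            if hi[0] < lo[1]:
                raise ValueError("bands must not overlap")
        if len(self.effect_sizes) != self.n_signal_traits:
            raise ValueError("effect_sizes length must equal n_signal_traits")
        for pair in self.correlated_pairs:
            if not 0 < abs(pair[2]) <= 1:
                raise ValueError("target correlations must be in (0, 1]")

    @property
    def n_populations(self) -> int:
        return (self.n_gradients * len(self.bands) * self.pops_per_band
                + self.n_extra_pops)

    @property
    def trait_names(self) -> list[str]:
        names = list(SIGNAL_TRAITS[:self.n_signal_traits])
        names += [f"T{i:02d}" for i in
                  range(len(names) + 1, self.n_traits + 1)]
        return names[:self.n_traits]


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated landscape."""

    true_suitability: np.ndarray
    true_variable_set: list[str]
    ecotype_of_pop: dict[str, int] = field(default_factory=dict)
    trait_functions: dict[str, dict] = field(default_factory=dict)


def _stream_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _layer_names(n_layers: int) -> list[str]:
    """elev + bioclim + soil + vegetation names, truncated to n_layers."""
    names = ["elev"]
    names += [f"bio{i:02d}" for i in range(1, 24)]
    names += [f"soil{i:02d}" for i in range(1, 9)]
    names += ["veg01", "veg02"]
    if n_layers > len(names):
        names += [f"env{i:02d}" for i in range(len(names) + 1, n_layers + 1)]
    return names[:n_layers]


def _gradient_strips(cfg: LandscapeConfig):
    """Column ranges of the gradient strips and the between-strip gaps."""
    rows, cols = cfg.grid_shape
    gap = cfg.gradient_gap_cells
    width = (cols - gap * (cfg.n_gradients - 1)) // cfg.n_gradients
    if width < 2 or rows < 4:
        raise ValueError("grid too small to host all gradients")
    strips = []
    start = 0
    for g in range(cfg.n_gradients):
        strips.append((start, start + width))
        start += width + gap
    return strips


def _elevation_surface(cfg: LandscapeConfig):
    """Monotone elevation ramps per gradient strip; gaps are no-data."""
    rows, cols = cfg.grid_shape
    lo = min(b[0] for b in cfg.bands) - 30.0
    hi = max(b[1] for b in cfg.bands) + 30.0
    elev = np.full((rows, cols), np.nan)
    ramp = np.linspace(lo, hi, rows)
    for g, (c0, c1) in enumerate(_gradient_strips(cfg)):
        column = ramp if g % 2 == 0 else ramp[::-1]
        # slight lateral tilt so cells within a band are not all identical
        tilt = np.linspace(0.0, 20.0, c1 - c0)
        elev[:, c0:c1] = column[:, None] + tilt[None, :]
    return elev


def generate_env_stack(config: LandscapeConfig) -> EnvRasterStack:
    """Generate the environmental raster stack.

    Layer 0 is the elevation surface (monotone ramps forming the configured
    gradients).  Every other layer is a smooth deterministic function of
    elevation plus a seeded smoothed-white-noise Gaussian field; configured
    correlated pairs are rebuilt by exact projection so the realized Pearson
    correlation over data cells equals the target.
    """
    cfg = config
    names = _layer_names(cfg.n_layers)
    elev = _elevation_surface(cfg)
    mask = np.isnan(elev)
    rows, cols = cfg.grid_shape
    xmin, ymin = cfg.origin
    extent = (xmin, ymin, xmin + cols * cfg.cell_size,
              ymin + rows * cfg.cell_size)

    z = (elev - np.nanmin(elev)) / (np.nanmax(elev) - np.nanmin(elev))
    layers = [elev]
    info: dict[str, dict] = {"elev": {"kind": "elevation"}}
    kinds = ("linear", "quadratic", "saturating")
    for i, name in enumerate(names[1:]):
        rng = _stream_rng(cfg.seed, 100 + i)
        kind = kinds[i % len(kinds)]
        a = rng.uniform(5.0, 20.0) * rng.choice([-1.0, 1.0])
        b = rng.uniform(20.0, 200.0)
        c = rng.uniform(0.25, 0.75)
        if kind == "linear":
            base = a * z + b
        elif kind == "quadratic":
            base = a * (z - c) ** 2 + b
        else:
            base = a * (1.0 - np.exp(-3.0 * z)) + b
        sd_base = np.nanstd(base)
        noise = rng.standard_normal((rows, cols))
        noise = gaussian_filter(noise, sigma=cfg.noise_smooth_sigma)
        nsd = np.nanstd(noise)
        if nsd > 0 and sd_base > 0 and cfg.layer_noise_sd > 0:
            noise = noise / nsd * (cfg.layer_noise_sd * sd_base)
        else:
            noise = np.zeros_like(noise)
        layer = np.where(mask, np.nan, base + noise)
        layers.append(layer)
        info[name] = {"kind": kind, "a": float(a), "b": float(b),
                      "center": float(c),
                      "noise_sd": float(cfg.layer_noise_sd)}

    values = np.stack(layers)
    stack = EnvRasterStack(names, values, extent, cfg.cell_size, mask,
                           layer_info=info)
    _impose_correlations(stack, cfg)
    return stack


def _impose_correlations(stack: EnvRasterStack, cfg: LandscapeConfig):
    """Rebuild the second layer of each pair for an exact target r."""
    valid = ~stack.nodata_mask
    for la, lb, r in cfg.correlated_pairs:
        if la not in stack.layer_names or lb not in stack.layer_names:
            continue
        ia = stack.layer_names.index(la)
        ib = stack.layer_names.index(lb)
        x = stack.values[ia][valid]
        y = stack.values[ib][valid]
        mu_y, sd_y = y.mean(), y.std()
        xs = (x - x.mean()) / x.std()
        resid = y - y.mean() - (y - y.mean()) @ xs / len(xs) * xs
        if resid.std() < 1e-12:
            continue
        zs = (resid - resid.mean()) / resid.std()
        new = mu_y + sd_y * (r * xs + np.sqrt(1.0 - r * r) * zs)
        out = stack.values[ib]
        out[valid] = new
        stack.layer_info.setdefault(lb, {})["correlated_with"] = (la, r)


def place_populations(config: LandscapeConfig,
                      stack: EnvRasterStack) -> pd.DataFrame:
    """Place one site per population inside its gradient and elevation band.

    Sites within a cluster are kept at least ``min_pop_sep_cells`` apart and
    never share a cell.  The two extra populations go to the first two
    gradient-band clusters, giving 26 sites under the default design.
    """
    cfg = config
    if "elev" not in stack.layer_names:
        raise ValueError("stack has no elevation layer")
    elev = stack.layer("elev")
    strips = _gradient_strips(cfg)
    extra = [(0, 0), (1, 1)][:cfg.n_extra_pops] if cfg.n_extra_pops else []
    rng = _stream_rng(cfg.seed, 7)
    rows_out = []
    used: set[tuple[int, int]] = set()
    for g, (c0, c1) in enumerate(strips):
        for b, (lo, hi) in enumerate(cfg.bands):
            m = cfg.edge_margin_cells
            in_band = np.zeros_like(elev, dtype=bool)
            in_band[m:elev.shape[0] - m, c0 + m:c1 - m] = True
            in_band &= (elev >= lo) & (elev < hi) & ~stack.nodata_mask
            if not in_band.any():   # tiny grids: relax the margin
                in_band = np.zeros_like(elev, dtype=bool)
                in_band[:, c0:c1] = True
                in_band &= (elev >= lo) & (elev < hi) & ~stack.nodata_mask
            cand = np.argwhere(in_band)
            if len(cand) == 0:
                raise ValueError(
                    f"elevation band {lo}-{hi} has no cells in gradient "
                    f"{g + 1}")
            n_here = cfg.pops_per_band + extra.count((g, b))
            chosen: list[np.ndarray] = []
            order = rng.permutation(len(cand))
            for idx in order:
                cell = cand[idx]
                if tuple(cell) in used:
                    continue
                if all(np.abs(cell - c).max() >= cfg.min_pop_sep_cells
                       for c in chosen):
                    chosen.append(cell)
                if len(chosen) == n_here:
                    break
            if len(chosen) < n_here:   # relax separation rather than fail
                for idx in order:
                    cell = cand[idx]
                    if tuple(cell) in used or any(
                            (cell == c).all() for c in chosen):
                        continue
                    chosen.append(cell)
                    if len(chosen) == n_here:
                        break
            if len(chosen) < n_here:
                raise ValueError(
                    f"cannot place {n_here} distinct sites in gradient "
                    f"{g + 1}, band {b + 1}")
            for p, (r, c) in enumerate(chosen):
                used.add((int(r), int(c)))
                lon, lat = stack.center_of(r, c)
                rows_out.append({
                    "population_id": f"G{g + 1}B{b + 1}P{p + 1}",
                    "lon": float(lon), "lat": float(lat),
                    "gradient": g + 1, "band": b + 1,
                    "elevation": float(elev[r, c]),
                    "row": int(r), "col": int(c),
                })
    return pd.DataFrame(rows_out)


def generate_true_suitability(stack: EnvRasterStack,
                              truth_spec: Mapping[str, Mapping[str, float]]
                              ) -> SyntheticTruth:
    """Build the true habitat-suitability surface from named layers.

    ``truth_spec`` maps layer name to ``{"linear": w1, "quad": w2,
    "center": c}`` terms on the min-max scaled layer; suitability is the
    inverse-logit of the summed terms, min-max rescaled to [0, 1] (left
    as-is when constant).  No-data cells are NaN.
    """
    eta = np.zeros(stack.shape)
    for name, terms in truth_spec.items():
        if name not in stack.layer_names:
            raise KeyError(f"layer {name!r} not in stack")
        lay = stack.layer(name)
        lo, hi = np.nanmin(lay), np.nanmax(lay)
        z = (lay - lo) / (hi - lo) if hi > lo else np.zeros_like(lay)
        eta = eta + terms.get("linear", 0.0) * z
        quad = terms.get("quad", 0.0)
        if quad:
            eta = eta + quad * (z - terms.get("center", 0.5)) ** 2
    suit = expit(eta)
    suit = np.where(stack.nodata_mask, np.nan, suit)
    rng_span = np.nanmax(suit) - np.nanmin(suit)
    if rng_span > 1e-12:
        suit = (suit - np.nanmin(suit)) / rng_span
    return SyntheticTruth(true_suitability=suit,
                          true_variable_set=list(truth_spec))


def default_truth_spec(stack: EnvRasterStack,
                       n_drivers: int = 3) -> dict[str, dict[str, float]]:
    """A mixed linear/quadratic truth over the first few non-elevation,
    non-correlated-duplicate layers."""
    skip = {lb for info in (stack.layer_info or {},)
            for lb, v in info.items() if "correlated_with" in v}
    drivers = [n for n in stack.layer_names
               if n != "elev" and n not in skip][:n_drivers]
    spec: dict[str, dict[str, float]] = {}
    shapes = ({"linear": 6.0}, {"quad": -12.0, "center": 0.5},
              {"linear": -4.0})
    for name, shape in zip(drivers, shapes):
        spec[name] = dict(shape)
    return spec


def assign_ecotypes(sites: pd.DataFrame) -> dict[str, int]:
    """True ecotype = the site's elevation band (1..3)."""
    return dict(zip(sites["population_id"], sites["band"].astype(int)))


def generate_traits(sites: pd.DataFrame, stack: EnvRasterStack,
                    truth: SyntheticTruth,
                    config: LandscapeConfig) -> pd.DataFrame:
    """Simulate the individual-level trait table.

    Each bird's trait value is intercept + ecotype shift + sex effect +
    environmental smooth + Gaussian residual; non-signal traits carry no
    ecotype shift or smooth.  Effect sizes are expressed in residual-SD
    units (taken as 1 unit when ``noise_sd`` is 0, so injected shifts remain
    recoverable exactly in the zero-noise limit).
    """
    cfg = config
    if not truth.ecotype_of_pop:
        truth.ecotype_of_pop = assign_ecotypes(sites)
    names = cfg.trait_names
    env_cols = truth.true_variable_set or [
        n for n in stack.layer_names if n != "elev"][:3]
    site_env = {}
    for _, s in sites.iterrows():
        vals = {}
        for k in env_cols:
            lay = stack.layer(k)
            lo, hi = np.nanmin(lay), np.nanmax(lay)
            v = lay[int(s["row"]), int(s["col"])]
            vals[k] = (v - lo) / (hi - lo) if hi > lo else 0.0
        site_env[s["population_id"]] = vals

    sd_unit = cfg.noise_sd if cfg.noise_sd > 0 else 1.0
    rng = _stream_rng(cfg.seed, 23)
    rows = []
    truth.trait_functions = {}
    for t, name in enumerate(names):
        signal = t < cfg.n_signal_traits
        alpha = SIGNAL_TRAIT_BASELINES.get(name, 10.0 + t)
        pattern = _ECOTYPE_PATTERNS[t % len(_ECOTYPE_PATTERNS)]
        delta = cfg.effect_sizes[t] if signal else 0.0
        beta = tuple(p * delta for p in pattern)
        sex_eff = 1.5 if signal else 0.5
        smooth_cov = env_cols[t % len(env_cols)] if signal else None
        amp = cfg.smooth_amplitude if signal else 0.0
        truth.trait_functions[name] = {
            "alpha": alpha, "beta": beta, "sex_effect": sex_eff,
            "smooth": ({"covariate": smooth_cov, "form": "amp*sin(2*pi*z)",
                        "amplitude": amp} if smooth_cov and amp else None),
            "signal": bool(signal),
        }
    for _, s in sites.iterrows():
        pop = s["population_id"]
        eco = truth.ecotype_of_pop[pop]
        for j in range(cfg.hens_per_pop + cfg.cocks_per_pop):
            sex = "hen" if j < cfg.hens_per_pop else "cock"
            rec = {"population_id": pop, "sex": sex,
                   "individual": f"{pop}_{j + 1:02d}"}
            for t, name in enumerate(names):
                fn = truth.trait_functions[name]
                val = fn["alpha"] + fn["beta"][eco - 1] * sd_unit
                if sex == "cock":
                    val += fn["sex_effect"] * sd_unit
                if fn["smooth"] is not None:
                    z = site_env[pop][fn["smooth"]["covariate"]]
                    val += (fn["smooth"]["amplitude"] * sd_unit
                            * np.sin(2.0 * np.pi * z))
                if cfg.noise_sd > 0:
                    val += rng.normal(0.0, cfg.noise_sd)
                else:
                    rng.normal(0.0, 1.0)  # keep stream alignment
                rec[name] = val
            rows.append(rec)
    return pd.DataFrame(rows)


def sample_presences(stack: EnvRasterStack, suitability: np.ndarray,
                     n: int, seed: int | np.random.Generator,
                     power: float = 1.0) -> pd.DataFrame:
    """Sample presence points (cell centers) with probability proportional
    to ``suitability**power``, with replacement."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    rows, cols = stack.valid_cells()
    w = np.asarray(suitability)[rows, cols].astype(float) ** power
    w = np.where(np.isfinite(w), w, 0.0)
    if w.sum() <= 0:
        raise ValueError("suitability has no positive mass")
    idx = rng.choice(len(rows), size=n, replace=True, p=w / w.sum())
    lon, lat = stack.center_of(rows[idx], cols[idx])
    return pd.DataFrame({"population_id": "sim", "lon": lon, "lat": lat,
                         "role": "center"})


def simulate_study(config: LandscapeConfig | None = None,
                   truth_spec: Mapping | None = None):
    """Generate the full synthetic study: stack, sites, truth, traits."""
    cfg = config or LandscapeConfig()
    stack = generate_env_stack(cfg)
    sites = place_populations(cfg, stack)
    truth = generate_true_suitability(
        stack, truth_spec or default_truth_spec(stack))
    truth.ecotype_of_pop = assign_ecotypes(sites)
    traits = generate_traits(sites, stack, truth, cfg)
    return stack, sites, truth, traits


def write_study(outdir, stack: EnvRasterStack, sites: pd.DataFrame,
                truth: SyntheticTruth, traits: pd.DataFrame):
    """Write rasters (.asc), sites/traits (CSV) and truth (YAML sidecar)."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stack(stack, outdir / "layers")
    sites.to_csv(outdir / "sites.csv", index=False)
    traits.to_csv(outdir / "traits.csv", index=False)
    doc = {
        "true_variable_set": list(truth.true_variable_set),
        "ecotype_of_pop": {k: int(v) for k, v in
                           truth.ecotype_of_pop.items()},
        "trait_functions": _yamlable(truth.trait_functions),
    }
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    np.savetxt(outdir / "true_suitability.txt", truth.true_suitability)
    return outdir


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
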