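"""End-to-end workflow: simulate -> SDM -> niches -> ecotypes ->
concordance -> GAM -> report.

Each stage reads its inputs from the output directory, writes its
artifacts there, and records a manifest (stage name, parameters, seed,
SHA-256 hashes of the files it wrote), so a rerun with the same seed is
hash-identical and any stage can be rerun in isolation.  Stage seeds are
derived from one root seed with ``numpy.random.SeedSequence([root,
stage_index])``, in the fixed stage order below.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (concordance, geodata, maxent, niche_clustering,
               pdm_gam, synthetic_landscape, trait_analysis)

STAGES = ("simulate", "sdm", "niches", "ecotypes", "concord", "gam",
          "report")


@dataclass
class PipelineConfig:
    """Workflow configuration (YAML-serializable)."""

    outdir: str = "nichepheno_out"
    seed: int = 0
    landscape: dict = field(default_factory=dict)
    # SDM stage
    combos: tuple = maxent.DEFAULT_COMBOS
    rm_values: tuple = maxent.DEFAULT_RMS
    n_background: int = 2000
    n_knots: int = 6
    use_bias: bool = True
    corr_thresh: float = 0.6
    contrib_thresh: float = 4.0
    per_pop_combo: str = "LQ"
    per_pop_rm: float = 1.0
    # clustering
    n_niches: int = 3
    overlap_mode: str = "rows"
    # traits
    sle: float = 0.15
    sls: float = 0.15
    ecotype_sex: str = "hen"
    k_range: tuple = (2, 8)
    # GAM
    gam_basis: str = "gp"
    gam_k: int = 8

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def landscape_config(self) -> synthetic_landscape.LandscapeConfig:
        kw = dict(self.landscape)
        kw.setdefault("seed", self.seed)
        if "bands" in kw:
            kw["bands"] = tuple(tuple(b) for b in kw["bands"])
        return synthetic_landscape.LandscapeConfig(**kw)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(root_seed), idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict,
                    outputs: list[Path], t0: float) -> None:
    manifest = {
        "stage": stage,
        "params": params,
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": {str(p.relative_to(outdir)): _sha256(p)
                    for p in outputs},
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(outdir: Path, filename: str, produced_by: str) -> Path:
    p = outdir / filename
    if not p.exists():
        raise FileNotFoundError(
            f"missing artifact {filename!r}; run the {produced_by!r} "
            "stage first")
    return p


def _read_csv(path: Path, required: tuple = ()) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise RuntimeError(f"corrupt intermediate file {path}: {exc}") \
            from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RuntimeError(f"corrupt intermediate file {path}: missing "
                           f"columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig) -> Path:
    t0 = time.time()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lcfg = cfg.landscape_config()
    lcfg = dataclasses.replace(lcfg, seed=stage_seed(cfg.seed, "simulate"))
    stack, sites, truth, traits = synthetic_landscape.simulate_study(lcfg)
    synthetic_landscape.write_study(outdir / "study", stack, sites, truth,
                                    traits)
    outputs = sorted((outdir / "study").rglob("*.*"))
    _write_manifest(outdir, "simulate",
                    {"landscape": dataclasses.asdict(lcfg)}, outputs, t0)
    return outdir


def _load_study(outdir: Path):
    study = outdir / "study"
    _require(study, "sites.csv", "simulate")
    layer_paths = sorted((study / "layers").glob("*.asc"))
    stack = geodata.read_stack(layer_paths)
    sites = _read_csv(study / "sites.csv",
                      required=("population_id", "lon", "lat"))
    traits = _read_csv(study / "traits.csv",
                       required=("population_id", "sex"))
    with open(study / "truth.yaml") as fh:
        truth_doc = yaml.safe_load(fh)
    return stack, sites, traits, truth_doc


def run_sdm(cfg: PipelineConfig) -> Path:
    """Occurrence expansion, tuning, variable selection, importance, and
    per-population suitability maps."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    stack, sites, _traits, _truth = _load_study(outdir)
    seed = stage_seed(cfg.seed, "sdm")
    occ = geodata.expand_occurrences(sites, extent=stack.extent)
    occ_env = geodata.extract_env(occ, stack)
    pres = occ_env.copy()
    bias = geodata.kernel_bias(occ, stack) if cfg.use_bias else None
    n_bg = min(cfg.n_background, int((~stack.nodata_mask).sum()))
    bg = geodata.sample_background(stack, n_bg, bias, seed)
    bg_env = geodata.extract_env(bg, stack)
    cells = stack.cell_table()
    layers = [n for n in stack.layer_names if n != "elev"]

    tune_res = maxent.tune(pres, bg_env, layers, cells,
                           combos=cfg.combos, rm_values=cfg.rm_values,
                           n_knots=cfg.n_knots)
    sel_combo = str(tune_res.selected["combo"])
    sel_rm = float(tune_res.selected["rm"])
    selected = maxent.select_variables(
        pres, bg_env, layers, cfg.corr_thresh, cfg.contrib_thresh,
        combo=sel_combo.replace("T", "").replace("P", "") or "LQ",
        rm=sel_rm, n_knots=cfg.n_knots)
    fs = maxent.build_features(bg_env, selected, sel_combo, cfg.n_knots)
    model = maxent.fit_maxent(fs.transform(pres), fs.transform(bg_env),
                              sel_rm, fs)
    pct = maxent.percent_contribution(model)
    jack = maxent.jackknife(selected, pres, bg_env, combo="LQH",
                            rm=sel_rm, n_knots=cfg.n_knots) \
        if len(selected) >= 2 else pd.DataFrame()

    # overall suitability surface
    suit = np.full(stack.shape, np.nan)
    logi = model.predict(cells, "logistic")
    suit[cells["row"].to_numpy(), cells["col"].to_numpy()] = logi
    geodata.write_ascii_grid(suit, stack.extent, stack.cell_size,
                             outdir / "suitability.asc")

    # per-population suitability maps from each population's own records
    pop_dir = outdir / "pop_maps"
    pop_dir.mkdir(exist_ok=True)
    pop_paths = []
    for pop, sub in pres.groupby("population_id"):
        fs_p = maxent.build_features(bg_env, selected, cfg.per_pop_combo,
                                     cfg.n_knots)
        m_p = maxent.fit_maxent(fs_p.transform(sub),
                                fs_p.transform(bg_env),
                                cfg.per_pop_rm, fs_p)
        smap = np.full(stack.shape, np.nan)
        smap[cells["row"].to_numpy(), cells["col"].to_numpy()] = \
            m_p.predict(cells, "logistic")
        p = pop_dir / f"{pop}.asc"
        geodata.write_ascii_grid(smap, stack.extent, stack.cell_size, p)
        pop_paths.append(p)

    occ.records.to_csv(outdir / "occurrences.csv", index=False)
    tune_res.table.to_csv(outdir / "tuning.csv", index=False)
    pct.rename("percent_contribution").to_csv(outdir / "contribution.csv")
    if len(jack):
        jack.to_csv(outdir / "jackknife.csv")
    pd.Series(selected, name="variable").to_csv(
        outdir / "selected_variables.csv", index=False)
    outputs = [outdir / "occurrences.csv", outdir / "tuning.csv",
               outdir / "contribution.csv",
               outdir / "selected_variables.csv",
               outdir / "suitability.asc"] + pop_paths
    if len(jack):
        outputs.append(outdir / "jackknife.csv")
    _write_manifest(outdir, "sdm",
                    {"seed": seed, "combo": sel_combo, "rm": sel_rm,
                     "selected": list(selected)}, outputs, t0)
    return outdir


def run_niches(cfg: PipelineConfig) -> Path:
    t0 = time.time()
    outdir = Path(cfg.outdir)
    pop_dir = outdir / "pop_maps"
    if not pop_dir.exists():
        raise FileNotFoundError("missing pop_maps/; run the 'sdm' stage "
                                "first")
    maps = {}
    for p in sorted(pop_dir.glob("*.asc")):
        values, _, _ = geodata.read_ascii_grid(p)
        maps[p.stem] = values
    overlap = niche_clustering.pairwise_overlap(maps)
    dend, niches, acs = niche_clustering.cluster_niches(
        overlap, k=cfg.n_niches, mode=cfg.overlap_mode)
    overlap.I.to_csv(outdir / "overlap_I.csv")
    overlap.D.to_csv(outdir / "overlap_D.csv")
    niches.index.name = "population_id"
    niches.to_csv(outdir / "niches.csv")
    (outdir / "niche_dendrogram.nwk").write_text(dend.to_newick() + "\n")
    with open(outdir / "niche_ac.json", "w") as fh:
        json.dump(acs, fh, indent=2, sort_keys=True)
    outputs = [outdir / n for n in
               ("overlap_I.csv", "overlap_D.csv", "niches.csv",
                "niche_dendrogram.nwk", "niche_ac.json")]
    _write_manifest(outdir, "niches",
                    {"k": cfg.n_niches, "mode": cfg.overlap_mode},
                    outputs, t0)
    return outdir


def run_ecotypes(cfg: PipelineConfig) -> Path:
    t0 = time.time()
    outdir = Path(cfg.outdir)
    traits = _read_csv(_require(outdir / "study", "traits.csv",
                                "simulate"),
                       required=("population_id", "sex"))
    stepwise = trait_analysis.stepwise_by_sex(traits, sle=cfg.sle,
                                              sls=cfg.sls)
    sel = stepwise.get(cfg.ecotype_sex)
    selected = sel.selected if sel is not None and sel.selected else \
        trait_analysis.trait_columns(traits)
    M = trait_analysis.population_means(traits, selected,
                                        sex=cfg.ecotype_sex)
    assign = trait_analysis.cluster_ecotypes(
        M, scan_k=True, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1))
    pca = trait_analysis.pca_variance(traits)
    rows = []
    for sex, res in stepwise.items():
        t = res.entries.copy()
        t.insert(0, "sex", sex)
        rows.append(t)
    pd.concat(rows, ignore_index=True).to_csv(
        outdir / "stepwise.csv", index=False)
    assign.labels.to_csv(outdir / "ecotypes.csv")
    assign.silhouette_curve.to_csv(outdir / "silhouette.csv", index=False)
    pca.to_csv(outdir / "pca.csv", index=False)
    (outdir / "ecotype_dendrogram.nwk").write_text(
        assign.dendrogram.to_newick() + "\n")
    with open(outdir / "ecotype_ac.json", "w") as fh:
        json.dump(assign.ac_by_method, fh, indent=2, sort_keys=True)
    outputs = [outdir / n for n in
               ("stepwise.csv", "ecotypes.csv", "silhouette.csv",
                "pca.csv", "ecotype_dendrogram.nwk", "ecotype_ac.json")]
    _write_manifest(outdir, "ecotypes",
                    {"sle": cfg.sle, "sls": cfg.sls, "k": assign.k,
                     "selected_traits": list(selected)}, outputs, t0)
    return outdir


def run_concord(cfg: PipelineConfig) -> Path:
    t0 = time.time()
    outdir = Path(cfg.outdir)
    sites = _read_csv(_require(outdir / "study", "sites.csv", "simulate"))
    eco = _read_csv(_require(outdir, "ecotypes.csv", "ecotypes"))
    eco = eco.set_index(eco.columns[0])["ecotype"]
    niches = _read_csv(_require(outdir, "niches.csv", "niches"))
    niches = niches.set_index(niches.columns[0])["niche"]
    schemes = {
        "sdm_niche": niches,
        "elevation_bands": concordance.classify_environment(
            sites, "elevation_bands"),
        "gradient": concordance.classify_environment(sites, "gradient"),
    }
    comp = concordance.compare_classifications(eco, schemes)
    ct = concordance.concordance_table(eco, niches)
    ct.per_ecotype.to_csv(outdir / "concordance_sdm.csv")
    comp.to_csv(outdir / "concordance_compare.csv", index=False)
    outputs = [outdir / "concordance_sdm.csv",
               outdir / "concordance_compare.csv"]
    _write_manifest(outdir, "concord",
                    {"overall_count": ct.overall_count,
                     "overall_pct_exact": ct.overall_pct_exact,
                     "overall_pct_mean": ct.overall_pct_mean},
                    outputs, t0)
    return outdir


def run_gam(cfg: PipelineConfig) -> Path:
    t0 = time.time()
    outdir = Path(cfg.outdir)
    stack, sites, traits, _ = _load_study(outdir)
    eco = _read_csv(_require(outdir, "ecotypes.csv", "ecotypes"))
    eco = eco.set_index(eco.columns[0])["ecotype"]
    niches = _read_csv(_require(outdir, "niches.csv", "niches"))
    niches = niches.set_index(niches.columns[0])["niche"]
    selected_vars = _read_csv(
        _require(outdir, "selected_variables.csv", "sdm"))["variable"] \
        .tolist()
    stepwise = _read_csv(_require(outdir, "stepwise.csv", "ecotypes"))
    sel_traits = stepwise.loc[stepwise["sex"] == cfg.ecotype_sex,
                              "trait"].tolist() \
        or trait_analysis.trait_columns(traits)[:4]
    site_env = geodata.extract_env(sites, stack)
    env_cols = [v for v in selected_vars if v in site_env.columns]
    data = traits[traits["sex"] == cfg.ecotype_sex].merge(
        site_env[["population_id"] + env_cols], on="population_id")
    data["ecotype"] = data["population_id"].map(eco)
    data["niche"] = data["population_id"].map(niches)
    summary = pdm_gam.fit_trait_gams(data, sel_traits, env_cols,
                                     basis=cfg.gam_basis, k=cfg.gam_k)
    summary.to_csv(outdir / "gam_summary.csv", index=False)
    pdp_dir = outdir / "pdp"
    pdp_dir.mkdir(exist_ok=True)
    outputs = [outdir / "gam_summary.csv"]
    fits = summary.attrs["fits"]
    for tr, fit in fits.items():
        for blk in fit.design.smooth_blocks:
            curve = pdm_gam.partial_dependence(fit, blk.term.covariate)
            p = pdp_dir / f"{tr}_{blk.term.covariate}.csv"
            curve.to_frame().to_csv(p, index=False)
            outputs.append(p)
    _write_manifest(outdir, "gam",
                    {"traits": sel_traits, "covariates": env_cols,
                     "basis": cfg.gam_basis, "k": cfg.gam_k},
                    outputs, t0)
    return outdir


def run_report(cfg: PipelineConfig) -> Path:
    """Assemble one markdown report from the stage artifacts."""
    t0 = time.time()
    outdir = Path(cfg.outdir)
    parts = ["# Integrated SDM + PDM report\n"]

    def section(title, path, reader=pd.read_csv, fmt=None):
        parts.append(f"\n## {title}\n")
        p = outdir / path
        if not p.exists():
            parts.append(f"_missing: {path}_\n")
            return
        if reader is None:
            parts.append("```\n" + p.read_text() + "```\n")
            return
        df = reader(p)
        parts.append((fmt(df) if fmt else df.to_string(index=False))
                     + "\n")

    section("Model tuning (feature combo x regularization multiplier)",
            "tuning.csv")
    section("Selected environmental variables", "selected_variables.csv")
    section("Percent contribution", "contribution.csv")
    section("Jackknife gains", "jackknife.csv")
    section("Niche dendrogram (newick)", "niche_dendrogram.nwk",
            reader=None)
    section("Ecotype assignment", "ecotypes.csv")
    section("Ecotype-niche concordance", "concordance_sdm.csv")
    section("Classification comparison", "concordance_compare.csv")
    section("GAM summaries", "gam_summary.csv")
    (outdir / "report.md").write_text("".join(parts))
    _write_manifest(outdir, "report", {}, [outdir / "report.md"], t0)
    return outdir / "report.md"


STAGE_FUNCS = {
    "simulate": run_simulate, "sdm": run_sdm, "niches": run_niches,
    "ecotypes": run_ecotypes, "concord": run_concord, "gam": run_gam,
    "report": run_report,
}


def run_stage(name: str, cfg: PipelineConfig):
    if name == "all":
        for stage in STAGES:
            STAGE_FUNCS[stage](cfg)
        return Path(cfg.outdir)
    if name not in STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; one of {STAGES} or "
                         "'all'")
    return STAGE_FUNCS[name](cfg)
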