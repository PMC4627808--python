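"""End-to-end orchestration: simulate/load -> metrics -> correlograms
-> Poisson GLMMs -> land-use models, with all result tables on disk.

The run writes, under the output directory:

* ``plot_metrics.csv`` — per-plot diversity, cover, soil and CWM columns
  (NaN where the trait-coverage rule omits a plot);
* ``correlograms.csv`` / ``pattern_summary.csv`` — per-site Mantel
  correlograms for species composition, trait composition and
  herbivore counts, with the pattern classification;
* ``moran_exclusions.csv`` — global Moran's I per site and which sites
  were dropped from the count models;
* ``glmm_total.csv`` / ``glmm_<family>.csv`` — predictor rankings for
  the herbivore ensemble and the most abundant family;
* ``mcc_lmm.csv`` — retained terms of the mixed model of Mantel
  coefficients vs land-use intensity, water-holding capacity and
  distance;
* ``site_lm.csv`` — site-level OLS of abundance, count variance and
  species richness on land-use intensity;
* ``manifest.json`` — config, seeds, package versions and collected
  warnings; enough to re-run bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import community_metrics as cm
from . import mixed_models as mm
from . import spatial_stats as ss
from .community_metrics import TRAITS
from .synthetic_data import SimConfig, TransectDataset, generate_dataset

__all__ = [
    "RunConfig",
    "read_fixtures",
    "compute_plot_metrics",
    "site_covariates",
    "most_abundant_family",
    "run_full",
]


@dataclass
class RunConfig:
    """Knobs of one full analysis run."""
    input_dir: str | None = None            # read fixtures from here ...
    sim: SimConfig | None = None            # ... or simulate with this config
    out_dir: str = "results"
    coverage_threshold: float = 0.8
    alpha: float = 0.05
    n_perm: int = 999
    n_boot: int = 500
    block_size: int = 3
    bootstrap_p: bool = True                # bootstrap p per GLMM predictor
    mcc_p_method: str = "bootstrap"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.coverage_threshold < 1 or not 0 < self.alpha < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        if min(self.n_perm, self.n_boot, self.block_size) <= 0:
            raise ValueError("counts must be positive")


# ---------------------------------------------------------------------------
# fixture readers
# ---------------------------------------------------------------------------

def read_fixtures(directory):
    """Read the four delimited-text tables back into datasets.

    Inverse of :func:`rootpatch.synthetic_data.write_fixtures`.
    Returns (pool, datasets, site_table).
    """
    directory = Path(directory)
    for name in ("cover.csv", "traits.csv", "cores.csv", "sites.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing input table {name}")
    pool = pd.read_csv(directory / "traits.csv", index_col="species")
    cover_all = pd.read_csv(directory / "cover.csv")
    cores_all = pd.read_csv(directory / "cores.csv")
    site_table = pd.read_csv(directory / "sites.csv")
    spacing = 0.3
    mpath = directory / "manifest.json"
    if mpath.exists():
        with open(mpath) as fh:
            spacing = float(json.load(fh).get("spacing", spacing))

    _validate_tables(pool, cover_all, cores_all, site_table)

    datasets = []
    meta_cols = ("site_id", "plot_index", "bare_soil")
    for _, srow in site_table.iterrows():
        sid = srow["site_id"]
        cov = (cover_all[cover_all["site_id"] == sid]
               .sort_values("plot_index").set_index("plot_index"))
        bare = cov["bare_soil"].to_numpy() if "bare_soil" in cov else None
        sp = cov.drop(columns=[c for c in meta_cols if c in cov.columns])
        sp = sp.loc[:, sp.sum(axis=0) > 0]
        cores = (cores_all[cores_all["site_id"] == sid]
                 .drop(columns="site_id").reset_index(drop=True))
        soil = (cores[["plot_index", "fresh_wt_g", "dry_wt_g",
                       "root_dry_mass_g"]]
                .drop_duplicates("plot_index").reset_index(drop=True))
        counts = cores[["plot_index", "family", "count"]].copy()
        whc = pd.DataFrame({
            "sat_wt_g": [srow["whc_sat_wt_g_1"], srow["whc_sat_wt_g_2"]],
            "dry_wt_g": [srow["whc_dry_wt_g_1"], srow["whc_dry_wt_g_2"]]})
        positions = sp.index.to_numpy(float) * spacing
        datasets.append(TransectDataset(
            site_id=sid, region_id=srow["region_id"],
            plot_positions=positions, cover=sp, counts=counts, soil=soil,
            whc_cores=whc,
            management={"F": srow["F"], "M": srow["M"], "G": srow["G"]},
            bare_soil=bare))
    return pool, datasets, site_table


def _validate_tables(pool, cover, cores, sites):
    problems = []
    if pool.isna().all(axis=None):
        problems.append("trait table has no values")
    for col in ("site_id", "plot_index"):
        if col not in cover.columns:
            problems.append(f"cover table lacks column {col!r}")
    for col in ("site_id", "plot_index", "family", "count",
                "fresh_wt_g", "dry_wt_g", "root_dry_mass_g"):
        if col not in cores.columns:
            problems.append(f"core table lacks column {col!r}")
    for col in ("site_id", "region_id", "F", "M", "G"):
        if col not in sites.columns:
            problems.append(f"site table lacks column {col!r}")
    if not problems:
        sp_cols = [c for c in cover.columns
                   if c not in ("site_id", "plot_index", "bare_soil")]
        if (cover[sp_cols].to_numpy(float) < 0).any():
            problems.append("negative covers")
        if (cores["count"].to_numpy() < 0).any():
            problems.append("negative counts")
    if problems:
        raise ValueError("input validation failed: " + "; ".join(problems))


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def compute_plot_metrics(datasets: list, pool: pd.DataFrame,
                         coverage_threshold: float = 0.8) -> pd.DataFrame:
    """Tidy per-plot metrics table across all sites."""
    frames = []
    for d in datasets:
        cov = d.cover
        vals, _frac = cm.cwm_table(cov, pool, coverage_threshold)
        n = len(cov)
        rows = {
            "site_id": [d.site_id] * n,
            "region_id": [d.region_id] * n,
            "plot_index": cov.index.to_numpy(),
            "position_m": d.plot_positions,
            "richness": (cov > 0).sum(axis=1).to_numpy(),
            "total_cover": cov.sum(axis=1).to_numpy(),
        }
        h = np.array([cm.shannon(row) for row in cov.to_numpy()])
        s = rows["richness"]
        rows["shannon"] = h
        rows["evenness"] = np.where(s >= 2, h / np.where(s >= 2, np.log(
            np.maximum(s, 2)), 1.0), np.nan)
        soil = d.soil.set_index("plot_index").reindex(cov.index)
        rows["wc"] = [cm.water_content(f, w) for f, w in
                      zip(soil["fresh_wt_g"], soil["dry_wt_g"])]
        rows["root_dry_mass"] = soil["root_dry_mass_g"].to_numpy()
        rows["bare_soil"] = (d.bare_soil if d.bare_soil is not None
                             else np.full(n, np.nan))
        rows["count"] = d.counts_per_core()
        frame = pd.DataFrame(rows)
        for t in pool.columns:
            frame[f"cwm_{t}"] = vals[t].to_numpy()
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def site_covariates(datasets: list, site_table: pd.DataFrame) -> pd.DataFrame:
    """Per-site LUI (regional reference means) and WHC (mean of 2 cores)."""
    refs = site_table.groupby("region_id")[["F", "M", "G"]].mean()
    rows = []
    for d in datasets:
        ref = refs.loc[d.region_id]
        lui = cm.lui_index(cm.SiteManagement(
            F=d.management["F"], M=d.management["M"], G=d.management["G"],
            F_ref=ref["F"], M_ref=ref["M"], G_ref=ref["G"]))
        whc = float(np.mean([cm.water_holding_capacity(s, w) for s, w in
                             zip(d.whc_cores["sat_wt_g"],
                                 d.whc_cores["dry_wt_g"])]))
        rows.append({"site_id": d.site_id, "region_id": d.region_id,
                     "lui": lui, "whc": whc})
    return pd.DataFrame(rows)


def most_abundant_family(core_table: pd.DataFrame) -> tuple[str, float]:
    """Family with the largest total count and its percent share.

    Ties go to the lexicographically first family (flagged by a
    warning).  Raises on an empty or all-zero table.
    """
    totals = core_table.groupby("family")["count"].sum().sort_index()
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("no herbivores recorded")
    best = totals.idxmax()          # first index at the max (sorted)
    if (totals == totals.max()).sum() > 1:
        warnings.warn("tie for most abundant family; choosing "
                      f"{best!r} (lexicographic)", stacklevel=2)
    return best, float(totals.loc[best] / grand * 100.0)


# correlogram responses analysed per site
_CORRELOGRAM_PARAMS = ("species_composition", "trait_composition",
                       "herbivore_counts")


def _site_correlograms(d: TransectDataset, metrics: pd.DataFrame,
                       cwm_cols: list, cfg: RunConfig, seed) -> dict:
    """Correlograms for one site, keyed by parameter name."""
    classes = ss.sturges_classes(d.plot_positions)
    msite = metrics[metrics["site_id"] == d.site_id]
    out = {}
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    rng = seed.spawn(3)
    dm = ss.bray_curtis(d.cover.to_numpy())
    out["species_composition"] = ss.mantel_correlogram(
        dm, classes, cfg.n_perm, cfg.alpha, rng[0])

    # trait composition: complete CWM rows, columns standardized so no
    # single trait dominates the Euclidean metric
    tr = msite[cwm_cols].dropna()
    if len(tr) >= 4:
        ztr = (tr - tr.mean()) / tr.std(ddof=1).replace(0, 1)
        dt = ss.euclidean(ztr.to_numpy())
        pos = msite.loc[tr.index, "position_m"].to_numpy()
        cls_t = ss.sturges_classes(pos) if len(tr) < len(msite) else classes
        out["trait_composition"] = ss.mantel_correlogram(
            dt, cls_t, cfg.n_perm, cfg.alpha, rng[1])
    counts = d.counts_per_core().astype(float)
    if np.ptp(counts) > 0:
        out["herbivore_counts"] = ss.mantel_correlogram(
            ss.euclidean(counts), classes, cfg.n_perm, cfg.alpha, rng[2])
    return out


_PREDICTORS = ([f"cwm_{t}" for t in TRAITS]
               + ["wc", "root_dry_mass", "total_cover", "bare_soil",
                  "richness", "shannon", "evenness"])


def _fit_rankings(pooled: pd.DataFrame, metrics: pd.DataFrame,
                  cfg: RunConfig, seed) -> pd.DataFrame:
    """One GLMM per predictor on the pooled blocks; ranked table."""
    fits = []
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    child = iter(seed.spawn(len(_PREDICTORS)))
    for pred in _PREDICTORS:
        sub_seed = next(child)
        if pred not in pooled.columns or pooled[pred].dropna().nunique() < 2:
            continue
        try:
            fit = mm.fit_poisson_glmm(pooled, pred,
                                      log_transform=(pred == "bare_soil"))
        except ValueError:
            continue
        if cfg.bootstrap_p:
            reduced = mm.fit_poisson_glmm(
                pooled.dropna(subset=[pred]), None, standardize=False)
            fit.p, _failed = mm.parametric_bootstrap_p(
                fit, reduced, n_boot=cfg.n_boot,
                seed=sub_seed)
        fits.append(fit)
    means = {p: (metrics[p].mean(), metrics[p].std(ddof=1))
             for p in _PREDICTORS if p in metrics.columns}
    return mm.rank_predictors(fits, means)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_full(cfg: RunConfig) -> dict:
    """Run the whole analysis chain; returns the result bundle.

    Deterministic given ``cfg.seed`` (one seed sequence feeds the
    simulation, the correlogram permutations and the bootstrap).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collected_warnings: list[str] = []
    root_ss = np.random.SeedSequence(cfg.seed)
    sim_seed, perm_seed, boot_seed, mcc_seed = root_ss.spawn(4)

    if cfg.input_dir is not None:
        pool, datasets, site_table = read_fixtures(cfg.input_dir)
    else:
        sim = cfg.sim if cfg.sim is not None else SimConfig(
            seed=sim_seed.generate_state(1)[0] % (2**31))
        pool, datasets, site_table = generate_dataset(sim)

    metrics = compute_plot_metrics(datasets, pool, cfg.coverage_threshold)
    metrics.to_csv(out / "plot_metrics.csv", index=False)
    covars = site_covariates(datasets, site_table)

    # --- correlograms & patterns -----------------------------------------
    cwm_cols = [f"cwm_{t}" for t in pool.columns]
    corr_rows, pattern_rows = [], []
    mcc_rows = {p: [] for p in _CORRELOGRAM_PARAMS}
    perm_children = np.random.SeedSequence(
        perm_seed.generate_state(1)[0] % (2**31)).spawn(len(datasets))
    for d, sd in zip(datasets, perm_children):
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            cgs = _site_correlograms(d, metrics, cwm_cols, cfg, sd)
        collected_warnings += [str(w.message) for w in wlist]
        prow = {"site_id": d.site_id}
        for param, cg in cgs.items():
            t = cg.table.copy()
            t.insert(0, "site_id", d.site_id)
            t.insert(1, "parameter", param)
            corr_rows.append(t)
            prow[param] = cg.pattern
            for _, r in cg.table.iterrows():
                mcc_rows[param].append({
                    "site_id": d.site_id, "distance": 0.5 * (r["lower"]
                                                             + r["upper"]),
                    "r": r["r"]})
        pattern_rows.append(prow)
    correlograms = pd.concat(corr_rows, ignore_index=True)
    correlograms.to_csv(out / "correlograms.csv", index=False)
    patterns = pd.DataFrame(pattern_rows)
    patterns.to_csv(out / "pattern_summary.csv", index=False)

    # --- Moran exclusion ---------------------------------------------------
    moran = {}
    for d, sd in zip(datasets, perm_children):
        counts = d.counts_per_core().astype(float)
        if np.ptp(counts) == 0:
            continue
        moran[d.site_id] = ss.global_morans_i(
            counts, d.plot_positions, n_perm=cfg.n_perm,
            seed=np.random.SeedSequence(sd.generate_state(1)[0] % (2**31) + 1))
    kept_sites, moran_report = mm.exclude_autocorrelated_sites(moran, cfg.alpha)
    moran_report.to_csv(out / "moran_exclusions.csv", index=False)

    # --- GLMM rankings ------------------------------------------------------
    fam, fam_share = most_abundant_family(
        pd.concat([d.counts for d in datasets], ignore_index=True))
    aggs_total, aggs_fam = [], []
    for d in datasets:
        if d.site_id not in kept_sites:
            continue
        msite = (metrics[metrics["site_id"] == d.site_id]
                 .set_index("plot_index").sort_index())
        preds = msite[[c for c in _PREDICTORS if c in msite.columns]]
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            aggs_total.append(mm.aggregate_blocks(
                d.counts_per_core(), preds, d.site_id, d.region_id,
                cfg.block_size))
            fam_counts = (d.counts[d.counts["family"] == fam]
                          .groupby("plot_index")["count"].sum()
                          .reindex(msite.index, fill_value=0).to_numpy())
            aggs_fam.append(mm.aggregate_blocks(
                fam_counts, preds, d.site_id, d.region_id, cfg.block_size))
        collected_warnings += [str(w.message) for w in wlist]

    boot_children = np.random.SeedSequence(
        boot_seed.generate_state(1)[0] % (2**31)).spawn(2)
    ranking_total = _fit_rankings(mm.pool_aggregated(aggs_total), metrics,
                                  cfg, boot_children[0])
    ranking_total.to_csv(out / "glmm_total.csv", index=False)
    try:
        ranking_fam = _fit_rankings(mm.pool_aggregated(aggs_fam), metrics,
                                    cfg, boot_children[1])
    except ValueError:
        ranking_fam = pd.DataFrame()
    ranking_fam.to_csv(out / f"glmm_{fam.lower()}.csv", index=False)

    # --- LMM of Mantel coefficients ----------------------------------------
    structured = [p for p in ("species_composition", "trait_composition")
                  if p in patterns.columns
                  and (patterns[p].fillna("none") != "none").any()]
    mcc_results = {}
    for param in structured:
        tbl = pd.DataFrame(mcc_rows[param]).dropna(subset=["r"])
        mcc_results[param] = mm.fit_mcc_lmm(
            tbl, covars, alpha=cfg.alpha, p_method=cfg.mcc_p_method,
            n_boot=cfg.n_boot,
            seed=mcc_seed.generate_state(1)[0] % (2**31))
    mcc_report = pd.DataFrame(
        [{"parameter": p, "retained": "+".join(f.retained) or "(intercept)",
          "formula": f.formula,
          "dropped": ";".join(f"{r.term}:p={r.p:.4g}"
                              for r in f.dropped.itertuples())}
         for p, f in mcc_results.items()])
    mcc_report.to_csv(out / "mcc_lmm.csv", index=False)

    # --- site-level linear models -------------------------------------------
    per_site = metrics.groupby("site_id").agg(
        total_abundance=("count", "sum"),
        count_variance=("count", "var"),
        species_richness=("richness", "mean")).reset_index()
    per_site = per_site.merge(covars, on="site_id")
    lm_rows = []
    for resp in ("total_abundance", "count_variance", "species_richness"):
        r2, p = mm.fit_site_level_lm(per_site, resp)
        lm_rows.append({"response": resp, "r2": r2, "p": p})
    site_lm = pd.DataFrame(lm_rows)
    site_lm.to_csv(out / "site_lm.csv", index=False)

    # --- manifest -------------------------------------------------------------
    import rootpatch
    cfg_dict = asdict(cfg)
    if cfg_dict.get("sim") is not None:
        for k, v in list(cfg_dict["sim"].items()):
            if isinstance(v, tuple):
                cfg_dict["sim"][k] = list(v)
    manifest = {
        "package": "rootpatch",
        "version": getattr(rootpatch, "__version__", "0"),
        "numpy": np.__version__, "pandas": pd.__version__,
        "config": cfg_dict,
        "seed": cfg.seed,
        "most_abundant_family": {"family": fam, "share_pct": fam_share},
        "excluded_sites": sorted(set(moran_report.loc[
            moran_report["excluded"], "site_id"])) if len(moran_report) else [],
        "warnings": collected_warnings,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return {"metrics": metrics, "correlograms": correlograms,
            "patterns": patterns, "moran": moran_report,
            "ranking_total": ranking_total, "ranking_family": ranking_fam,
            "family": (fam, fam_share), "mcc": mcc_results,
            "site_lm": site_lm, "covariates": covars, "manifest": manifest}
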