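"""Synthetic grassland transect datasets with known ground truth.

Emulates the sampling design the analysis assumes: 28 sites in 3
regions (10 + 9 + 9), one 9 m transect per site with 30 plots/soil
cores at 0.3 m spacing, a ~190-species pool with 10 functional traits,
spatially patchy species composition, and per-core herbivore counts
whose log-mean depends on a community-weighted mean trait with a site
random intercept, zero-inflated so that site totals average ~20
individuals over 30 cores with per-core counts in the 0-22 range.

Vegetation patchiness is built from species-specific Gaussian patch
kernels: each species present at a site receives a Poisson number of
patch centers along the transect and its cover decays with distance
from the nearest centers over ``patch_length_scale``; a couple of
broad "matrix" species keep every plot vegetated.  Expected
between-plot Bray-Curtis similarity therefore decreases with plot
separation, and the decay range is tunable.

Counts are zero-inflated Poisson: a Bernoulli structural-zero mask
with probability ``zero_inflation_pi`` on top of
Poisson(exp(beta0 + region + site intercept + beta_trait * z(CWM))).
Soil measurements are lognormal around site means, with within-site
water-content variation of ~4%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .community_metrics import TRAITS, cwm_table

__all__ = [
    "SimConfig",
    "TransectDataset",
    "generate_species_pool",
    "generate_vegetation",
    "generate_counts",
    "generate_dataset",
    "write_fixtures",
    "DEFAULT_TRAIT_MEANS",
    "DEFAULT_TRAIT_SDS",
    "DEFAULT_FAMILY_SHARES",
]

# Community-level trait means/sds guide the species pool; species-level
# spread is wider than the plot-level spread it induces.
DEFAULT_TRAIT_MEANS = {
    "sla": 20.1, "ldmc": 316.0, "leaf_density": 0.29, "vh": 0.24,
    "rh": 0.39, "leaf_cn": 19.6, "root_cn": 36.6, "vegetative_spread": 0.06,
    "root_density_soil": 0.07, "root_density_topsoil": 0.12,
}
DEFAULT_TRAIT_SDS = {
    "sla": 5.0, "ldmc": 80.0, "leaf_density": 0.08, "vh": 0.12,
    "rh": 0.18, "leaf_cn": 5.0, "root_cn": 10.0, "vegetative_spread": 0.05,
    "root_density_soil": 0.03, "root_density_topsoil": 0.05,
}
# fraction of species without a value, per trait (drives the 80% rule)
DEFAULT_MISSING_FRACTION = {
    "sla": 0.0, "ldmc": 0.0, "leaf_density": 0.06, "vh": 0.01,
    "rh": 0.0, "leaf_cn": 0.04, "root_cn": 0.05, "vegetative_spread": 0.0,
    "root_density_soil": 0.12, "root_density_topsoil": 0.12,
}
# herbivore family composition of the count draws
DEFAULT_FAMILY_SHARES = {
    "Byrrhiidae": 0.002, "Chrysomelidae": 0.045, "Curculionidae": 0.183,
    "Elateridae": 0.430, "Scarabaeidae": 0.002, "Cecidomyiidae": 0.296,
    "Stratiomyidae": 0.004, "Tipulidae": 0.038,
}


@dataclass
class SimConfig:
    """All knobs of the transect generator (defaults = study conditions)."""
    n_regions: int = 3
    sites_per_region: tuple = (10, 9, 9)
    plots_per_site: int = 30
    spacing: float = 0.3                       # m between cores/plots
    n_species: int = 190
    species_per_site: int = 30
    n_matrix_species: int = 3                  # broad-cover dominants
    n_patches_mean: float = 2.0                # Poisson mean patches/species
    patch_length_scale: float = 1.0            # m, kernel sd
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    trait_sds: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SDS))
    missing_fraction: dict = field(
        default_factory=lambda: dict(DEFAULT_MISSING_FRACTION))
    total_cover_mean: float = 95.6             # % per plot
    total_cover_sd: float = 31.1
    bare_soil_mean: float = 9.7
    bare_soil_sd: float = 13.1
    beta0: float = 0.0                         # baseline log-mean count/core
    beta_trait: dict = field(default_factory=lambda: {"sla": 0.3})
    site_intercept_sd: float = 0.3
    region_effects: tuple = (0.0, -0.1, 0.1)
    zero_inflation_pi: float = 0.35
    family_shares: dict = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_SHARES))
    wc_mean: float = 32.7                      # % dry weight, between sites
    wc_between_sd: float = 18.8
    wc_within_cv: float = 0.04                 # ~4% within-site variation
    core_dry_wt_mean: float = 120.0            # g
    root_mass_mean: float = 0.6                # g per core
    root_mass_sd: float = 0.5
    whc_mean: float = 63.0
    whc_sd: float = 26.0
    fertilization_range: tuple = (0.0, 94.0)   # kg N / ha
    mowing_range: tuple = (0, 3)               # cuts / yr
    grazing_range: tuple = (9.0, 1060.0)       # LU d / ha
    seed: int = 0

    def __post_init__(self):
        if len(self.sites_per_region) != self.n_regions:
            raise ValueError("sites_per_region must have n_regions entries")
        if len(self.region_effects) != self.n_regions:
            raise ValueError("region_effects must have n_regions entries")
        if any(sd < 0 for sd in self.trait_sds.values()):
            raise ValueError("trait sds must be non-negative")
        if not 0.0 <= self.zero_inflation_pi <= 1.0:
            raise ValueError("zero_inflation_pi must lie in [0, 1]")
        if self.spacing <= 0 or self.patch_length_scale <= 0:
            raise ValueError("spacing and patch_length_scale must be > 0")
        if self.site_intercept_sd < 0:
            raise ValueError("site_intercept_sd must be >= 0")
        unknown = set(self.trait_means) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits: {sorted(unknown)}")

    @property
    def n_sites(self) -> int:
        return int(sum(self.sites_per_region))

    @property
    def extent(self) -> float:
        return (self.plots_per_site - 1) * self.spacing

    def positions(self) -> np.ndarray:
        return np.arange(self.plots_per_site) * self.spacing


@dataclass
class TransectDataset:
    """One site's aligned vegetation, counts and soil measurements."""
    site_id: str
    region_id: str
    plot_positions: np.ndarray
    cover: pd.DataFrame          # plot x species percent cover
    counts: pd.DataFrame         # plot_index, family, count (long)
    soil: pd.DataFrame           # plot_index, fresh_wt_g, dry_wt_g, root_dry_mass_g
    whc_cores: pd.DataFrame      # two rows: sat_wt_g, dry_wt_g
    management: dict             # F, M, G
    bare_soil: np.ndarray | None = None
    site_intercept: float = 0.0  # ground truth, not written to fixtures

    def counts_per_core(self) -> np.ndarray:
        """Total herbivores per core in transect order."""
        tot = self.counts.groupby("plot_index")["count"].sum()
        return tot.reindex(range(len(self.plot_positions)), fill_value=0).to_numpy()


# ---------------------------------------------------------------------------
# species pool
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with given mean and sd."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    return np.log(mean) - sigma2 / 2, np.sqrt(sigma2)


def generate_species_pool(cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Species x trait table; traits lognormal, some values missing.

    Missing cells (NaN) follow per-trait Bernoulli masks with the
    configured fractions, exercising the downstream coverage rule.
    """
    if cfg.n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    species = [f"sp{k:04d}" for k in range(1, cfg.n_species + 1)]
    data = {}
    for trait in TRAITS:
        mean = cfg.trait_means.get(trait, 1.0)
        sd = cfg.trait_sds.get(trait, 0.0)
        if sd == 0:
            vals = np.full(cfg.n_species, mean)
        else:
            mu, sigma = _lognormal_params(mean, sd)
            vals = rng.lognormal(mu, sigma, cfg.n_species)
        miss = cfg.missing_fraction.get(trait, 0.0)
        if miss > 0:
            vals = np.where(rng.random(cfg.n_species) < miss, np.nan, vals)
        data[trait] = vals
    return pd.DataFrame(data, index=pd.Index(species, name="species"))


# ---------------------------------------------------------------------------
# vegetation
# ---------------------------------------------------------------------------

def generate_vegetation(cfg: SimConfig, pool: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Percent-cover matrix (plots x species) for one site.

    Gaussian patch kernels per species plus a few broad matrix species;
    per-plot totals rescaled to a lognormal around the configured mean
    total cover.  Covers below 0.1% are treated as absence.
    """
    x = cfg.positions()
    idx = rng.choice(cfg.n_species, size=min(cfg.species_per_site,
                                             cfg.n_species), replace=False)
    species = pool.index[np.sort(idx)]
    raw = np.zeros((cfg.plots_per_site, len(species)))
    ell = cfg.patch_length_scale
    # constant expected occupancy: smaller patches come in larger numbers
    patch_rate = cfg.n_patches_mean * np.clip(cfg.extent / (4.0 * ell),
                                              1.0, 8.0)
    for s in range(len(species)):
        if s < cfg.n_matrix_species:
            raw[:, s] = rng.lognormal(np.log(8.0), 0.3) \
                * (1.0 + 0.1 * rng.standard_normal(cfg.plots_per_site))
            continue
        n_patch = rng.poisson(patch_rate)
        if n_patch == 0:
            continue
        centers = rng.uniform(-ell, cfg.extent + ell, n_patch)
        amps = rng.lognormal(np.log(5.0), 0.6, n_patch)
        for c, a in zip(centers, amps):
            raw[:, s] += a * np.exp(-0.5 * ((x - c) / ell) ** 2)
    raw = np.clip(raw, 0.0, None)
    totals = raw.sum(axis=1)
    totals[totals == 0] = 1.0
    mu, sigma = _lognormal_params(cfg.total_cover_mean, cfg.total_cover_sd)
    target = rng.lognormal(mu, sigma, cfg.plots_per_site)
    cover = raw / totals[:, None] * target[:, None]
    cover[cover < 0.1] = 0.0
    # keep every plot vegetated: restore the largest species if zeroed out
    for j in np.where(cover.sum(axis=1) == 0)[0]:
        cover[j, np.argmax(raw[j])] = max(target[j], 1.0)
    plots = pd.Index(range(cfg.plots_per_site), name="plot_index")
    out = pd.DataFrame(cover, index=plots, columns=species)
    return out.loc[:, out.sum(axis=0) > 0]   # drop species absent from the site


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def generate_counts(cfg: SimConfig, cwm: pd.DataFrame, focal_trait: str,
                    rng=None) -> pd.DataFrame:
    """Zero-inflated Poisson herbivore counts per core, all sites.

    ``cwm`` is the pooled plot-level CWM table with columns
    ``site_id``, ``region_id`` and one column per trait; the focal
    trait must have no missing value.  The log-mean is
    beta0 + region effect + site intercept + beta * z(CWM focal),
    z-scored over the pooled plots; structural zeros are drawn with
    probability ``zero_inflation_pi``.  Returns a long table
    (site_id, plot_index, family, count) plus the total column, and
    the drawn site intercepts as a ``site_intercept`` attribute column
    ``_site_b`` merged per site for ground-truth checks.
    """
    if focal_trait not in cwm.columns:
        raise KeyError(f"unknown focal trait {focal_trait!r}")
    vals = cwm[focal_trait].to_numpy(float)
    if np.any(~np.isfinite(vals)):
        raise ValueError("focal trait has missing CWM values")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    sd = vals.std(ddof=1)
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
    beta = cfg.beta_trait.get(focal_trait, 0.0)

    sites = cwm["site_id"].to_numpy()
    regions = cwm["region_id"].to_numpy()
    region_ids = [f"R{r + 1}" for r in range(cfg.n_regions)]
    region_eff = dict(zip(region_ids, cfg.region_effects))
    uniq_sites = pd.unique(sites)
    b = dict(zip(uniq_sites,
                 rng.normal(0.0, cfg.site_intercept_sd, uniq_sites.size)))
    eta = np.array([cfg.beta0 + region_eff[r] + b[s]
                    for s, r in zip(sites, regions)]) + beta * z
    lam = np.exp(eta)
    zero_mask = rng.random(lam.size) < cfg.zero_inflation_pi
    total = np.where(zero_mask, 0, rng.poisson(lam))

    families = sorted(cfg.family_shares)
    shares = np.array([cfg.family_shares[f] for f in families], float)
    shares = shares / shares.sum()
    rows = []
    for k, tot in enumerate(total):
        per_fam = rng.multinomial(tot, shares)
        for fam, c in zip(families, per_fam):
            rows.append({"site_id": sites[k],
                         "plot_index": int(cwm["plot_index"].iloc[k]),
                         "family": fam, "count": int(c)})
    counts = pd.DataFrame(rows)
    counts.attrs["site_intercepts"] = b
    return counts


# ---------------------------------------------------------------------------
# soil and management
# ---------------------------------------------------------------------------

def _generate_soil(cfg: SimConfig, rng: np.random.Generator) -> tuple:
    mu, sigma = _lognormal_params(cfg.wc_mean, cfg.wc_between_sd)
    wc_site = rng.lognormal(mu, sigma)
    wc = wc_site * (1.0 + cfg.wc_within_cv
                    * rng.standard_normal(cfg.plots_per_site))
    wc = np.clip(wc, 0.5, None)
    dry = rng.lognormal(np.log(cfg.core_dry_wt_mean), 0.08, cfg.plots_per_site)
    fresh = dry * (1.0 + wc / 100.0)
    mu_r, s_r = _lognormal_params(cfg.root_mass_mean, cfg.root_mass_sd)
    roots = rng.lognormal(mu_r, s_r, cfg.plots_per_site)
    soil = pd.DataFrame({"plot_index": range(cfg.plots_per_site),
                         "fresh_wt_g": fresh, "dry_wt_g": dry,
                         "root_dry_mass_g": roots})
    whc_site = max(rng.normal(cfg.whc_mean, cfg.whc_sd), 5.0)
    whc_dry = rng.lognormal(np.log(cfg.core_dry_wt_mean), 0.08, 2)
    whc_vals = whc_site * (1.0 + 0.03 * rng.standard_normal(2))
    whc = pd.DataFrame({"sat_wt_g": whc_dry * (1.0 + whc_vals / 100.0),
                        "dry_wt_g": whc_dry})
    return soil, whc


def _generate_management(cfg: SimConfig, rng: np.random.Generator) -> dict:
    return {"F": float(rng.uniform(*cfg.fertilization_range)),
            "M": float(rng.integers(cfg.mowing_range[0],
                                    cfg.mowing_range[1] + 1)),
            "G": float(rng.uniform(*cfg.grazing_range))}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SimConfig):
    """Full synthetic study: trait pool, per-site transects, site table.

    Returns (pool, datasets, site_table).  Deterministic in
    ``cfg.seed``: per-site streams are spawned from one seed sequence.
    """
    ss = np.random.SeedSequence(cfg.seed)
    n_streams = 2 + cfg.n_sites
    children = ss.spawn(n_streams)
    pool_rng = np.random.default_rng(children[0])
    counts_rng = np.random.default_rng(children[1])
    pool = generate_species_pool(cfg, pool_rng)

    focal = next(iter(cfg.beta_trait), "sla")
    site_meta = []
    covers = {}
    site_rngs = {}
    k = 0
    for r in range(cfg.n_regions):
        region_id = f"R{r + 1}"
        for s in range(cfg.sites_per_region[r]):
            site_id = f"S{k + 1:02d}"
            rng = np.random.default_rng(children[2 + k])
            site_rngs[site_id] = rng
            covers[site_id] = generate_vegetation(cfg, pool, rng)
            site_meta.append({"site_id": site_id, "region_id": region_id})
            k += 1

    # generator-truth CWM of the focal trait (no coverage omission)
    frames = []
    for m in site_meta:
        vals, _ = cwm_table(covers[m["site_id"]], pool[[focal]],
                            coverage_threshold=0.0)
        f = vals.reset_index()
        f.insert(0, "site_id", m["site_id"])
        f.insert(1, "region_id", m["region_id"])
        frames.append(f)
    cwm_truth = pd.concat(frames, ignore_index=True)
    counts_all = generate_counts(cfg, cwm_truth, focal, counts_rng)
    site_b = counts_all.attrs["site_intercepts"]

    datasets = []
    rows = []
    positions = cfg.positions()
    for m in site_meta:
        sid, rid = m["site_id"], m["region_id"]
        rng = site_rngs[sid]
        soil, whc = _generate_soil(cfg, rng)
        mgmt = _generate_management(cfg, rng)
        mu_b, s_b = _lognormal_params(max(cfg.bare_soil_mean, 1e-6),
                                      max(cfg.bare_soil_sd, 1e-6))
        bare = rng.lognormal(mu_b, s_b, cfg.plots_per_site)
        datasets.append(TransectDataset(
            site_id=sid, region_id=rid, plot_positions=positions.copy(),
            cover=covers[sid],
            counts=counts_all[counts_all["site_id"] == sid]
                   .drop(columns="site_id").reset_index(drop=True),
            soil=soil, whc_cores=whc, management=mgmt, bare_soil=bare,
            site_intercept=float(site_b[sid])))
        rows.append({"site_id": sid, "region_id": rid, **mgmt,
                     "whc_sat_wt_g_1": whc["sat_wt_g"].iloc[0],
                     "whc_dry_wt_g_1": whc["dry_wt_g"].iloc[0],
                     "whc_sat_wt_g_2": whc["sat_wt_g"].iloc[1],
                     "whc_dry_wt_g_2": whc["dry_wt_g"].iloc[1]})
    return pool, datasets, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"   # shortest-lossless is not stable across rows; 17 digits round-trip


def write_fixtures(pool: pd.DataFrame, datasets: list, site_table: pd.DataFrame,
                   directory) -> dict:
    """Write the four delimited-text input tables plus a manifest.

    Byte-deterministic for a fixed generator seed.  Returns the
    manifest dict (also written as ``manifest.json``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"files": [], "n_sites": len(datasets)}
    if datasets:
        pos = datasets[0].plot_positions
        manifest["spacing"] = float(pos[1] - pos[0])
        manifest["plots_per_site"] = int(len(pos))

    if datasets:
        cov_frames = []
        core_frames = []
        for d in datasets:
            c = d.cover.copy()
            c.insert(0, "site_id", d.site_id)
            c.insert(1, "plot_index", d.cover.index)
            if d.bare_soil is not None:
                c["bare_soil"] = d.bare_soil
            cov_frames.append(c.reset_index(drop=True))
            merged = d.counts.merge(d.soil, on="plot_index")
            merged.insert(0, "site_id", d.site_id)
            core_frames.append(merged)
        cover = pd.concat(cov_frames, ignore_index=True).fillna(0.0)
        # stable species column order
        sp_cols = sorted(c for c in cover.columns
                         if c not in ("site_id", "plot_index", "bare_soil"))
        tail = ["bare_soil"] if "bare_soil" in cover.columns else []
        cover = cover[["site_id", "plot_index"] + sp_cols + tail]
        cores = pd.concat(core_frames, ignore_index=True)
        for name, frame, index in (
                ("cover.csv", cover, False),
                ("traits.csv", pool, True),
                ("cores.csv", cores, False),
                ("sites.csv", site_table, False)):
            path = directory / name
            frame.to_csv(path, index=index, float_format=_FLOAT_FMT)
            manifest["files"].append(name)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
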