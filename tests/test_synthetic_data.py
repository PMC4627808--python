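"""Tests of the transect generator: determinism, marginals, spatial control."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rootpatch import SimConfig
from rootpatch import spatial_stats as ss
from rootpatch import synthetic_data as sd
from rootpatch.pipeline import read_fixtures


def _flat_cfg(**kw):
    base = dict(sites_per_region=(2, 2, 2), n_species=40,
                species_per_site=15, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestSpeciesPool:
    def test_zero_sd_degenerate(self):
        cfg = _flat_cfg(trait_sds={t: 0.0 for t in sd.DEFAULT_TRAIT_SDS},
                        missing_fraction={})
        pool = sd.generate_species_pool(cfg)
        assert (pool.nunique() == 1).all()

    def test_no_missing_when_fraction_zero(self):
        pool = sd.generate_species_pool(_flat_cfg(missing_fraction={}))
        assert not pool.isna().any().any()

    def test_deterministic(self):
        cfg = _flat_cfg(seed=77)
        pd.testing.assert_frame_equal(sd.generate_species_pool(cfg),
                                      sd.generate_species_pool(cfg))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            _flat_cfg(trait_sds={"sla": -1.0})


class TestVegetation:
    def test_similarity_decays_with_distance(self):
        cfg = _flat_cfg(patch_length_scale=1.0)
        pool = sd.generate_species_pool(cfg)
        rng = np.random.default_rng(3)
        near, far = [], []
        for _ in range(10):
            cov = sd.generate_vegetation(cfg, pool, rng)
            d = ss.bray_curtis(cov.to_numpy())
            pos = cfg.positions()
            sep = np.abs(pos[:, None] - pos[None, :])
            iu = np.triu_indices(len(pos), 1)
            near.append(d[iu][sep[iu] <= 0.9].mean())
            far.append(d[iu][sep[iu] >= 6.0].mean())
        assert np.mean(near) < np.mean(far)

    def test_first_class_r_increases_with_patch_scale(self):
        """Spatial control: the first-class Mantel coefficient is
        stochastically increasing in the patch length scale (rank
        correlation over a grid of simulated transects)."""
        scales = [0.1, 0.3, 0.5, 1.0, 2.0]
        ells, rs = [], []
        for k, ell in enumerate(scales):
            cfg = _flat_cfg(patch_length_scale=ell, seed=50 + k)
            pool = sd.generate_species_pool(cfg)
            rng = np.random.default_rng(100 + k)
            cls = ss.sturges_classes(cfg.positions())
            for rep in range(15):
                cov = sd.generate_vegetation(cfg, pool, rng)
                cg = ss.mantel_correlogram(ss.bray_curtis(cov.to_numpy()),
                                           cls, n_perm=99, seed=rep)
                ells.append(ell)
                rs.append(cg.r[0])
        rho, p = spearmanr(ells, rs)
        assert rho > 0 and p < 0.05, (rho, p)

    def test_every_plot_vegetated(self):
        cfg = _flat_cfg(patch_length_scale=0.1)
        pool = sd.generate_species_pool(cfg)
        cov = sd.generate_vegetation(cfg, pool, np.random.default_rng(0))
        assert (cov.sum(axis=1) > 0).all()
        assert (cov.to_numpy() >= 0).all()


def _cwm_frame(cfg, values):
    n = len(values)
    return pd.DataFrame({
        "site_id": np.repeat([f"S{i}" for i in range(n // cfg.plots_per_site)],
                             cfg.plots_per_site),
        "region_id": "R1",
        "plot_index": np.tile(np.arange(cfg.plots_per_site),
                              n // cfg.plots_per_site),
        "sla": values,
    })


class TestCounts:
    def test_all_structural_zeros(self):
        cfg = _flat_cfg(zero_inflation_pi=1.0, n_regions=1,
                        sites_per_region=(2,), region_effects=(0.0,))
        frame = _cwm_frame(cfg, np.random.default_rng(0).normal(20, 2, 60))
        counts = sd.generate_counts(cfg, frame, "sla")
        assert (counts["count"] == 0).all()

    def test_poisson_mean_without_structure(self):
        # beta=0, no site noise, no zero inflation: iid Poisson(exp(beta0))
        cfg = _flat_cfg(n_regions=1, sites_per_region=(10,),
                        region_effects=(0.5,), beta0=0.2,
                        beta_trait={"sla": 0.0}, site_intercept_sd=0.0,
                        zero_inflation_pi=0.0, plots_per_site=100)
        frame = _cwm_frame(cfg, np.random.default_rng(1).normal(20, 2, 1000))
        counts = sd.generate_counts(cfg, frame, "sla", np.random.default_rng(2))
        per_core = counts.groupby(["site_id", "plot_index"])["count"].sum()
        lam = np.exp(0.7)
        se = np.sqrt(lam / len(per_core))
        assert abs(per_core.mean() - lam) < 3 * se

    def test_zero_inflated_marginal_mean(self):
        # per-core mean converges to (1 - pi) * lambda
        pi, beta0 = 0.4, 0.3
        cfg = _flat_cfg(n_regions=1, sites_per_region=(10,),
                        region_effects=(0.0,), beta0=beta0,
                        beta_trait={"sla": 0.0}, site_intercept_sd=0.0,
                        zero_inflation_pi=pi, plots_per_site=1000)
        frame = _cwm_frame(cfg, np.random.default_rng(4).normal(20, 2, 10000))
        counts = sd.generate_counts(cfg, frame, "sla", np.random.default_rng(5))
        per_core = counts.groupby(["site_id", "plot_index"])["count"].sum()
        lam = np.exp(beta0)
        expected = (1 - pi) * lam
        sd_marginal = np.sqrt((1 - pi) * (lam + lam**2) - expected**2)
        assert abs(per_core.mean() - expected) < 4 * sd_marginal / np.sqrt(10000)

    def test_unknown_focal_trait(self):
        cfg = _flat_cfg()
        frame = _cwm_frame(cfg, np.zeros(60))
        with pytest.raises(KeyError):
            sd.generate_counts(cfg, frame, "nonesuch")


class TestDatasetAndFixtures:
    def test_generate_dataset_deterministic(self):
        cfg = _flat_cfg(seed=9)
        p1, d1, s1 = sd.generate_dataset(cfg)
        p2, d2, s2 = sd.generate_dataset(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(s1, s2)
        for a, b in zip(d1, d2):
            pd.testing.assert_frame_equal(a.cover, b.cover)
            pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_roundtrip(self, tmp_path):
        cfg = _flat_cfg(seed=13)
        pool, datasets, sites = sd.generate_dataset(cfg)
        sd.write_fixtures(pool, datasets, sites, tmp_path)
        pool2, datasets2, sites2 = read_fixtures(tmp_path)
        pd.testing.assert_frame_equal(pool, pool2)
        assert len(datasets2) == len(datasets)
        for a, b in zip(datasets, datasets2):
            assert a.site_id == b.site_id and a.region_id == b.region_id
            pd.testing.assert_frame_equal(
                a.cover, b.cover, check_names=False)
            np.testing.assert_array_equal(a.counts_per_core(),
                                          b.counts_per_core())
            np.testing.assert_allclose(a.plot_positions, b.plot_positions)
            np.testing.assert_allclose(a.soil["fresh_wt_g"],
                                       b.soil["fresh_wt_g"])
            assert a.management == pytest.approx(b.management)

    def test_byte_identical_files(self, tmp_path):
        cfg = _flat_cfg(seed=21)
        for sub in ("a", "b"):
            pool, datasets, sites = sd.generate_dataset(cfg)
            sd.write_fixtures(pool, datasets, sites, tmp_path / sub)
        for name in ("cover.csv", "traits.csv", "cores.csv", "sites.csv",
                     "manifest.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_empty_dataset_list(self, tmp_path):
        manifest = sd.write_fixtures(pd.DataFrame(), [], pd.DataFrame(),
                                     tmp_path)
        assert manifest["files"] == []
        assert not (tmp_path / "cover.csv").exists()
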