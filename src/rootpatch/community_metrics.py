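"""Plot-level vegetation and soil descriptors.

Diversity indices (Shannon H', Pielou J'), leaf trait derivations
(SLA, LDMC, leaf density), community-weighted mean (CWM) traits with a
trait-coverage omission rule, the land-use-intensity index (LUI), and
gravimetric soil water content / water-holding capacity.

Conventions
-----------
* Percent covers are used as raw weights; totals may exceed 100 because
  of layered canopies.
* The CWM for a trait is only reported for a plot when species with a
  known value for that trait jointly contribute at least
  ``coverage_threshold`` (default 0.8) of the plot's total cover;
  otherwise the plot is omitted for that trait.  Weights are
  renormalized over the species that have the trait value.
* Soil water quantities are expressed as percent of dry weight, so
  values above 100% are legitimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TRAITS",
    "SiteManagement",
    "shannon",
    "evenness",
    "leaf_traits",
    "cwm",
    "cwm_table",
    "lui_index",
    "water_content",
    "water_holding_capacity",
    "z_standardize",
]

#: Canonical trait columns of the species trait table, in reporting order.
TRAITS = [
    "sla",                  # specific leaf area, mm^2 mg^-1
    "ldmc",                 # leaf dry matter content, mg g^-1
    "leaf_density",         # mg mm^-3
    "vh",                   # vegetative plant height, m
    "rh",                   # reproductive plant height, m
    "leaf_cn",              # leaf C/N ratio, dimensionless
    "root_cn",              # root C/N ratio, dimensionless
    "vegetative_spread",    # m
    "root_density_soil",    # % fill, whole profile
    "root_density_topsoil", # % fill, 0-0.2 m
]


class DegenerateCommunityError(ValueError):
    """Raised when a community has no positive cover (or S too small)."""


# ---------------------------------------------------------------------------
# diversity indices
# ---------------------------------------------------------------------------

def shannon(cover_by_species) -> float:
    """Shannon diversity H' = -sum(p_i ln p_i) of percent covers.

    ``p_i`` is the share of total plant cover held by species *i*;
    zero-cover species contribute nothing.  Raises
    :class:`DegenerateCommunityError` for an all-zero community, which
    is distinct from the legitimate H' = 0 of a monoculture.
    """
    cover = np.asarray(cover_by_species, dtype=float)
    if cover.ndim != 1:
        raise ValueError("cover_by_species must be one-dimensional")
    if np.any(cover < 0):
        raise ValueError("covers must be non-negative")
    total = cover.sum()
    if total <= 0:
        raise DegenerateCommunityError("no species with positive cover")
    p = cover[cover > 0] / total
    return float(-(p * np.log(p)).sum())


def evenness(h: float, s: int) -> float:
    """Pielou evenness J' = H' / ln(S) for species richness S >= 2."""
    if s < 2:
        raise DegenerateCommunityError("evenness undefined for S < 2")
    return float(h / np.log(s))


# ---------------------------------------------------------------------------
# leaf trait derivations
# ---------------------------------------------------------------------------

def leaf_traits(area_mm2: float, fresh_mass_mg: float, dry_mass_mg: float,
                thickness_mm: float) -> tuple[float, float, float]:
    """SLA, LDMC and leaf density from one leaf sample.

    SLA = area / dry mass           [mm^2 mg^-1]
    LDMC = dry mass / fresh mass    [mg g^-1]  (fresh mass given in mg)
    density = dry mass / (area * thickness)  [mg mm^-3]
    """
    for name, v in (("area", area_mm2), ("fresh_mass", fresh_mass_mg),
                    ("dry_mass", dry_mass_mg), ("thickness", thickness_mm)):
        if not v > 0:
            raise ValueError(f"{name} must be > 0")
    if dry_mass_mg > fresh_mass_mg:
        raise ValueError("dry mass cannot exceed fresh mass")
    sla = area_mm2 / dry_mass_mg
    ldmc = dry_mass_mg / (fresh_mass_mg / 1000.0)  # mg per g fresh
    density = dry_mass_mg / (area_mm2 * thickness_mm)
    return sla, ldmc, density


# ---------------------------------------------------------------------------
# community-weighted means
# ---------------------------------------------------------------------------

def cwm(cover_by_species: pd.Series, traits: pd.DataFrame,
        coverage_threshold: float = 0.8) -> tuple[pd.Series, pd.Series]:
    """Community-weighted mean of each trait for one plot.

    Parameters
    ----------
    cover_by_species
        Percent cover indexed by species name; total must be positive.
    traits
        Species x trait table; NaN marks a missing trait value.
    coverage_threshold
        Minimum fraction of total cover that species *with* the trait
        value must contribute for the CWM to be reported.

    Returns
    -------
    (values, covered_fraction)
        Two Series indexed by trait.  ``values`` holds the CWM, with
        NaN where the plot is omitted for that trait;
        ``covered_fraction`` the share of total cover carried by
        species with a known value.
    """
    cover = cover_by_species[cover_by_species > 0]
    total = float(cover.sum())
    if total <= 0:
        raise DegenerateCommunityError("plot has no positive cover")
    values = {}
    covered = {}
    tr = traits.reindex(cover.index)
    for trait in traits.columns:
        tv = tr[trait]
        have = tv.notna()
        frac = float(cover[have].sum()) / total
        covered[trait] = frac
        if frac >= coverage_threshold and have.any():
            w = cover[have] / cover[have].sum()
            values[trait] = float((w * tv[have]).sum())
        else:
            values[trait] = np.nan
    cols = list(traits.columns)
    return (pd.Series(values, index=cols, dtype=float),
            pd.Series(covered, index=cols, dtype=float))


def cwm_table(cover_matrix: pd.DataFrame, traits: pd.DataFrame,
              coverage_threshold: float = 0.8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CWM per plot (rows of ``cover_matrix``) and the coverage fractions."""
    vals = {}
    fracs = {}
    for plot, row in cover_matrix.iterrows():
        v, f = cwm(row, traits, coverage_threshold)
        vals[plot] = v
        fracs[plot] = f
    values = pd.DataFrame(vals).T
    coverage = pd.DataFrame(fracs).T
    values.index = cover_matrix.index
    coverage.index = cover_matrix.index
    return values, coverage


# ---------------------------------------------------------------------------
# land-use intensity
# ---------------------------------------------------------------------------

@dataclass
class SiteManagement:
    """Per-site management intensities and their regional reference means.

    F: fertilization (kg N ha^-1 yr^-1); M: mowing (cuts yr^-1);
    G: grazing (livestock units d ha^-1 yr^-1).
    """
    F: float
    M: float
    G: float
    F_ref: float
    M_ref: float
    G_ref: float


def lui_index(mgmt: SiteManagement) -> float:
    """Land-use intensity index LUI = F/F_R + M/M_R + G/G_R.

    A component whose regional mean is zero contributes zero provided
    the site value is also zero; a positive site value with zero
    regional mean is a data error.
    """
    total = 0.0
    for comp, ref in ((mgmt.F, mgmt.F_ref), (mgmt.M, mgmt.M_ref),
                      (mgmt.G, mgmt.G_ref)):
        if comp < 0 or ref < 0:
            raise ValueError("management intensities must be non-negative")
        if ref == 0:
            if comp > 0:
                raise ValueError("site intensity positive but regional mean zero")
            continue
        total += comp / ref
    return total


# ---------------------------------------------------------------------------
# soil water
# ---------------------------------------------------------------------------

def water_content(fresh_wt: float, dry_wt: float) -> float:
    """Gravimetric water content, % of dry weight."""
    if dry_wt <= 0:
        raise ValueError("dry weight must be positive")
    if fresh_wt < dry_wt:
        raise ValueError("fresh weight below dry weight")
    return (fresh_wt - dry_wt) / dry_wt * 100.0


def water_holding_capacity(saturated_wt: float, dry105_wt: float) -> float:
    """Water-holding capacity, % of dry weight (105 degC dry basis)."""
    return water_content(saturated_wt, dry105_wt)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def z_standardize(values) -> np.ndarray:
    """z-scores with sample (n-1) standard deviation.

    Standardization is meant to run once over the pooled analysis
    dataset (all retained blocks of all sites) so that slopes on
    different predictors are comparable.  NaNs are ignored for the
    moments and propagated in the output.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2 or np.all(finite == finite[0]):
        raise ValueError("z-standardization needs >= 2 distinct values")
    mean = finite.mean()
    sd = finite.std(ddof=1)
    return (x - mean) / sd
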