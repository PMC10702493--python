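"""Taxonomic and spatial aggregation of CFs, and gap-filling proxies.

Taxonomic aggregation is two-step with equal weights: vertebrate groups are
averaged first, then plants and the vertebrate mean are averaged, so every
species group counts the same regardless of how many species it holds.
Spatial aggregation to countries or the globe is an ecoregion-area-weighted
mean (optionally land-use-area-weighted at the global level), with a relative
weighted standard deviation expressing the spatial spread.

Proxies fill missing (ecoregion, class) CFs in a fixed order: rescale from a
sibling intensity of the same land use; else average donor ecoregions of the
same biome and reweight by the target's GEP; a missing GEP is itself proxied
from the biome's GEP-per-area density.  Proxy outputs are flagged and never
overwrite natively computed values, and proxy-derived values are excluded
from donor pools.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PLANTS = "plants"


def aggregate_taxa(cf_by_group: dict[str, float], plants: str = PLANTS) -> float:
    """Equal-weight two-step mean: 0.5 * (CF_plants + mean over vertebrates)."""
    if plants not in cf_by_group:
        raise KeyError("plant CF required for taxonomic aggregation")
    verts = [v for g, v in cf_by_group.items() if g != plants]
    if not verts:
        raise KeyError("at least one vertebrate-group CF required")
    return 0.5 * (cf_by_group[plants] + float(np.mean(verts)))


def weighted_mean_sd(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted mean and weighted SD (population form, weights as masses)."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("at least one positive weight required")
    mean = float(np.sum(weights * values) / total)
    sd = float(np.sqrt(np.sum(weights * (values - mean) ** 2) / total))
    return mean, sd


def aggregate_spatial(
    cfs: pd.Series | np.ndarray, weights: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Area-weighted mean CF and its *relative* weighted SD (SD / mean)."""
    mean, sd = weighted_mean_sd(np.asarray(cfs, float), np.asarray(weights, float))
    rel = sd / mean if mean != 0 else np.nan
    return mean, rel


def aggregate_to_countries(
    cf_table: pd.DataFrame, overlaps: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate ecoregion CFs to countries, weighted by overlap area.

    ``overlaps`` has columns ecoregion, country, overlap_m2.  Output mirrors
    the CF schema with a ``country`` key instead of ``ecoregion`` and a
    populated ``rel_weighted_sd``.
    """
    merged = cf_table.merge(overlaps, on="ecoregion", how="inner")
    keys = ["country", "group", "land_use", "intensity", "approach", "extent", "kind"]
    rows = []
    for key, sub in merged.groupby(keys, sort=True):
        mean, rel = aggregate_spatial(sub["value"], sub["overlap_m2"])
        rows.append(dict(zip(keys, key)) | {
            "value": mean,
            "unit": sub["unit"].iloc[0],
            "proxy_flag": bool(sub["proxy_flag"].any()),
            "rel_weighted_sd": rel,
        })
    return pd.DataFrame(rows)


def aggregate_global(
    cf_table: pd.DataFrame,
    ecoregion_areas: pd.DataFrame,
    landuse_areas: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate ecoregion CFs to a single global value per class and group.

    Default weighting is by ecoregion area (columns ecoregion, area_m2); when
    ``landuse_areas`` (ecoregion, land_use, intensity, area_m2) is supplied an
    alternative land-use-area weighting is reported alongside, which weights
    each ecoregion by how much of the class it actually holds.
    """
    keys = ["group", "land_use", "intensity", "approach", "extent", "kind"]
    merged = cf_table.merge(ecoregion_areas, on="ecoregion", how="inner")
    rows = []
    for key, sub in merged.groupby(keys, sort=True):
        mean, rel = aggregate_spatial(sub["value"], sub["area_m2"])
        row = dict(zip(keys, key)) | {
            "value": mean, "unit": sub["unit"].iloc[0],
            "proxy_flag": bool(sub["proxy_flag"].any()),
            "rel_weighted_sd": rel, "weighting": "ecoregion_area",
        }
        if landuse_areas is not None:
            lu = sub.drop(columns=["area_m2"]).merge(
                landuse_areas, on=["ecoregion", "land_use", "intensity"], how="inner"
            )
            if not lu.empty and lu["area_m2"].sum() > 0:
                row["value_landuse_weighted"], row["rel_weighted_sd_landuse"] = (
                    aggregate_spatial(lu["value"], lu["area_m2"])
                )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proxies
# ---------------------------------------------------------------------------

def proxy_intensity(
    cf_table: pd.DataFrame,
    affinity_lookup,
    ecoregion,
    group: str,
    land_use: str,
    target_intensity: str,
) -> pd.DataFrame | None:
    """Fill a missing intensity level from a sibling intensity of the land use.

    The source CF is rescaled along the affinity pathway: average CFs carry
    the allocation weight A*(1-h), so the ratio (1 - h_target)/(1 - h_source)
    transfers the intensity effect of the richness tables onto the CF scale.
    The nearest available intensity level is used as the source.  Returns the
    proxied records (flagged) or None when no sibling exists.
    """
    order = ["minimal", "light", "intense"]
    native = cf_table[
        (cf_table["ecoregion"] == ecoregion)
        & (cf_table["group"] == group)
        & (cf_table["land_use"] == land_use)
        & (~cf_table["proxy_flag"])
    ]
    siblings = [m for m in order if m in set(native["intensity"])]
    if not siblings or target_intensity not in order:
        return None
    tgt_pos = order.index(target_intensity)
    source = min(siblings, key=lambda m: (abs(order.index(m) - tgt_pos), order.index(m)))
    h_src = affinity_lookup(group, ecoregion, land_use, source)
    h_tgt = affinity_lookup(group, ecoregion, land_use, target_intensity)
    if h_src >= 1.0:
        scale = 1.0
        warnings.warn("source class fully benign (h=1); intensity proxy unscaled")
    else:
        scale = (1.0 - h_tgt) / (1.0 - h_src)
    out = native[native["intensity"] == source].copy()
    out["intensity"] = target_intensity
    out["value"] = out["value"] * scale
    out["proxy_flag"] = True
    return out


def proxy_biome(
    cf_table: pd.DataFrame,
    ecoregion_biome: pd.DataFrame,
    gep_target: float,
    ecoregion,
    group: str,
    land_use: str,
    intensity: str,
) -> pd.DataFrame | None:
    """Fill a missing land use from the biome's donor ecoregions.

    Regional CFs of non-proxy donors in the same biome are averaged; the
    global extent is rebuilt from that mean times the target ecoregion's GEP.
    Returns None when the biome holds no donor for the class.
    """
    biome_map = ecoregion_biome.set_index("ecoregion")["biome"]
    if ecoregion not in biome_map.index:
        return None
    biome = biome_map[ecoregion]
    donors_idx = biome_map[biome_map == biome].index.difference([ecoregion])
    donors = cf_table[
        cf_table["ecoregion"].isin(donors_idx)
        & (cf_table["group"] == group)
        & (cf_table["land_use"] == land_use)
        & (cf_table["intensity"] == intensity)
        & (cf_table["extent"] == "regional")
        & (~cf_table["proxy_flag"])
    ]
    if donors.empty:
        log.warning("no donor in biome %s for (%s, %s, %s)", biome, group,
                    land_use, intensity)
        return None
    rows = []
    for (approach, kind), sub in donors.groupby(["approach", "kind"], sort=True):
        mean_reg = float(sub["value"].mean())
        base = {
            "ecoregion": ecoregion, "group": group, "land_use": land_use,
            "intensity": intensity, "approach": approach, "kind": kind,
            "unit": sub["unit"].iloc[0], "proxy_flag": True,
            "rel_weighted_sd": np.nan,
        }
        rows.append(base | {"extent": "regional", "value": mean_reg})
        rows.append(base | {"extent": "global", "value": mean_reg * gep_target})
    return pd.DataFrame(rows)


def proxy_gep(
    gep_table: pd.DataFrame,
    ecoregion_biome: pd.DataFrame,
    ecoregion_areas: pd.DataFrame,
    group: str,
    ecoregion,
) -> float:
    """Proxy a missing GEP from the biome's GEP-per-area density.

    Donor GEPs in the biome are divided by their ecoregion areas, averaged,
    and multiplied by the target ecoregion's area.
    """
    biome_map = ecoregion_biome.set_index("ecoregion")["biome"]
    areas = ecoregion_areas.set_index("ecoregion")["area_m2"]
    biome = biome_map[ecoregion]
    donors_idx = biome_map[biome_map == biome].index.difference([ecoregion])
    donors = gep_table[
        (gep_table["group"] == group) & gep_table["ecoregion"].isin(donors_idx)
    ]
    if donors.empty:
        raise KeyError(f"no GEP donors in biome {biome} for {group}")
    density = donors["gep"].to_numpy() / areas.loc[donors["ecoregion"]].to_numpy()
    return float(density.mean() * areas[ecoregion])


def proxy_country(
    country_cfs: pd.DataFrame,
    centroids: pd.DataFrame,
    target_country: str,
    n_neighbours: int = 3,
) -> pd.DataFrame:
    """Fill a country with no ecoregion match from its nearest neighbours.

    ``centroids`` has columns country, x, y.  The ``n_neighbours`` nearest
    countries by centroid Euclidean distance (ties broken by country
    identifier) contribute a simple mean CF; their spatial SDs are pooled as
    sqrt(mean within-country variance + between-country variance of means),
    reported relative to the pooled mean.
    """
    cent = centroids.set_index("country")
    if target_country not in cent.index:
        raise KeyError(f"no centroid for {target_country}")
    tx, ty = cent.loc[target_country, ["x", "y"]]
    others = cent.drop(index=target_country, errors="ignore")
    candidates = others.index[others.index.isin(country_cfs["country"].unique())]
    d = np.hypot(others.loc[candidates, "x"] - tx, others.loc[candidates, "y"] - ty)
    ranked = sorted(zip(d.to_numpy(), candidates))
    if len(ranked) < n_neighbours:
        warnings.warn(
            f"only {len(ranked)} candidate countries; using all", stacklevel=2
        )
    chosen = [c for _dist, c in ranked[:n_neighbours]]
    sub = country_cfs[country_cfs["country"].isin(chosen)]
    keys = ["group", "land_use", "intensity", "approach", "extent", "kind"]
    rows = []
    for key, grp in sub.groupby(keys, sort=True):
        mean = float(grp["value"].mean())
        sds = grp["value"] * grp["rel_weighted_sd"].fillna(0.0)
        pooled_var = float(np.mean(sds**2) + np.var(grp["value"].to_numpy()))
        rows.append(dict(zip(keys, key)) | {
            "country": target_country, "value": mean,
            "unit": grp["unit"].iloc[0], "proxy_flag": True,
            "rel_weighted_sd": np.sqrt(pooled_var) / mean if mean else np.nan,
        })
    return pd.DataFrame(rows)


def fill_gaps(
    cf_table: pd.DataFrame,
    gaps: pd.DataFrame,
    affinity_lookup,
    ecoregion_biome: pd.DataFrame,
    gep_lookup,
) -> pd.DataFrame:
    """Apply the proxy chain (intensity sibling, then biome mean) to a gap list.

    ``gaps`` has columns ecoregion, group, land_use, intensity.  Native rows
    are never overwritten; unresolved gaps stay absent.
    """
    pieces = [cf_table]
    for g in gaps.itertuples():
        if g.land_use in ("*", "natural"):
            continue
        have = cf_table[
            (cf_table["ecoregion"] == g.ecoregion)
            & (cf_table["group"] == g.group)
            & (cf_table["land_use"] == g.land_use)
            & (cf_table["intensity"] == g.intensity)
        ]
        if not have.empty:
            continue
        filled = proxy_intensity(
            cf_table, affinity_lookup, g.ecoregion, g.group, g.land_use, g.intensity
        )
        if filled is None:
            filled = proxy_biome(
                cf_table, ecoregion_biome, gep_lookup(g.group, g.ecoregion),
                g.ecoregion, g.group, g.land_use, g.intensity,
            )
        if filled is not None and not filled.empty:
            pieces.append(filled)
    out = pd.concat(pieces, ignore_index=True)
    return out.sort_values(
        ["ecoregion", "group", "land_use", "intensity", "approach", "extent", "kind"]
    ).reset_index(drop=True)
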