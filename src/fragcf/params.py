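"""Biological parameter tables for the characterization-factor model.

Builds habitat affinities from relative local species richness, intensity
scaling factors, landscape resistances, and median dispersal distances with
taxonomic gap-filling, plus the Welch-test-based merging of practically
indistinguishable intensity levels.

Notation
--------
rr : relative local species richness of a land-use class, relative to natural
     habitat (dimensionless, > 0; may exceed 1 in samples).
h  : habitat affinity in [0, 1]; h = min(1, rr**(1/z)).  Natural habitat has
     h = 1 by definition of the reference state.
f  : intensity scaling factor, the ratio rr(m) / rr(minimal) of a land use.
r  : landscape resistance in [0, 1]; 0 = fully permeable matrix.
z  : slope of the species-area power law, per species group and biome.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

INTENSITY_ORDER = ["minimal", "light", "intense"]

#: species groups whose dispersal distance is a fixed configured constant
FIXED_DISPERSAL_M = {"amphibians": 9_000.0, "reptiles": 9_000.0}

#: taxonomic ranks used for dispersal gap-filling, most specific first
FILL_RANKS = ["genus", "family", "order", "class", "kingdom"]


def affinity_from_rr(rr: float, z: float) -> float:
    """Habitat affinity h = min(1, rr**(1/z)).

    Inverts the species-area power law at the local scale: a class whose local
    richness is a fraction rr of the natural reference behaves like habitat of
    affinity rr**(1/z).  Clamped at 1 because affinity is a suitability
    fraction even when sampled richness exceeds the reference.
    """
    if rr <= 0:
        raise ValueError("relative richness must be positive")
    if not 0 < z < 1:
        raise ValueError("z must lie in (0, 1)")
    return min(1.0, rr ** (1.0 / z))


def rr_from_affinity(h: float, z: float) -> float:
    """Back-calculate rr = h**z from an affinity (inverse of affinity_from_rr)."""
    if not 0 < h <= 1:
        raise ValueError("affinity must lie in (0, 1]")
    if not 0 < z < 1:
        raise ValueError("z must lie in (0, 1)")
    return h**z


def intensity_scaling_factor(rr_m: float, rr_minimal: float) -> float:
    """f = rr(m) / rr(minimal) for one land use; f(minimal) = 1 by construction."""
    if rr_m <= 0 or rr_minimal <= 0:
        raise ValueError("relative richness values must be positive")
    f = rr_m / rr_minimal
    if f > 1:
        log.info("intensity scaling factor %.3f exceeds 1 (richness ratio > 1)", f)
    return f


def rescale_affinity(h_broad: float, f: float, z: float) -> float:
    """Apply an intensity scaling factor to a broad-class affinity.

    The factor acts in rr-space and is carried onto the affinity scale through
    the same 1/z exponent as the affinity itself: h_im = min(1, h * f**(1/z)).
    """
    if not 0 <= h_broad <= 1:
        raise ValueError("broad affinity must lie in [0, 1]")
    if f <= 0:
        raise ValueError("scaling factor must be positive")
    return min(1.0, h_broad * f ** (1.0 / z))


def resistance_plants(rr_habitat: float, rr_surrounding: float) -> float:
    """Plant landscape resistance r = 1 - min(1, rr_surround / rr_habitat).

    A surrounding class supporting at least the habitat's richness is fully
    permeable (r = 0); one supporting none of it is impermeable (r -> 1).
    """
    if rr_habitat <= 0 or rr_surrounding <= 0:
        raise ValueError("relative richness values must be positive")
    return 1.0 - min(1.0, rr_surrounding / rr_habitat)


def resistance_vertebrates(s_habitat: int, s_shared: int, f_surrounding: float) -> float:
    """Vertebrate resistance r = 1 - (S_shared / S_habitat) * min(1, f).

    ``s_shared`` is the number of habitat species that also occur in the
    surrounding class; the intensity scaling factor of the surrounding class
    discounts the overlap further.
    """
    if s_habitat <= 0:
        raise ValueError("habitat species count must be positive")
    if not 0 <= s_shared <= s_habitat:
        raise ValueError("shared species count must lie in [0, S_habitat]")
    if f_surrounding <= 0:
        raise ValueError("scaling factor must be positive")
    return 1.0 - (s_shared / s_habitat) * min(1.0, f_surrounding)


def welch_p(est_a: float, se_a: float, est_b: float, se_b: float,
            n_a: float | None = None, n_b: float | None = None) -> float:
    """Two-sided Welch's t-test p-value from estimates and standard errors.

    With sample sizes the Welch-Satterthwaite degrees of freedom are used;
    without them the df is taken as infinite (normal approximation), which is
    the only option when the inputs are model estimates with SEs only.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    va, vb = se_a**2, se_b**2
    t = (est_a - est_b) / math.sqrt(va + vb)
    if n_a is not None and n_b is not None:
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        return float(2 * stats.t.sf(abs(t), df))
    return float(2 * stats.norm.sf(abs(t)))


def merge_intensity_levels(
    estimates: dict[str, tuple[float, float | None]],
    abs_threshold: float = 0.05,
    alpha: float = 0.05,
) -> list[list[str]]:
    """Partition intensity levels into merged classes.

    ``estimates`` maps intensity level -> (estimate, SE).  Adjacent levels (in
    minimal < light < intense order) are merged when the absolute difference
    of their estimates is below ``abs_threshold`` (practically insignificant)
    AND Welch's t-test cannot distinguish them at ``alpha`` (statistically
    insignificant); merging is transitively closed along the intensity order.
    Levels with a missing SE cannot be tested and stay separate.

    Returns the partition as a list of groups, each a list of level names in
    intensity order.
    """
    levels = [l for l in INTENSITY_ORDER if l in estimates]
    extra = set(estimates) - set(levels)
    if extra:
        raise ValueError(f"unknown intensity levels: {sorted(extra)}")
    if len(levels) < 2:
        return [[l] for l in levels]
    groups: list[list[str]] = [[levels[0]]]
    for prev, cur in zip(levels, levels[1:]):
        est_p, se_p = estimates[prev]
        est_c, se_c = estimates[cur]
        if se_p is None or se_c is None or not np.isfinite(se_p or np.nan) or not np.isfinite(se_c or np.nan):
            warnings.warn(
                f"missing SE for {prev}/{cur}: levels kept separate", stacklevel=2
            )
            mergeable = False
        else:
            practically = abs(est_p - est_c) < abs_threshold
            # degenerate alphas act as hard switches: 0 never deems a pair
            # statistically mergeable, 1 always does
            if alpha <= 0:
                statistically = False
            elif alpha >= 1:
                statistically = True
            else:
                statistically = welch_p(est_p, se_p, est_c, se_c) >= alpha
            mergeable = practically and statistically
        if mergeable:
            groups[-1].append(cur)
        else:
            groups.append([cur])
    return groups


def pooled_estimate(members: list[tuple[float, float]]) -> tuple[float, float]:
    """Inverse-variance-weighted mean and its SE for a merged class."""
    est = np.array([m[0] for m in members], float)
    se = np.array([m[1] for m in members], float)
    w = 1.0 / se**2
    return float(np.sum(w * est) / np.sum(w)), float(np.sqrt(1.0 / np.sum(w)))


def apply_intensity_merging(
    rr_table: pd.DataFrame,
    abs_threshold: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Merge statistically indistinguishable intensity levels of an rr table.

    Expects columns group, land_use, intensity, rr, se (lo/hi carried through
    by pooling when present).  Each merged class keeps the rows of its member
    levels but assigns them the pooled estimate, so downstream keying by
    (land use, intensity) is unchanged.
    """
    out = rr_table.copy()
    for (g, lu), sub in rr_table.groupby(["group", "land_use"]):
        ests = {
            r.intensity: (float(r.rr), float(r.se) if np.isfinite(r.se) else None)
            for r in sub.itertuples()
        }
        for members in merge_intensity_levels(ests, abs_threshold, alpha):
            if len(members) < 2:
                continue
            pooled, pooled_se = pooled_estimate([ests[m] for m in members])
            sel = (
                (out["group"] == g)
                & (out["land_use"] == lu)
                & (out["intensity"].isin(members))
            )
            out.loc[sel, "rr"] = pooled
            out.loc[sel, "se"] = pooled_se
            if "lo" in out.columns:
                out.loc[sel, "lo"] = pooled - 1.959963984540054 * pooled_se
                out.loc[sel, "hi"] = pooled + 1.959963984540054 * pooled_se
            out.loc[sel, "merged_class"] = "+".join(members)
    if "lo" in out.columns:
        out["lo"] = out["lo"].clip(lower=1e-6)
    return out


def fill_dispersal_gaps(traits: pd.DataFrame) -> pd.DataFrame:
    """Fill missing species dispersal distances from taxonomic averages.

    Missing values take the mean distance of observed congeners; failing that,
    of the family, order, class and, as a last resort, the kingdom.  Observed
    values are never altered.  Adds a ``fill_level`` column (``observed`` or
    the rank used).
    """
    required = {"species", "dispersal_m", *FILL_RANKS}
    if not required.issubset(traits.columns):
        raise ValueError(f"traits table needs columns {sorted(required)}")
    if len(traits) == 0 or traits["dispersal_m"].notna().sum() == 0:
        raise ValueError("need at least one species with a known distance")
    known = traits["dispersal_m"].notna()
    if (traits.loc[known, "dispersal_m"] <= 0).any():
        raise ValueError("observed dispersal distances must be positive")
    out = traits.copy()
    out["fill_level"] = np.where(known, "observed", "")
    observed = traits[known]
    for rank in FILL_RANKS:
        missing = out["dispersal_m"].isna()
        if not missing.any():
            break
        means = observed.groupby(rank)["dispersal_m"].mean()
        fill = out.loc[missing, rank].map(means)
        got = missing & fill.reindex(out.index).notna()
        out.loc[got, "dispersal_m"] = out.loc[got, rank].map(means)
        out.loc[got, "fill_level"] = rank
    if out["dispersal_m"].isna().any():
        # cannot happen when every row shares the kingdom of some observed row
        raise ValueError("some species could not be gap-filled at any rank")
    return out


def median_dispersal_per_ecoregion(
    traits: pd.DataFrame,
    presence: pd.DataFrame,
    species_group: str,
) -> pd.Series:
    """Median dispersal distance (m) per ecoregion for one species group.

    ``traits`` must be gap-filled (no missing distances); ``presence`` has
    columns species, ecoregion.  Amphibians and reptiles use the configured
    9 km constant regardless of traits.  Ecoregions with no present species
    get NaN, to be resolved by a proxy downstream.
    """
    ecoregions = pd.Index(sorted(presence["ecoregion"].unique()), name="ecoregion")
    if species_group in FIXED_DISPERSAL_M:
        return pd.Series(FIXED_DISPERSAL_M[species_group], index=ecoregions)
    if traits["dispersal_m"].isna().any():
        raise ValueError("traits contain missing distances; run fill_dispersal_gaps")
    merged = presence.merge(traits[["species", "dispersal_m"]], on="species", how="left")
    med = merged.groupby("ecoregion")["dispersal_m"].median()
    return med.reindex(ecoregions)


@dataclass
class ParamSet:
    """Bundle of parameter tables keyed the way the CF engine consumes them.

    rr        : DataFrame [group, land_use, intensity, rr, se, lo, hi]
    z         : DataFrame [group, biome, z]
    dispersal : DataFrame [group, ecoregion, d_med_m]
    gep       : DataFrame [group, ecoregion, gep]
    regen     : DataFrame [group, land_use, t_years]
    suitability : DataFrame [group, ecoregion, land_use, S, S_shared] or None;
                  vertebrate broad-class habitat use counts (S species use the
                  class, out of S_total in the ecoregion)
    s_total   : DataFrame [group, ecoregion, S_total] or None
    vertebrate_groups : groups parameterised through the suitability route
    """

    rr: pd.DataFrame
    z: pd.DataFrame
    dispersal: pd.DataFrame
    gep: pd.DataFrame
    regen: pd.DataFrame
    ecoregion_biome: pd.DataFrame  # [ecoregion, biome]
    suitability: pd.DataFrame | None = None
    s_total: pd.DataFrame | None = None
    vertebrate_groups: tuple[str, ...] = ()
    forest_land_use: str = "managed_forest"

    def biome_of(self, ecoregion) -> str:
        row = self.ecoregion_biome.loc[self.ecoregion_biome["ecoregion"] == ecoregion]
        if row.empty:
            raise KeyError(f"ecoregion {ecoregion} has no biome assignment")
        return row["biome"].iloc[0]

    def z_value(self, group: str, ecoregion) -> float:
        biome = self.biome_of(ecoregion)
        row = self.z.loc[(self.z["group"] == group) & (self.z["biome"] == biome)]
        if row.empty:
            raise KeyError(f"no z for ({group}, biome {biome})")
        return float(row["z"].iloc[0])

    def rr_value(self, group: str, land_use: str, intensity: str,
                 bound: str = "point") -> float:
        col = {"point": "rr", "lo": "lo", "hi": "hi"}[bound]
        row = self.rr.loc[
            (self.rr["group"] == group)
            & (self.rr["land_use"] == land_use)
            & (self.rr["intensity"] == intensity)
        ]
        if row.empty:
            raise KeyError(f"no rr for ({group}, {land_use}, {intensity})")
        return float(row[col].iloc[0])

    def scaling_factor(self, group: str, land_use: str, intensity: str,
                       bound: str = "point") -> float:
        """f = rr(m) / rr(baseline); baseline is the least intense level the
        land use actually has (minimal where present)."""
        sub = self.rr.loc[
            (self.rr["group"] == group) & (self.rr["land_use"] == land_use)
        ]
        levels = [m for m in INTENSITY_ORDER if m in set(sub["intensity"])]
        if not levels:
            raise KeyError(f"no rr rows for ({group}, {land_use})")
        return intensity_scaling_factor(
            self.rr_value(group, land_use, intensity, bound),
            self.rr_value(group, land_use, levels[0], "point"),
        )

    def broad_affinity(self, group: str, ecoregion, land_use: str) -> float:
        """Ecoregion-level vertebrate broad-class affinity S_use / S_total."""
        if self.suitability is None or self.s_total is None:
            raise KeyError("no suitability tables supplied")
        s = self.suitability.loc[
            (self.suitability["group"] == group)
            & (self.suitability["ecoregion"] == ecoregion)
            & (self.suitability["land_use"] == land_use)
        ]
        tot = self.s_total.loc[
            (self.s_total["group"] == group)
            & (self.s_total["ecoregion"] == ecoregion)
        ]
        if s.empty or tot.empty:
            raise KeyError(f"no suitability for ({group}, {ecoregion}, {land_use})")
        return min(1.0, float(s["S"].iloc[0]) / float(tot["S_total"].iloc[0]))

    # -- affinities ---------------------------------------------------------

    def affinity(self, group: str, ecoregion, land_use: str, intensity: str,
                 bound: str = "point", use_intensity: bool = True) -> float:
        """Habitat affinity h for one class, following the group's route.

        Plants (and vertebrates in managed forests) go through rr and the
        power-law inversion; other vertebrate classes start from the
        ecoregion-level broad affinity and are rescaled by the global
        intensity scaling factor in rr-space.  ``use_intensity=False``
        pools rr over intensities (plants/forests) or skips the rescaling
        (other vertebrate classes).
        """
        z = self.z_value(group, ecoregion)
        plant_route = (group not in self.vertebrate_groups) or (
            land_use == self.forest_land_use
        )
        if plant_route:
            if use_intensity:
                rr = self.rr_value(group, land_use, intensity, bound)
            else:
                rr = self._pooled_rr(group, land_use, bound)
            return affinity_from_rr(rr, z)
        h_broad = self.broad_affinity(group, ecoregion, land_use)
        if not use_intensity:
            return h_broad
        f = self.scaling_factor(group, land_use, intensity, bound)
        return rescale_affinity(h_broad, f, z)

    def _pooled_rr(self, group: str, land_use: str, bound: str) -> float:
        sub = self.rr.loc[
            (self.rr["group"] == group) & (self.rr["land_use"] == land_use)
        ]
        if sub.empty:
            raise KeyError(f"no rr rows for ({group}, {land_use})")
        pooled, pooled_se = pooled_estimate(
            [(float(r.rr), float(r.se)) for r in sub.itertuples()]
        )
        if bound == "point":
            return pooled
        delta = 1.959963984540054 * pooled_se
        return max(1e-6, pooled - delta) if bound == "lo" else pooled + delta

    # -- resistance ---------------------------------------------------------

    def resistance(self, group: str, ecoregion, habitat: tuple[str, str],
                   surrounding: tuple[str, str], bound: str = "point",
                   use_intensity: bool = True) -> float:
        """Resistance of a surrounding class to a species group of a habitat.

        Natural habitat is always fully permeable.  Plants compare relative
        richness (habitat vs surrounding); vertebrates compare the species
        overlap discounted by the surrounding class's intensity factor.  When
        one class of a vertebrate pair is ecoregion-specific its rr is
        back-calculated from the affinity (rr = h**z).
        """
        s_lu, s_m = surrounding
        if s_lu == "natural":
            return 0.0
        h_lu, h_m = habitat
        z = self.z_value(group, ecoregion)
        if group not in self.vertebrate_groups:
            rr_hab = (1.0 if h_lu == "natural"
                      else self.rr_value(group, h_lu, h_m, bound))
            rr_sur = self.rr_value(group, s_lu, s_m, bound)
            return resistance_plants(rr_hab, rr_sur)
        # vertebrates: species overlap between habitat and surrounding class
        if s_lu == self.forest_land_use or h_lu == self.forest_land_use:
            # managed-forest pairs fall back to the rr comparison, with the
            # non-forest side back-calculated from its ecoregion affinity
            rr_hab = self._vert_rr(group, ecoregion, h_lu, h_m, bound, z)
            rr_sur = self._vert_rr(group, ecoregion, s_lu, s_m, bound, z)
            return resistance_plants(rr_hab, rr_sur)
        s_hab, s_shared = self._overlap(group, ecoregion, h_lu, s_lu)
        f = (self.scaling_factor(group, s_lu, s_m, bound)
             if use_intensity else 1.0)
        return resistance_vertebrates(s_hab, s_shared, f)

    def _vert_rr(self, group, ecoregion, lu, m, bound, z) -> float:
        if lu == "natural":
            return 1.0
        if lu == self.forest_land_use:
            return self.rr_value(group, lu, m, bound)
        return rr_from_affinity(
            max(1e-9, self.affinity(group, ecoregion, lu, m, bound)), z
        )

    def _overlap(self, group, ecoregion, habitat_lu, surround_lu) -> tuple[int, int]:
        if self.suitability is None:
            raise KeyError("no suitability tables supplied")
        sub = self.suitability.loc[
            (self.suitability["group"] == group)
            & (self.suitability["ecoregion"] == ecoregion)
        ].set_index("land_use")
        if habitat_lu == "natural":
            if self.s_total is None:
                raise KeyError("no species totals supplied")
            tot = self.s_total.loc[
                (self.s_total["group"] == group)
                & (self.s_total["ecoregion"] == ecoregion), "S_total"]
            s_hab = int(tot.iloc[0])
            s_shared = int(sub.loc[surround_lu, "S"])
        else:
            s_hab = int(sub.loc[habitat_lu, "S"])
            s_shared = int(sub.loc[surround_lu, "S_shared"])
            s_shared = min(s_shared, s_hab)
        return s_hab, s_shared

    def d_med(self, group: str, ecoregion) -> float:
        if group in FIXED_DISPERSAL_M:
            return FIXED_DISPERSAL_M[group]
        row = self.dispersal.loc[
            (self.dispersal["group"] == group)
            & (self.dispersal["ecoregion"] == ecoregion)
        ]
        if row.empty or not np.isfinite(row["d_med_m"].iloc[0]):
            raise KeyError(f"no dispersal distance for ({group}, {ecoregion})")
        return float(row["d_med_m"].iloc[0])

    def gep_value(self, group: str, ecoregion) -> float:
        row = self.gep.loc[
            (self.gep["group"] == group) & (self.gep["ecoregion"] == ecoregion)
        ]
        if row.empty:
            raise KeyError(f"no GEP for ({group}, {ecoregion})")
        return float(row["gep"].iloc[0])

    def regen_time(self, group: str, land_use: str) -> float:
        row = self.regen.loc[
            (self.regen["group"] == group) & (self.regen["land_use"] == land_use)
        ]
        if row.empty:
            raise KeyError(f"no regeneration time for ({group}, {land_use})")
        return float(row["t_years"].iloc[0])

    @property
    def groups(self) -> list[str]:
        return sorted(self.rr["group"].unique())
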