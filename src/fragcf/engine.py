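"""Characterization-factor engine: species-habitat relationship to CFs.

The countryside species-habitat relationship predicts the relative regional
species loss (RSL, conventionally in PDF) of a species group in an ecoregion
from the suitable connected area H before and after land use:

    RSL = 1 - (H1 / H0)**z,      H = sum_im h_im * ECA_im,      H0 = A_j

where the sum runs over all land-cover classes including natural habitat
(h = 1), ECA is the equivalent connected area of the class's patch mosaic and
z is the biome- and group-specific slope of the power law.  The regional loss
is converted to per-area characterization factors either by allocating the
total loss over the occupied area (average approach) or by differentiating it
with respect to the class area (marginal approach); occupation CFs (PDF/m2)
become transformation CFs (PDF yr/m2) through a linear-regeneration integral,
and regional CFs become global ones through the ecoregion's global extinction
probability (GEP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import (
    DispersalSpec,
    LandscapeGrid,
    Legend,
    class_connectivity_summary,
    resistance_map_for_class,
)
from .params import ParamSet

log = logging.getLogger(__name__)

APPROACHES = ("average", "marginal")
EXTENTS = ("regional", "global")
KINDS = ("occupation", "transformation")

#: relative step of the central finite difference for marginal CFs
FD_REL_STEP = 1e-4

CF_COLUMNS = [
    "ecoregion", "group", "land_use", "intensity", "approach", "extent",
    "kind", "value", "unit", "proxy_flag", "rel_weighted_sd",
]


@dataclass
class HabitatState:
    """Areas, connectivities and affinities of one (ecoregion, group) pair.

    classes : DataFrame [land_use, intensity, code, total_area, eca, h]
              including the natural class (h = 1)
    ecoregion_area : A_j in m2 (the reference suitable connected area H0)
    """

    classes: pd.DataFrame
    ecoregion_area: float
    ecoregion: str | int = 0
    group: str = ""

    def __post_init__(self):
        if (self.classes["h"] < 0).any() or (self.classes["h"] > 1).any():
            raise ValueError("affinities must lie in [0, 1]")
        if ((self.classes["eca"] - self.classes["total_area"]) > 1e-6 * self.ecoregion_area).any():
            raise ValueError("ECA cannot exceed the class area")

    @property
    def suitable_connected_area(self) -> float:
        """H1 = sum over classes of h * ECA."""
        return float((self.classes["h"] * self.classes["eca"]).sum())

    def anthropogenic(self) -> pd.DataFrame:
        return self.classes[self.classes["land_use"] != "natural"]

    def row(self, land_use: str, intensity: str) -> pd.Series:
        sel = self.classes[
            (self.classes["land_use"] == land_use)
            & (self.classes["intensity"] == intensity)
        ]
        if sel.empty:
            raise KeyError(f"class ({land_use}, {intensity}) not in state")
        return sel.iloc[0]


def regional_species_loss(state: HabitatState, z: float) -> float:
    """RSL = 1 - (H1/H0)**z, the potential relative loss of regional species."""
    if not 0 < z < 1:
        raise ValueError("z must lie in (0, 1)")
    h0 = state.ecoregion_area
    h1 = state.suitable_connected_area
    if h1 > h0 * (1 + 1e-9):
        raise ValueError("suitable connected area exceeds the reference state")
    return 1.0 - (min(h1, h0) / h0) ** z


def natural_conversion_rate(state: HabitatState) -> float:
    """Connected natural habitat lost per m2 of land converted (lambda >= 1).

    Converting land removes natural habitat area one-for-one and additionally
    fragments what natural habitat remains, so the connected natural habitat
    lost per converted m2, averaged over the conversion from the pristine
    state (where the natural ECA was the whole ecoregion A_j) to the present
    one, is

        lambda = (A_j - ECA_nat) / sum_k A_k  >=  1,

    with the sum over anthropogenic class areas.  Without fragmentation
    (ECA_nat = A_nat) lambda is exactly 1.  Both the allocation weights and
    the marginal derivative value converted natural habitat at this rate, so
    the two CF approaches account for the same total loss.
    """
    anth_area = float(state.anthropogenic()["total_area"].sum())
    if anth_area <= 0:
        return 1.0
    nat = state.classes[state.classes["land_use"] == "natural"]
    eca_nat = float(nat["eca"].sum()) if not nat.empty else 0.0
    return (state.ecoregion_area - eca_nat) / anth_area


def used_connectivity_ratio(state: HabitatState) -> float:
    """Affinity-weighted mean ECA/A of the anthropogenic classes (rho_bar).

    rho_bar = sum_k h_k ECA_k / sum_k h_k A_k summarises how connected the
    habitat offered by used land is; it is 1 without fragmentation and equals
    any class's own ECA/A when ratios are uniform.  Classes offering no
    habitat (h = 0) do not contribute; a landscape whose used classes offer
    no habitat at all gets the neutral value 1.
    """
    anth = state.anthropogenic()
    denom = float((anth["h"] * anth["total_area"]).sum())
    if denom <= 0:
        return 1.0
    return float((anth["h"] * anth["eca"]).sum()) / denom


def allocation_factor(state: HabitatState, land_use: str, intensity: str) -> float:
    """Share of the regional loss attributed to one anthropogenic class.

    Each class is weighted by its net habitat deficit per unit area: the
    connected natural habitat its footprint consumed (lambda per m2, see
    :func:`natural_conversion_rate`) minus the habitat it offers in return,
    valued at the mean within-class connectivity of used land
    (:func:`used_connectivity_ratio`),

        w_im = A_im * (lambda - h_im * rho_bar)  >=  0.

    Valuing every class's habitat at the shared ratio rho_bar rather than
    its own realized ECA/A keeps the attribution independent of the
    stochastic fragmentation of individual classes, so CFs inherit the
    intensity ordering of the affinities; and because the weights sum to
    exactly the total deficit H0 - H1, the average CFs and the marginal
    derivative account for the same total loss, which keeps marginal CFs at
    or above average CFs under the convex power law.  Without fragmentation
    (lambda = rho_bar = 1) the weight reduces to the classic
    area-times-unsuitability form A * (1 - h), and a fully benign class
    (h = 1) carries no impact.
    """
    anth = state.anthropogenic()
    lam = natural_conversion_rate(state)
    rho = used_connectivity_ratio(state)
    weights = (anth["total_area"] * (lam - rho * anth["h"])).clip(lower=0.0)
    total = float(weights.sum())
    if total == 0.0:
        log.warning("all-natural or fully benign landscape: allocation undefined")
        return 0.0
    r = state.row(land_use, intensity)
    w = max(0.0, float(r["total_area"]) * (lam - rho * float(r["h"])))
    return w / total


def cf_occ_average(state: HabitatState, z: float, land_use: str, intensity: str) -> float:
    """Average occupation CF: RSL * a / A_im, in PDF per m2 of the class."""
    r = state.row(land_use, intensity)
    if r["total_area"] <= 0:
        raise KeyError(f"class ({land_use}, {intensity}) has zero area")
    rsl = regional_species_loss(state, z)
    a = allocation_factor(state, land_use, intensity)
    return rsl * a / float(r["total_area"])


def cf_occ_marginal(state: HabitatState, z: float, land_use: str, intensity: str,
                    rel_step: float = FD_REL_STEP) -> float:
    """Marginal occupation CF: dRSL/dA_im by central finite difference.

    The expanding class gains habitat at h * rho_bar per m2 - its affinity
    times the mean within-class connectivity of used land
    (:func:`used_connectivity_ratio`), i.e. new conversion is assumed to be
    as fragmented as existing used land on average rather than inheriting
    the class's own stochastic patch realization.  The natural habitat
    consumed is valued at the path-average connected-habitat rate lambda
    (:func:`natural_conversion_rate`), which charges the induced
    fragmentation of the remaining natural habitat to the expanding land
    use.  A frozen-structure derivative that scattered the expansion
    proportionally across patches and shrank natural patches proportionally
    would drop the natural-fragmentation component and undervalue marginal
    impacts relative to the average CF's total-loss accounting.  When no
    natural habitat remains to convert, a one-sided (backward) difference is
    used.
    """
    r = state.row(land_use, intensity)
    a_im = float(r["total_area"])
    if a_im <= 0:
        raise KeyError(f"class ({land_use}, {intensity}) has zero area")
    nat = state.classes[state.classes["land_use"] == "natural"]
    a_nat = float(nat["total_area"].sum()) if not nat.empty else 0.0
    delta = rel_step * a_im

    base_h1 = state.suitable_connected_area
    h_im = float(r["h"])
    lam = natural_conversion_rate(state)
    rho = used_connectivity_ratio(state)

    def h1_at(d: float) -> float:
        # the class gains habitat at h * rho_bar per m2; converted natural
        # habitat costs lambda m2 of connected habitat per m2
        return base_h1 + h_im * rho * d - lam * d

    def rsl_at(d: float) -> float:
        h1 = min(max(h1_at(d), 0.0), state.ecoregion_area)
        return 1.0 - (h1 / state.ecoregion_area) ** z

    if a_nat >= delta:
        cf = (rsl_at(delta) - rsl_at(-delta)) / (2 * delta)
    else:
        log.warning("no natural habitat left to convert: one-sided difference")
        cf = (rsl_at(0.0) - rsl_at(-delta)) / delta
    # a class providing more connected habitat than it displaces has no
    # marginal impact (mirrors the clipped allocation weight)
    return max(0.0, cf)


def cf_transformation(cf_occ: float, t_years: float) -> float:
    """Transformation CF = 0.5 * t * CF_occ (linear regeneration over t years)."""
    if t_years < 0:
        raise ValueError("regeneration time must be non-negative")
    return 0.5 * t_years * cf_occ


def to_global(cf_regional: float, gep: float) -> float:
    """Weight a regional CF by the ecoregion's global extinction probability."""
    if not 0 <= gep <= 1:
        raise ValueError("GEP must lie in [0, 1]")
    return cf_regional * gep


@dataclass
class EngineOptions:
    """Model variant switches consumed by the CF engine."""

    fragmentation: bool = True        # False: ECA replaced by total class area
    use_intensity: bool = True        # False: pooled rr / unscaled affinities
    rr_bound: str = "point"           # point | lo | hi
    connectivity: int = 8
    p_cutoff: float = 1e-6
    fd_rel_step: float = FD_REL_STEP


def build_habitat_state(
    grid: LandscapeGrid,
    legend: Legend,
    params: ParamSet,
    group: str,
    options: EngineOptions | None = None,
) -> HabitatState:
    """Assemble per-class A, ECA and affinities for one (ecoregion, group).

    The ECA of each class is computed with the group's dispersal kernel over
    least-cost distances through a resistance surface specific to the moving
    species' habitat class; resistances always use the point rr estimates so
    that richness-bound variants act through the affinities alone.
    """
    opts = options or EngineOptions()
    eco = grid.ecoregion_id
    dispersal = DispersalSpec(group, params.d_med(group, eco))
    present = [int(c) for c in np.unique(grid.codes[grid.valid_mask()])]

    resistance_maps = {}
    if opts.fragmentation:
        for code in present:
            habitat = legend.lookup(code)
            class_r = {}
            for other in present:
                if other == code:
                    continue
                class_r[other] = params.resistance(
                    group, eco, habitat, legend.lookup(other),
                    bound="point", use_intensity=opts.use_intensity,
                )
            resistance_maps[code] = resistance_map_for_class(
                grid, legend, code, class_r
            )

    summary = class_connectivity_summary(
        grid, legend, dispersal, resistance_maps if opts.fragmentation else None,
        connectivity=opts.connectivity, cutoff=opts.p_cutoff,
    )
    if not opts.fragmentation:
        summary = summary.assign(eca=summary["total_area"])

    hs = []
    for r in summary.itertuples():
        if r.land_use == "natural":
            hs.append(1.0)
        else:
            hs.append(
                params.affinity(
                    group, eco, r.land_use, r.intensity,
                    bound=opts.rr_bound, use_intensity=opts.use_intensity,
                )
            )
    state = HabitatState(
        classes=summary.assign(h=hs),
        ecoregion_area=grid.area(),
        ecoregion=eco,
        group=group,
    )
    return state


def compute_ecoregion_cfs(
    grid: LandscapeGrid,
    legend: Legend,
    params: ParamSet,
    groups: list[str] | None = None,
    options: EngineOptions | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """All CF records for one ecoregion: the full cross product of present
    anthropogenic classes x species groups x {average, marginal} x
    {regional, global} x {occupation, transformation}.

    Returns (records, gaps); a record that cannot be computed because of a
    missing parameter key is skipped and reported in the machine-readable gap
    list instead.
    """
    opts = options or EngineOptions()
    groups = groups or params.groups
    records: list[dict] = []
    gaps: list[dict] = []
    eco = grid.ecoregion_id

    for group in groups:
        try:
            state = build_habitat_state(grid, legend, params, group, opts)
            z = params.z_value(group, eco)
        except KeyError as err:
            gaps.append({"ecoregion": eco, "group": group, "land_use": "*",
                         "intensity": "*", "reason": str(err)})
            continue
        anth = state.anthropogenic()
        if anth.empty:
            log.info("ecoregion %s fully natural: no CFs for %s", eco, group)
            continue
        try:
            gep = params.gep_value(group, eco)
        except KeyError as err:
            gep = None
            gaps.append({"ecoregion": eco, "group": group, "land_use": "*",
                         "intensity": "*", "reason": f"global extent: {err}"})
        for r in anth.itertuples():
            try:
                t = params.regen_time(group, r.land_use)
            except KeyError as err:
                t = None
            cf_avg = cf_occ_average(state, z, r.land_use, r.intensity)
            cf_marg = cf_occ_marginal(state, z, r.land_use, r.intensity,
                                      opts.fd_rel_step)
            for approach, cf_occ in (("average", cf_avg), ("marginal", cf_marg)):
                variants: list[tuple[str, str, float | None, str]] = [
                    ("regional", "occupation", cf_occ, "PDF/m2"),
                ]
                variants.append((
                    "regional", "transformation",
                    cf_transformation(cf_occ, t) if t is not None else None,
                    "PDF*yr/m2",
                ))
                if gep is not None:
                    variants.append(("global", "occupation",
                                     to_global(cf_occ, gep), "PDF/m2"))
                    if t is not None:
                        variants.append((
                            "global", "transformation",
                            to_global(cf_transformation(cf_occ, t), gep),
                            "PDF*yr/m2",
                        ))
                for extent, kind, value, unit in variants:
                    if value is None:
                        gaps.append({
                            "ecoregion": eco, "group": group,
                            "land_use": r.land_use, "intensity": r.intensity,
                            "reason": f"missing regeneration time ({kind})",
                        })
                        continue
                    records.append({
                        "ecoregion": eco, "group": group,
                        "land_use": r.land_use, "intensity": r.intensity,
                        "approach": approach, "extent": extent, "kind": kind,
                        "value": value, "unit": unit,
                        "proxy_flag": False, "rel_weighted_sd": np.nan,
                    })
    frame = pd.DataFrame(records, columns=CF_COLUMNS)
    frame = frame.sort_values(
        ["ecoregion", "group", "land_use", "intensity", "approach", "extent", "kind"]
    ).reset_index(drop=True)
    return frame, gaps


def regional_loss_table(
    grids: dict, legend: Legend, params: ParamSet,
    groups: list[str] | None = None, options: EngineOptions | None = None,
) -> pd.DataFrame:
    """Ecoregion-level RSL per species group (used by the sensitivity runs)."""
    groups = groups or params.groups
    rows = []
    for eco, grid in grids.items():
        for group in groups:
            state = build_habitat_state(grid, legend, params, group, options)
            z = params.z_value(group, eco)
            rows.append({"ecoregion": eco, "group": group,
                         "rsl": regional_species_loss(state, z)})
    return pd.DataFrame(rows)
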