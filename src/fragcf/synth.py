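"""Synthetic worlds with known ground truth for end-to-end exercising.

Generates internally consistent stand-ins for the global inputs the CF model
needs: categorical landscapes per ecoregion (five anthropogenic land uses at
up to three intensity levels plus natural habitat), richness tables with
standard errors, biome-specific power-law slopes, dispersal traits, habitat
suitability counts, global extinction probabilities, regeneration times, a
country overlay, and Red-List-style threat records with a planted qualifying
subset.  Everything is driven by one seed; identical specs and seeds yield
byte-identical outputs.

Landscape placement uses seeded cluster growth: the fragmentation parameter
``phi`` in [0, 1] sets the number of cluster seeds per class, from a single
connected patch (phi = 0) to independently scattered cells (phi = 1), so the
two limits are exact and the ECA/A ratio of a class falls as phi rises.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import ThreatRecord
from .landscape import LandscapeGrid, Legend
from .params import FIXED_DISPERSAL_M, ParamSet, fill_dispersal_gaps, median_dispersal_per_ecoregion

SPECIES_GROUPS = ("plants", "amphibians", "birds", "mammals", "reptiles")
VERTEBRATE_GROUPS = ("amphibians", "birds", "mammals", "reptiles")
LAND_USES = ("cropland", "pasture", "plantation", "managed_forest", "urban")
INTENSITIES = ("minimal", "light", "intense")

#: default anthropogenic class shares of an ecoregion's area (rest natural);
#: roughly the global picture of ~40% used land dominated by agriculture
DEFAULT_SHARES: dict[tuple[str, str], float] = {
    ("cropland", "minimal"): 0.04, ("cropland", "light"): 0.04,
    ("cropland", "intense"): 0.04,
    ("pasture", "minimal"): 0.04, ("pasture", "light"): 0.03,
    ("pasture", "intense"): 0.03,
    ("plantation", "minimal"): 0.02, ("plantation", "light"): 0.02,
    ("managed_forest", "minimal"): 0.03, ("managed_forest", "light"): 0.03,
    ("managed_forest", "intense"): 0.02,
    ("urban", "light"): 0.01, ("urban", "intense"): 0.02,
}

#: mean relative richness per land use at minimal intensity; intensity
#: reduces richness multiplicatively so the rr ordering is built in
RR_BASE = {
    "cropland": 0.75, "pasture": 0.85, "plantation": 0.70,
    "managed_forest": 0.90, "urban": 0.45,
}
RR_INTENSITY_STEP = {"minimal": 1.0, "light": 0.88, "intense": 0.72}


@dataclass
class WorldSpec:
    """Blueprint of a synthetic world; the seed fixes all randomness."""

    n_ecoregions: int = 4
    n_biomes: int = 2
    n_countries: int = 3
    grid_shape: tuple[int, int] = (36, 36)
    cell_size: float = 1_000.0                      # m
    shares: dict = field(default_factory=lambda: dict(DEFAULT_SHARES))
    phi: float = 0.35                               # fragmentation in [0, 1]
    groups: tuple[str, ...] = SPECIES_GROUPS
    z_range: tuple[float, float] = (0.15, 0.35)
    rr_se_range: tuple[float, float] = (0.01, 0.06)
    plant_dispersal_range: tuple[float, float] = (200.0, 3_000.0)   # m
    bird_dispersal_range: tuple[float, float] = (5_000.0, 40_000.0)
    mammal_dispersal_range: tuple[float, float] = (2_000.0, 15_000.0)
    regen_range: tuple[float, float] = (20.0, 150.0)                 # yr
    n_species_per_group: int = 30
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")
        if sum(self.shares.values()) > 1.0:
            raise ValueError("class shares must sum to at most 1")

    def ecoregions(self) -> list[str]:
        return [f"eco{i:02d}" for i in range(self.n_ecoregions)]


def default_legend(shares: dict | None = None) -> Legend:
    """Integer codes: 0 = natural, then anthropogenic classes in fixed order."""
    shares = shares if shares is not None else DEFAULT_SHARES
    rows = [{"code": 0, "land_use": "natural", "intensity": "natural"}]
    code = 1
    for lu in LAND_USES:
        for m in INTENSITIES:
            if (lu, m) in shares:
                rows.append({"code": code, "land_use": lu, "intensity": m})
                code += 1
    return Legend(pd.DataFrame(rows))


def _rng(spec: WorldSpec, *key) -> np.random.Generator:
    # stable across processes (Python's str hash is salted per run)
    parts = [zlib.crc32(repr(k).encode()) & 0x7FFFFFFF for k in key]
    ss = np.random.SeedSequence([spec.seed & 0x7FFFFFFF, *parts])
    return np.random.default_rng(ss)


def gen_landscape(spec: WorldSpec, ecoregion: str, legend: Legend | None = None,
                  phi: float | None = None) -> LandscapeGrid:
    """One ecoregion's categorical raster via seeded cluster growth.

    Each class receives exactly its target cell count (rounded share of the
    grid); ``phi`` (defaulting to the spec's) maps to the number of cluster
    seeds: 1 at phi = 0 (a single connected patch per class) up to one seed
    per cell at phi = 1 (independent scatter).
    """
    legend = legend or default_legend(spec.shares)
    phi = spec.phi if phi is None else phi
    rng = _rng(spec, "landscape", ecoregion, round(phi * 1e6))
    nrow, ncol = spec.grid_shape
    n_cells = nrow * ncol
    codes = np.zeros((nrow, ncol), dtype=np.int64)  # 0 = natural

    targets = {}
    for (lu, m), share in sorted(spec.shares.items()):
        t = int(round(share * n_cells))
        if t > 0:
            targets[legend.code_of(lu, m)] = t
    if sum(targets.values()) > n_cells:
        raise ValueError("class shares infeasible for this grid")

    for code in sorted(targets):
        t = targets[code]
        n_seeds = 1 if phi == 0.0 else max(1, int(round(phi * t)))
        n_seeds = min(n_seeds, t)
        free = np.flatnonzero(codes.ravel() == 0)
        seeds = rng.choice(free, size=n_seeds, replace=False)
        codes.ravel()[seeds] = code
        placed = n_seeds
        # frontier growth: randomly accrete natural 4-neighbours of the class
        frontier = _frontier(codes, code, nrow, ncol)
        while placed < t:
            if not frontier:
                free = np.flatnonzero(codes.ravel() == 0)
                if len(free) == 0:
                    raise ValueError("grid exhausted while placing classes")
                pick = int(rng.choice(free))
            else:
                pick = int(rng.choice(np.fromiter(frontier, dtype=np.int64)))
                frontier.discard(pick)
            if codes.ravel()[pick] != 0:
                continue
            codes.ravel()[pick] = code
            placed += 1
            r, c = divmod(pick, ncol)
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= nr < nrow and 0 <= nc < ncol and codes[nr, nc] == 0:
                    frontier.add(nr * ncol + nc)
    return LandscapeGrid(codes, spec.cell_size, ecoregion_id=ecoregion)


def _frontier(codes: np.ndarray, code: int, nrow: int, ncol: int) -> set[int]:
    out: set[int] = set()
    for r, c in np.argwhere(codes == code):
        for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= nr < nrow and 0 <= nc < ncol and codes[nr, nc] == 0:
                out.add(int(nr) * ncol + int(nc))
    return out


def gen_rr_table(spec: WorldSpec) -> pd.DataFrame:
    """Relative richness with SEs and 95% CI bounds per (group, class).

    Intensity ordering rr(minimal) >= rr(light) >= rr(intense) is enforced by
    construction; SEs span the configured range so that some adjacent
    intensity pairs are statistically mergeable and others are not.
    """
    rng = _rng(spec, "rr")
    rows = []
    classes = sorted({(lu, m) for lu, m in spec.shares})
    land_uses = sorted({lu for lu, _ in classes})
    for group in spec.groups:
        for lu in land_uses:
            base = RR_BASE[lu] * float(rng.uniform(0.85, 1.15))
            for m in INTENSITIES:
                if (lu, m) not in spec.shares:
                    continue
                rr = base * RR_INTENSITY_STEP[m] * float(rng.uniform(0.97, 1.0))
                se = float(rng.uniform(*spec.rr_se_range))
                rows.append({
                    "group": group, "land_use": lu, "intensity": m,
                    "rr": rr, "se": se,
                    "lo": max(1e-3, rr - 1.96 * se), "hi": rr + 1.96 * se,
                })
    return pd.DataFrame(rows)


def gen_z_table(spec: WorldSpec) -> pd.DataFrame:
    rng = _rng(spec, "z")
    rows = [
        {"group": g, "biome": f"biome{b}", "z": float(rng.uniform(*spec.z_range))}
        for g in spec.groups for b in range(spec.n_biomes)
    ]
    return pd.DataFrame(rows)


def gen_trait_table(spec: WorldSpec, group: str = "plants") -> pd.DataFrame:
    """Species trait table with taxonomy and partly missing dispersal."""
    rng = _rng(spec, "traits", group)
    lo, hi = spec.plant_dispersal_range
    n = spec.n_species_per_group
    rows = []
    for i in range(n):
        genus = f"gen{i % max(2, n // 3):02d}"
        rows.append({
            "species": f"{group[:2]}_sp{i:03d}",
            "genus": genus,
            "family": f"fam{i % max(2, n // 6):02d}",
            "order": f"ord{i % 3:02d}",
            "class": "cls00",
            "kingdom": "Plantae" if group == "plants" else "Animalia",
            "dispersal_m": (
                float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                if rng.uniform() > 0.3 else np.nan
            ),
        })
    df = pd.DataFrame(rows)
    if df["dispersal_m"].notna().sum() == 0:  # keep the table fillable
        df.loc[0, "dispersal_m"] = float(np.sqrt(lo * hi))
    return df


def gen_presence(spec: WorldSpec, traits: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(spec, "presence")
    rows = []
    for eco in spec.ecoregions():
        k = int(rng.integers(max(3, len(traits) // 4), len(traits) + 1))
        chosen = rng.choice(traits["species"].to_numpy(), size=k, replace=False)
        rows += [{"species": s, "ecoregion": eco} for s in sorted(chosen)]
    return pd.DataFrame(rows)


def gen_dispersal(spec: WorldSpec) -> pd.DataFrame:
    """Median dispersal distance per (group, ecoregion).

    Plants go through the trait table and taxonomic gap-filling; birds and
    mammals draw ecoregion medians in their configured ranges; amphibians and
    reptiles use the fixed 9 km default.
    """
    rng = _rng(spec, "dispersal")
    rows = []
    traits = fill_dispersal_gaps(gen_trait_table(spec, "plants"))
    presence = gen_presence(spec, traits)
    plant_med = median_dispersal_per_ecoregion(traits, presence, "plants")
    ranges = {"birds": spec.bird_dispersal_range,
              "mammals": spec.mammal_dispersal_range}
    for group in spec.groups:
        for eco in spec.ecoregions():
            if group in FIXED_DISPERSAL_M:
                d = FIXED_DISPERSAL_M[group]
            elif group == "plants":
                d = float(plant_med.get(eco, np.nan))
                if not np.isfinite(d):
                    d = float(np.sqrt(np.prod(spec.plant_dispersal_range)))
            else:
                lo, hi = ranges.get(group, spec.mammal_dispersal_range)
                d = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            rows.append({"group": group, "ecoregion": eco, "d_med_m": d})
    return pd.DataFrame(rows)


def gen_geps(spec: WorldSpec) -> pd.DataFrame:
    """Global extinction probabilities: positive scores normalised so the sum
    over ecoregions is exactly 1 for each species group."""
    rng = _rng(spec, "gep")
    rows = []
    ecos = spec.ecoregions()
    for group in spec.groups:
        scores = rng.gamma(2.0, 1.0, size=len(ecos))
        gep = scores / scores.sum()
        gep[-1] = 1.0 - gep[:-1].sum()  # exact unit sum despite rounding
        rows += [{"group": group, "ecoregion": e, "gep": float(p)}
                 for e, p in zip(ecos, gep)]
    return pd.DataFrame(rows)


def gen_regen(spec: WorldSpec) -> pd.DataFrame:
    rng = _rng(spec, "regen")
    land_uses = sorted({lu for lu, _ in spec.shares})
    return pd.DataFrame([
        {"group": g, "land_use": lu,
         "t_years": float(rng.uniform(*spec.regen_range))}
        for g in spec.groups for lu in land_uses
    ])


def gen_suitability(spec: WorldSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vertebrate habitat-use counts per (group, ecoregion, land use).

    S species of the ecoregion's S_total use the class; S_shared of them also
    occur in neighbouring anthropogenic classes (a single pooled overlap
    count per class, a deliberate simplification of pair-specific overlaps).
    """
    rng = _rng(spec, "suitability")
    land_uses = sorted({lu for lu, _ in spec.shares})
    suit_rows, tot_rows = [], []
    for group in spec.groups:
        if group == "plants":
            continue
        for eco in spec.ecoregions():
            s_total = int(rng.integers(80, 400))
            tot_rows.append({"group": group, "ecoregion": eco, "S_total": s_total})
            for lu in land_uses:
                frac = float(rng.uniform(0.25, 0.85))
                s = max(1, int(round(frac * s_total)))
                s_shared = int(round(float(rng.uniform(0.3, 0.9)) * s))
                suit_rows.append({"group": group, "ecoregion": eco,
                                  "land_use": lu, "S": s, "S_shared": s_shared})
    return pd.DataFrame(suit_rows), pd.DataFrame(tot_rows)


def gen_threat_records(spec: WorldSpec) -> tuple[list[ThreatRecord], set[str]]:
    """Red-List-style records with a planted ground-truth qualifying subset.

    The generator mixes qualifying species with near-misses that fail exactly
    one gate (category, threat code, or d/e-only A criteria) so the filter is
    exercised on both sides of every rule.
    """
    rng = _rng(spec, "threats")
    cases = [
        # (category, threats, criteria, qualifies)
        ("EN", ("2.2",), "A2c", True),
        ("VU", ("1",), "A1d; A1e", False),       # only d/e A criteria
        ("CR", ("2.1.2",), "B1ab(iii)", True),   # subcode match, no A criteria
        ("LC", ("2.1",), "A2c", False),          # category gate
        ("EN", ("5.3",), "A2c", False),          # no land-use threat
        ("EX", ("2.3", "9.1"), "A2cd", True),    # mixed subletters pass
        ("VU", ("1.1",), "A4e; B2b", False),     # only-e A criterion
        ("DD", ("2.2",), "A2c", False),          # data deficient
        ("EW", ("2.3.1",), "C2a(i)", True),
        ("NT", ("1",), "A2c", False),            # near threatened
    ]
    records, truth = [], set()
    n_copies = max(1, spec.n_species_per_group // len(cases))
    i = 0
    for _ in range(n_copies):
        for cat, threats, crit, ok in cases:
            name = f"threat_sp{i:03d}"
            i += 1
            records.append(ThreatRecord(name, cat, tuple(threats), crit))
            if ok:
                truth.add(name)
    order = rng.permutation(len(records))
    records = [records[j] for j in order]
    return records, truth


def gen_country_overlay(spec: WorldSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Voronoi country overlay over the ecoregion mosaic.

    Ecoregions are laid out as square tiles in the unit square; each tile is
    sampled on an 8x8 lattice and every sample is assigned to the nearest of
    the country seed points, giving nontrivial (ecoregion, country) overlap
    areas.  Returns (overlaps, centroids): overlap areas in m2 and country
    centroids in tile coordinates.
    """
    rng = _rng(spec, "countries")
    seeds = rng.uniform(0, 1, size=(spec.n_countries, 2))
    ncols = int(np.ceil(np.sqrt(spec.n_ecoregions)))
    tile = 1.0 / ncols
    area = spec.grid_shape[0] * spec.grid_shape[1] * spec.cell_size**2
    lattice = (np.arange(8) + 0.5) / 8.0
    overlap_rows = []
    pts_by_country: dict[int, list[np.ndarray]] = {i: [] for i in range(spec.n_countries)}
    for idx, eco in enumerate(spec.ecoregions()):
        r, c = divmod(idx, ncols)
        xs = (c + lattice) * tile
        ys = (r + lattice) * tile
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        d = np.linalg.norm(pts[:, None, :] - seeds[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        for ci in range(spec.n_countries):
            share = float((nearest == ci).mean())
            if share > 0:
                overlap_rows.append({
                    "ecoregion": eco, "country": f"country{ci}",
                    "overlap_m2": share * area,
                })
                pts_by_country[ci].append(pts[nearest == ci])
    centroid_rows = []
    for ci in range(spec.n_countries):
        if pts_by_country[ci]:
            allpts = np.vstack(pts_by_country[ci])
            x, y = allpts.mean(axis=0)
        else:
            x, y = seeds[ci]
        centroid_rows.append({"country": f"country{ci}", "x": float(x), "y": float(y)})
    return pd.DataFrame(overlap_rows), pd.DataFrame(centroid_rows)


def gen_params(spec: WorldSpec) -> ParamSet:
    """Full, internally consistent parameter bundle for the spec's world."""
    ecos = spec.ecoregions()
    rng = _rng(spec, "biomes")
    biomes = rng.integers(0, spec.n_biomes, size=len(ecos))
    eco_biome = pd.DataFrame({
        "ecoregion": ecos, "biome": [f"biome{b}" for b in biomes]
    })
    suit, s_total = gen_suitability(spec)
    return ParamSet(
        rr=gen_rr_table(spec),
        z=gen_z_table(spec),
        dispersal=gen_dispersal(spec),
        gep=gen_geps(spec),
        regen=gen_regen(spec),
        ecoregion_biome=eco_biome,
        suitability=suit if not suit.empty else None,
        s_total=s_total if not s_total.empty else None,
        vertebrate_groups=tuple(g for g in spec.groups if g in VERTEBRATE_GROUPS),
        forest_land_use="managed_forest",
    )


@dataclass
class SyntheticWorld:
    """Everything the pipeline needs, generated from one WorldSpec + seed."""

    spec: WorldSpec
    legend: Legend
    grids: dict[str, LandscapeGrid]
    params: ParamSet
    overlaps: pd.DataFrame
    centroids: pd.DataFrame

    def ecoregion_areas(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"ecoregion": e, "area_m2": g.area()} for e, g in self.grids.items()
        ])

    def landuse_areas(self) -> pd.DataFrame:
        rows = []
        for eco, grid in self.grids.items():
            codes, counts = np.unique(grid.codes[grid.valid_mask()], return_counts=True)
            for code, cnt in zip(codes, counts):
                lu, m = self.legend.lookup(int(code))
                if lu == "natural":
                    continue
                rows.append({"ecoregion": eco, "land_use": lu, "intensity": m,
                             "area_m2": cnt * grid.cell_area})
        return pd.DataFrame(rows)


def make_world(spec: WorldSpec) -> SyntheticWorld:
    legend = default_legend(spec.shares)
    grids = {eco: gen_landscape(spec, eco, legend) for eco in spec.ecoregions()}
    overlaps, centroids = gen_country_overlay(spec)
    return SyntheticWorld(
        spec=spec, legend=legend, grids=grids, params=gen_params(spec),
        overlaps=overlaps, centroids=centroids,
    )
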