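# Methods

`fragcf` computes land-use biodiversity characterization factors (CFs) for
life cycle impact assessment from a countryside species–habitat relationship
whose habitat term accounts for both land-use *intensity* and landscape
*fragmentation*. This note documents the model, its parameters, the design
choices made where the design was genuinely open, and what the synthetic
test worlds do and do not demonstrate.

## The species–habitat relationship

For a species group *g* in an ecoregion *j* the relative regional species
loss (RSL, reported in PDF — potentially disappeared fraction) is

    RSL = 1 − (H₁ / H₀)^z

where *z* ∈ (0, 1) is the biome- and group-specific slope of the species–area
power law, H₀ = A_j (the ecoregion area; the reference state is fully natural
habitat with affinity 1), and the suitable connected area H₁ sums over all
land-cover classes (land use *i* at intensity *m*, plus natural habitat):

    H₁ = Σ_im  h_im · ECA_im

`h` is the habitat affinity of the class (1 for natural habitat) and `ECA`
its equivalent connected area. RSL is a long-term committed loss (extinction
debt), not an imminent one.

### Equivalent connected area

The ECA of a class is the area of one hypothetical patch with the same
probability of connectivity as the class's actual patch mosaic:

    ECA = sqrt( Σ_x Σ_y  A_x · A_y · p_xy )

over patch pairs (x, y) of the class, with `p_xx = 1`. It equals the total
class area when all patches are perfectly connected and falls towards the
largest single patch as connectivity vanishes. Patches are connected
components (8-neighbourhood by default; raster diagonals should not sever
habitat) of one class in the categorical raster; areas are cell counts ×
cell area.

**Dispersal kernel.** `p = 2^(−d_eff / d_med)` — a negative exponential
parameterised so the probability halves at the species group's median
dispersal distance. This is the minimal kernel honouring the "median"
semantics of the dispersal inputs: p(0) = 1, p(d_med) = ½, strictly
decreasing. Probabilities below 1e−6 are truncated to 0 to bound pairwise
work on large grids.

**Effective distance.** Without a resistance surface, the minimum
edge-to-edge Euclidean distance between boundary-cell centres (centroid
distance would overstate the separation of large patches). With a
resistance surface r ∈ [0, 1], the least-cost distance over the 8-connected
cell graph in which traversing a cell costs `cell_size × (1 + r)` (diagonal
steps scaled by √2); a resistant matrix can only lengthen separation, and
natural habitat always has r = 0.

## Parameter construction

**Affinity from relative richness.** Local sampling yields the relative
species richness `rr` of a class (richness relative to natural habitat).
Inverting the power law at the local scale gives `h = min(1, rr^(1/z))`; the
cap applies because affinity is a suitability fraction even when sampled
richness exceeds the reference. The inverse `rr = h^z` is used where a
class's richness must be back-calculated from an ecoregion-level affinity.

**Vertebrate route.** For vertebrates outside managed forests, ecoregion
affinities for *broad* land uses come from habitat-use species counts
(h_broad = S_use / S_total); intensity enters through globally defined
scaling factors `f = rr_m / rr_baseline` applied in rr-space:
`h_im = min(1, h_broad · f^(1/z))`. The baseline is the land use's least
intense available level, so f(minimal) = 1 whenever a minimal level exists.
f > 1 is allowed (richness ratios can exceed 1 empirically) and logged.
Managed forests use the plant route. Choosing rr-space (rather than
multiplying affinities directly) keeps the scaling consistent with the
power-law inversion that defines the affinities.

**Resistance.** Plants: `r = 1 − min(1, rr_surround / rr_habitat)` — a
matrix at least as rich as the habitat is fully permeable. Vertebrates:
`r = 1 − (S_shared / S_habitat) · min(1, f_surround)`, the species overlap
between habitat and matrix discounted by the matrix's intensity factor;
managed-forest pairs fall back to the rr comparison with back-calculated
rr where needed. The overlap counts are stored per surrounding class (one
pooled `S_shared` per class rather than per class pair).

**Intensity merging.** Adjacent intensity levels of a land use are merged
when their difference is practically insignificant (|Δ| < 0.05) *and*
statistically insignificant (two-sided Welch's t-test, p ≥ 0.05), evaluated
pairwise in intensity order and transitively closed; merged classes take the
inverse-variance-weighted mean. The rr tables carry estimates and standard
errors but no sample sizes, so the Welch statistic uses infinite degrees of
freedom (normal approximation) unless per-level sample sizes are supplied,
in which case Welch–Satterthwaite df apply. Degenerate thresholds act as
switches: α ≤ 0 never merges on statistical grounds, α ≥ 1 always does.

**Dispersal distances.** Species-level maximum dispersal distances with
gaps filled by taxonomy — the mean over observed congeners, then family,
order, class, and as a last resort the kingdom; observed values are never
altered and the fill rank is recorded. The per-ecoregion `d_med` is the
median over species present. Amphibians and reptiles use a fixed 9 km
default.

## Characterization factors

Four families per (ecoregion, group, class): {average, marginal} ×
{occupation, transformation}, each at regional and global extent.

**Average occupation CF** = RSL · a / A_im, with the allocation factor

    a_im = A_im (λ − h_im ρ̄)  /  Σ_k A_k (λ − h_k ρ̄)

where λ = (A_j − ECA_nat) / Σ_k A_k ≥ 1 is the connected natural habitat
consumed per m² of conversion (averaged over the conversion history — this
charges the induced fragmentation of the *remaining* natural habitat to land
use) and ρ̄ = Σ h_k ECA_k / Σ h_k A_k is the affinity-weighted mean
connectivity ratio of used land. The weights sum to exactly the total
deficit H₀ − H₁ and reduce to the classic `A · (1 − h)` form when
fragmentation is off (λ = ρ̄ = 1). Two properties motivated this weighting
over the alternatives (class-own ECA in the weights, or ignoring the
natural-habitat fragmentation deficit): the weights depend on a class only
through its area and affinity, so CFs inherit the intensity ordering of the
affinities instead of the stochastic fragmentation realization of
individual classes; and the weights match the marginal direction below, so
the two approaches account for the same total loss.

**Marginal occupation CF** = ∂RSL/∂A_im, by central finite difference with
relative step 1e−4. The expanding class gains habitat at h·ρ̄ per m² (new
conversion assumed as fragmented as existing used land on average) and
consumes natural habitat at λ per m². With this pairing,
marginal / average = z x^(z−1)(1 − x)/(1 − x^z) ≥ 1 for x = H₁/H₀ ∈ (0, 1),
so marginal CFs exceed average CFs on every landscape — the accelerating
loss expected from the convex power law. In the fragmentation-free limit
the derivative matches the closed form z/A_j · ((A_j − A)/A_j)^(z−1)
exactly (used as the test oracle). When no natural habitat remains, a
one-sided backward difference is used, with a warning.

**Transformation CF** = ½ · t · CF_occ, the area under a linear recovery of
the lost species over the regeneration time t (years) of the group, region
and land use.

**Global extent.** CF_glo = CF_reg × GEP, where the global extinction
probabilities of a species group sum to exactly 1 over all ecoregions, so a
regional extirpation converts to a global extinction expectation.

## Aggregation, uncertainty and proxies

Taxonomic aggregation is two-step with equal weights: vertebrate groups are
averaged, then plants and the vertebrate mean are averaged — a group's
species count never enters. Spatial aggregation to countries (and the
globe) is the mean of ecoregion CFs weighted by ecoregion(-within-country)
overlap area, with the relative weighted standard deviation (weighted SD /
weighted mean) expressing spatial spread; global aggregation optionally
weights by land-use-class area instead.

Gaps are filled in a fixed order and always flagged: (1) a missing
intensity level is rescaled from the nearest available sibling intensity of
the same land use by the unsuitability ratio (1 − h_target)/(1 − h_source) —
average CFs carry the allocation weight ∝ (1 − h) without fragmentation, so
this transfers the richness tables' intensity effect onto the CF scale;
(2) a missing land use takes the mean regional CF of non-proxy donor
ecoregions in the same biome times the target's GEP; (3) a missing GEP is
the biome's mean GEP-per-area density times the target's area. Proxy values
never overwrite native ones and never join donor pools. Countries with no
ecoregion match average their three nearest neighbours (centroid Euclidean
distance, ties by identifier); SDs are pooled as
sqrt(mean within-country variance + between-country variance of the means).

## Sensitivity variants and comparison statistics

Five variants: `default`; `rr_lo`/`rr_hi` (95 % CI bounds of rr, propagated
through the affinity route only — resistances keep point estimates, because
resistance depends on rr *ratios*, which do not shift monotonically under a
uniform bound, whereas the bounds should act monotonically on the loss);
`no_intensity` (rr pooled by inverse-variance mean for the plant route,
rescaling skipped for the vertebrate route); `no_fragmentation` (ECA
replaced by the class area). Variants are compared on ecoregion-level RSL
with Spearman rank correlation (average ranks for ties) and the sum-based
percent bias 100 · Σ(old − new)/Σ(new), negative when the old set is
smaller. Contribution-to-variance attributes CF variation to model factors
as ρ²/Σρ² of rank correlations. The threat filter keeps Red-List species in
categories VU/EN/CR/EW/EX with at least one land-use threat code (1, 2.1,
2.2, 2.3 or subcodes) whose A1–A4 listing criteria are not based solely on
the d/e subletters (exploitation, introduced taxa, pollutants).

## Synthetic worlds

The generator emits complete, internally consistent input bundles with
known ground truth: categorical landscapes (five anthropogenic land uses ×
up to three intensities + natural, ~37 % anthropogenic by default, roughly
the global share of used land), rr tables with SEs spanning 0.01–0.06 so
that some intensity pairs merge and some do not, z in 0.15–0.35, dispersal
medians (plants through the trait-table/gap-filling route, ~0.2–3 km; birds
5–40 km; mammals 2–15 km; herptiles fixed 9 km), GEPs normalised per group,
regeneration times 20–150 yr, habitat-use counts for the vertebrate route,
a Voronoi country overlay with lattice-sampled overlap areas, and Red-List
records with a planted qualifying subset. Landscape placement is seeded
cluster growth: the fragmentation parameter φ sets the number of cluster
seeds per class, so φ = 0 gives exactly one connected patch per class and
φ = 1 independent scatter, with ECA/A falling monotonically in between.
One seed fixes all randomness (stable CRC-keyed child streams), and
identical specs produce byte-identical bundles.

Default problem sizes in the test suite and acceptance script (24–36² cell
grids, 1 km cells, 1–4 ecoregions, 20 replicate worlds for ordering checks,
200 random instances for the ECA oracle) were chosen to exercise every code
path with multiple patches per class while keeping a full run in minutes.

**What passing tests show — and don't.** The synthetic worlds validate the
model's internal mathematics (oracle equivalence, orderings, limits,
determinism), not its ecological calibration: real land-use maps have
autocorrelated, legacy-shaped patterns rather than cluster-grown ones; real
rr tables come from mixed-effects models over heterogeneous studies; real
dispersal and suitability inputs carry taxonomic and spatial biases none of
which the generator emulates. Results on synthetic worlds therefore say
nothing about the magnitude of real-world CFs.

## Numerical choices and degenerate inputs

- ECA is clipped at the class area (guards float creep in the double sum).
- Dispersal probabilities below 1e−6 are set to 0.
- Finite-difference step: 1e−4 relative to the class area; one-sided when
  natural habitat is smaller than the step.
- H₁ is clamped to [0, H₀] inside the difference; RSL raises if H₁ exceeds
  H₀ beyond float tolerance.
- A fully natural ecoregion emits no CFs (logged); an all-benign landscape
  returns allocation 0 with a warning.
- Missing parameter keys skip the affected records and append to a
  machine-readable gap list consumed by the proxy stage.
- CSV outputs are schema-stable, sorted by the full record key, and written
  with `%.12g` floats so reruns are byte-identical.

## Known limitations

- The marginal CF uses the stylised (λ, ρ̄) conversion rates rather than a
  true geometric derivative through patch shapes; the CFs therefore cannot
  value a change in the *degree* of fragmentation at fixed areas.
- Only square-cell rasters in the ESRI ASCII grid format are read; vector
  landscapes and GeoTIFF are not supported.
- Vertebrate matrix permeability uses one pooled overlap count per
  surrounding class, not pair-specific overlaps.
- Occupation CFs describe sustained land use; no discounting of the
  extinction debt is applied.
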