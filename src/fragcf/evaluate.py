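"""Sensitivity variants, comparison statistics and the threat-filter rule.

The model variants exercise the main modelling choices: confidence-interval
bounds of the richness tables (``rr_lo``/``rr_hi``), pooling away land-use
intensity (``no_intensity``) and replacing the equivalent connected area by
the plain class area (``no_fragmentation``).  Variants are compared to the
default on the ecoregion-level regional species loss with Spearman's rank
correlation and a sum-based percent bias.  A rank-based contribution-to-
variance attributes CF variation to model factors.  The threat filter picks
species plausibly threatened by land use from Red-List-style records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .engine import EngineOptions, regional_loss_table
from .landscape import Legend
from .params import ParamSet

VARIANTS = ("default", "no_intensity", "no_fragmentation", "rr_lo", "rr_hi")

THREATENED_CATEGORIES = {"VU", "EN", "CR", "EW", "EX"}
CATEGORIES = {"LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD"}
#: IUCN threat classification prefixes tied to land use: residential and
#: commercial development (1), non-timber crops (2.1), wood and pulp
#: plantations (2.2), livestock farming (2.3)
LAND_USE_THREAT_PREFIXES = ("1", "2.1", "2.2", "2.3")


def spearman(a, b) -> float:
    """Spearman rank correlation with average ranks for ties."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman undefined for a constant vector")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def percent_bias(old, new) -> float:
    """100 * sum(old - new) / sum(new); negative means the old set is smaller."""
    old = np.asarray(old, float)
    new = np.asarray(new, float)
    if len(old) != len(new):
        raise ValueError("vectors must have equal length")
    denom = new.sum()
    if denom == 0:
        raise ValueError("reference values sum to zero")
    return float(100.0 * (old - new).sum() / denom)


def contribution_to_variance(factors: dict[str, np.ndarray], cf) -> dict[str, float]:
    """Share of CF variation attributed to each factor.

    share_i = rho_i**2 / sum_k rho_k**2, with rho the Spearman correlation of
    the factor against the CF vector; shares sum to 1 and are invariant to
    monotone rescaling of any factor.
    """
    if len(factors) < 2:
        raise ValueError("need at least two factors")
    rho2 = {name: spearman(vals, cf) ** 2 for name, vals in factors.items()}
    total = sum(rho2.values())
    if total == 0:
        raise ValueError("all factors uncorrelated with the CFs")
    return {name: v / total for name, v in rho2.items()}


def variant_options(name: str, base: EngineOptions | None = None) -> EngineOptions:
    base = base or EngineOptions()
    if name == "default":
        return replace(base, fragmentation=True, use_intensity=True, rr_bound="point")
    if name == "no_intensity":
        return replace(base, use_intensity=False)
    if name == "no_fragmentation":
        return replace(base, fragmentation=False)
    if name == "rr_lo":
        return replace(base, rr_bound="lo")
    if name == "rr_hi":
        return replace(base, rr_bound="hi")
    raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")


def run_variants(
    grids: dict,
    legend: Legend,
    params: ParamSet,
    groups: list[str] | None = None,
    variants: tuple[str, ...] = VARIANTS,
    base_options: EngineOptions | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ecoregion-level RSL per variant plus the variant-vs-default statistics.

    Returns (rsl_table, comparison): the first holds one RSL column per
    variant keyed by (ecoregion, group); the second the Spearman correlation
    and percent bias of each variant against the default, per species group
    (the default is its own reference: rho = 1, bias = 0).
    """
    if "default" not in variants:
        variants = ("default",) + tuple(variants)
    tables = {}
    for name in variants:
        t = regional_loss_table(
            grids, legend, params, groups, variant_options(name, base_options)
        )
        tables[name] = t.rename(columns={"rsl": name})
    out = tables["default"]
    for name in variants:
        if name == "default":
            continue
        out = out.merge(tables[name], on=["ecoregion", "group"])
    comp_rows = []
    for group, sub in out.groupby("group", sort=True):
        ref = sub["default"].to_numpy()
        for name in variants:
            vals = sub[name].to_numpy()
            can_rank = len(ref) >= 3 and np.ptp(ref) > 0 and np.ptp(vals) > 0
            comp_rows.append({
                "group": group, "variant": name,
                "spearman": spearman(vals, ref) if can_rank else np.nan,
                "percent_bias": percent_bias(vals, ref),
            })
    return out, pd.DataFrame(comp_rows)


# ---------------------------------------------------------------------------
# threat filter
# ---------------------------------------------------------------------------

@dataclass
class ThreatRecord:
    species: str
    category: str                 # LC|NT|VU|EN|CR|EW|EX|DD
    threat_codes: tuple[str, ...]  # e.g. ("2.1.2", "5.3")
    criteria: str                  # e.g. "A2cd; B1ab(iii)"


_CRITERION_A = re.compile(r"A([1-4])([a-z]+)")


def _land_use_threat(code: str) -> bool:
    code = code.strip()
    return any(
        code == p or code.startswith(p + ".") for p in LAND_USE_THREAT_PREFIXES
    )


def _only_de_a_criteria(criteria: str) -> bool:
    """True when the record's A1-A4 criteria use only the d/e subletters.

    Those subletters denote declines driven by exploitation, introduced taxa,
    pollutants etc. rather than habitat loss, so a listing based only on them
    is not attributed to land use.  Records without any A criterion are not
    excluded.
    """
    letters: set[str] = set()
    found = False
    for m in _CRITERION_A.finditer(criteria):
        found = True
        letters.update(m.group(2))
    return found and letters <= {"d", "e"}


def filter_threatened_by_land_use(records: list[ThreatRecord]) -> list[str]:
    """Species threatened specifically by land use.

    Keeps species whose Red-List category is threatened-or-worse (VU, EN, CR,
    EW, EX), that face at least one land-use threat (codes 1, 2.1, 2.2, 2.3
    or their subcodes), and whose A1-A4 listing criteria are not based only
    on the d/e subletters.  Malformed records are skipped with a warning.
    """
    import warnings

    kept = []
    for rec in records:
        if rec.category not in CATEGORIES:
            warnings.warn(f"{rec.species}: unknown category {rec.category!r}; skipped",
                          stacklevel=2)
            continue
        if rec.category not in THREATENED_CATEGORIES:
            continue
        if not any(_land_use_threat(c) for c in rec.threat_codes):
            continue
        if _only_de_a_criteria(rec.criteria):
            continue
        kept.append(rec.species)
    return kept
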