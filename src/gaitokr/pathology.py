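"""Region-level pathology densities and pathology-behavior correlations.

AT8+ (phospho-Tau) cell counts per region are converted to densities per
10^4 um^2 by pooling sections (count-sum over area-sum, both hemispheres),
then correlated with per-animal behavioral summaries using Pearson r.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import REGIONS

DENSITY_UNIT_UM2 = 1e4

#: largest n for which the two-sided Pearson p is computed by exhaustive
#: permutation enumeration (n! <= 5040) rather than the t approximation
EXACT_PERMUTATION_MAX_N = 7


@dataclass(frozen=True)
class CorrelationResult:
    region: str
    behavior_measure: str
    pearson_r: float
    p_value: float
    n: int
    method: str   # "permutation-exact" | "t"


def compute_density(counts: pd.DataFrame,
                    regions: tuple[str, ...] | None = REGIONS) -> pd.DataFrame:
    """Pooled density per animal and region.

    ``counts`` needs columns animal_id, region, at8_count, area_um2 (one row
    per section; a section_id column is allowed and ignored).  Sections are
    pooled before division: density = sum(count) / (sum(area)/1e4), which is
    invariant to how a region's area is split into sections.
    """
    required = {"animal_id", "region", "at8_count", "area_um2"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    if (counts["at8_count"] < 0).any():
        raise ValueError("counts must be >= 0")
    if (counts["area_um2"] <= 0).any():
        raise ValueError("section areas must be > 0")
    if regions is not None:
        unknown = set(counts["region"]) - set(regions)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")
    pooled = (counts.groupby(["animal_id", "region"], as_index=False)
              .agg(at8_count=("at8_count", "sum"), area_um2=("area_um2", "sum")))
    if (pooled["area_um2"] <= 0).any():
        raise ValueError("zero total area for some animal-region")
    pooled["density"] = pooled["at8_count"] / (pooled["area_um2"] / DENSITY_UNIT_UM2)
    return pooled


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Pearson r with a two-sided p.

    For n <= EXACT_PERMUTATION_MAX_N the p is the exact permutation
    probability P(|r_perm| >= |r_obs|) over all n! pairings; the t
    approximation is unreliable at these n.  Larger samples use the standard
    t-based p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan, "undefined (zero variance)"
    r_obs = float(np.corrcoef(x, y)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        xc = (x - x.mean()) / (x.std() * math.sqrt(n))
        yc = (y - y.mean()) / (y.std() * math.sqrt(n))
        perms = np.array(list(itertools.permutations(range(n))))
        r_perm = yc[perms] @ xc
        p = float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))
        return r_obs, p, "permutation-exact"
    res = stats.pearsonr(x, y)
    return r_obs, float(res.pvalue), "t"


def correlate_pathology_behavior(densities: pd.DataFrame,
                                 behaviors: pd.DataFrame,
                                 min_n: int = 3) -> list[CorrelationResult]:
    """Pearson correlation of each region's density with each behavior measure.

    Animals missing either value are dropped pairwise; pairs with fewer than
    ``min_n`` complete animals, or with zero variance, are skipped with a
    warning.  Results are sorted by |r| descending.
    """
    if "density" not in densities.columns:
        densities = compute_density(densities)
    measures = [c for c in behaviors.columns if c != "animal_id"]
    wide = densities.pivot(index="animal_id", columns="region", values="density")
    merged = wide.join(behaviors.set_index("animal_id"), how="inner")
    results: list[CorrelationResult] = []
    for region in wide.columns:
        for measure in measures:
            sub = merged[[region, measure]].dropna()
            if len(sub) < min_n:
                warnings.warn(f"{region} x {measure}: fewer than {min_n} complete "
                              "animals; skipped")
                continue
            x = sub[region].to_numpy()
            y = sub[measure].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(f"{region} x {measure}: zero variance; correlation "
                              "undefined")
                results.append(CorrelationResult(region, measure, math.nan,
                                                 math.nan, len(sub),
                                                 "undefined (zero variance)"))
                continue
            r, p, method = pearson_with_p(x, y)
            results.append(CorrelationResult(region, measure, r, p, len(sub),
                                             method))
    return sorted(results, key=lambda c: (-abs(c.pearson_r)
                                          if np.isfinite(c.pearson_r) else 0.0))


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; per-region correlations are reported
    unadjusted by default, mirroring common practice in small-cohort
    histology studies — interpret accordingly)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results],
                        columns=["region", "behavior_measure", "pearson_r",
                                 "p_value", "n", "method"])
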