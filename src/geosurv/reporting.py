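"""Posterior draws → headline tables: HRRs, importance flags, region counts.

An association is *statistically important* when the 95% equal-tailed
credible interval of the hazard-rate ratio excludes 1, and *protective* when
additionally the interval lies below 1 (upper bound strictly < 1). Per-region
counts of protective interventions summarise where the intervention mix is
effective; harmful-important entries (lower bound > 1) are reported but never
counted as effective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorDraws, gelman_rubin
from .spatial_model import effective_range

NATIONAL = "National"


@dataclass
class HrrEntry:
    intervention: str
    scope: str  # NATIONAL or a region name
    hrr_median: float
    bci95: tuple[float, float]
    important: bool
    protective: bool


def flag_importance(hrr_median: float, bci95) -> tuple[bool, bool]:
    """(important, protective) flags for a median and 95% interval."""
    lower, upper = float(bci95[0]), float(bci95[1])
    if not (lower <= hrr_median <= upper):
        raise ValueError(f"malformed interval: median {hrr_median} outside ({lower}, {upper})")
    important = (lower > 1.0) or (upper < 1.0)
    protective = important and (upper < 1.0)
    return important, protective


def _entry(intervention, scope, draws_1d) -> HrrEntry:
    med = float(np.percentile(draws_1d, 50))
    lo = float(np.percentile(draws_1d, 2.5))
    hi = float(np.percentile(draws_1d, 97.5))
    important, protective = flag_importance(med, (lo, hi))
    return HrrEntry(intervention, scope, med, (lo, hi), important, protective)


def regional_hrr(draws: PosteriorDraws, intervention: str = "intervention",
                 region_ids=None) -> list:
    """National and per-region HRR entries from draws of a and w.

    The national entry summarises exp(a); region q summarises exp(a + w_q),
    so the regional HRR applies the spatially varying coefficient as a whole.
    """
    a = draws.pooled("a")
    w_names = [n for n in draws.names() if n.startswith("w[")]
    if region_ids is None:
        region_ids = [n[2:-1] for n in w_names]
    entries = [_entry(intervention, NATIONAL, np.exp(a))]
    for rid in region_ids:
        name = f"w[{rid}]"
        if name not in draws.params:
            raise KeyError(f"no draws for region {rid!r}")
        entries.append(_entry(intervention, rid, np.exp(a + draws.pooled(name))))
    return entries


def effective_range_summary(rho_draws) -> dict:
    """Median and 95% BCI of the effective range −log(0.05)/ρ, in km."""
    rho = np.asarray(rho_draws, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho draws must be positive")
    rng_draws = effective_range(rho)
    return {
        "median": float(np.percentile(rng_draws, 50)),
        "lower": float(np.percentile(rng_draws, 2.5)),
        "upper": float(np.percentile(rng_draws, 97.5)),
    }


def entries_to_frame(entries) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "intervention": [e.intervention for e in entries],
            "scope": [e.scope for e in entries],
            "hrr": [e.hrr_median for e in entries],
            "lower": [e.bci95[0] for e in entries],
            "upper": [e.bci95[1] for e in entries],
            "important": [e.important for e in entries],
            "protective": [e.protective for e in entries],
        }
    )


def count_protective_per_region(table: pd.DataFrame) -> dict:
    """Count interventions with 95% BCI upper bound < 1 per region.

    ``table`` has one row per (intervention, scope) with columns
    ``lower``/``upper``; national rows are excluded from the counts.
    Returns per-region counts plus their min / median / max.
    """
    regional = table[table["scope"] != NATIONAL]
    dup = regional.duplicated(subset=["intervention", "scope"])
    if dup.any():
        pairs = regional.loc[dup, ["intervention", "scope"]].values.tolist()
        raise ValueError(f"duplicate (intervention, region) rows: {pairs[:5]}")
    protective = regional["upper"] < 1.0
    counts = (
        regional.assign(protective=protective)
        .groupby("scope")["protective"]
        .sum()
        .astype(int)
        .sort_index()
    )
    return {
        "per_region": counts.to_dict(),
        "min": int(counts.min()),
        "median": float(np.median(counts.to_numpy())),
        "max": int(counts.max()),
    }


def cohort_bookkeeping(clusters: tuple, children: tuple, deaths: tuple) -> dict:
    """Retention and mortality percentages from (kept, total) count pairs."""
    out = {}
    for key, (num, den) in {"clusters": clusters, "children": children, "deaths": deaths}.items():
        if den <= 0 or num < 0 or num > den:
            raise ValueError(f"invalid counts for {key}: {num}/{den}")
        out[f"{key}_pct"] = round(100.0 * num / den, 1)
    return out


def fit_report(draws: PosteriorDraws, intervention: str) -> dict:
    """Bundle the headline posterior summaries of one intervention fit."""
    entries = regional_hrr(draws, intervention=intervention)
    psrf = {
        name: gelman_rubin(draws.params[name])
        for name in draws.names()
        if not name.startswith("phi[")
    }
    return {
        "hrr": entries_to_frame(entries),
        "range_km": effective_range_summary(draws.pooled("rho")),
        "sigma2": float(np.percentile(draws.pooled("sigma2"), 50)),
        "sigmaq2": float(np.percentile(draws.pooled("sigmaq2"), 50)),
        "psrf": psrf,
        "acceptance": draws.acceptance,
    }
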