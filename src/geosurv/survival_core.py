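"""Weibull proportional-hazards likelihood for right-censored child survival.

The hazard for child j is h(t) = δ t^{δ-1} exp(η_j) with Weibull shape δ and
linear predictor η_j; the survivor function is S(t) = exp(−t^δ e^{η_j}).
A child who died contributes log h(t_j) − H(t_j), a censored child only the
cumulative hazard −H(t_j), with H(t) = t^δ e^η.
"""

from __future__ import annotations

import numpy as np
from lifelines import KaplanMeierFitter

MIN_TIME_MONTHS = 0.25


def shift_zero_times(times: np.ndarray, minimum: float = MIN_TIME_MONTHS):
    """Shift times recorded as zero months up to ``minimum``.

    Survey records give age at death in whole months, so a death in the first
    days of life appears as 0 — which would make log t infinite. Only such
    exact zeros are lifted (to 0.25 months by default); genuinely positive
    times are never altered, since flooring them distorts the early-death
    mass that identifies the Weibull shape. Returns the adjusted times and
    the adjustment count.
    """
    times = np.asarray(times, dtype=float).copy()
    mask = times < 1e-8
    times[mask] = minimum
    return times, int(mask.sum())


def loglik(times, events, eta, delta: float) -> float:
    """Weibull PH log-likelihood for right-censored data.

    Σ_j [ event_j (log δ + (δ−1) log t_j + η_j) − t_j^δ e^{η_j} ].
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    eta = np.broadcast_to(np.asarray(eta, dtype=float), t.shape)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("all times must be positive")
    if delta <= 0:
        raise ValueError("delta must be positive")
    logt = np.log(t)
    return float(
        np.sum(e * (np.log(delta) + (delta - 1.0) * logt + eta))
        - np.sum(np.exp(delta * logt + eta))
    )


def survival(t, eta, delta: float):
    """S(t) = exp(−t^δ e^η), the Weibull PH survivor function."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    return np.exp(-np.power(t, delta) * np.exp(np.asarray(eta, dtype=float)))


def hazard(t, eta, delta: float):
    """h(t) = δ t^{δ−1} e^η."""
    t = np.asarray(t, dtype=float)
    return delta * np.power(t, delta - 1.0) * np.exp(np.asarray(eta, dtype=float))


def km_5q0(times, events, horizon: float = 60.0) -> float:
    """Deaths per 1000 before ``horizon`` months, by Kaplan–Meier.

    1000 × (1 − Ŝ_KM(horizon)); censored children contribute risk time up to
    their censoring age. This is a product-limit proxy for the under-five
    mortality rate, not the DHS synthetic-cohort life-table statistic.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("km_5q0 requires a nonempty record set")
    km = KaplanMeierFitter()
    km.fit(t, event_observed=e)
    s60 = float(km.survival_function_at_times(horizon).iloc[0])
    return 1000.0 * (1.0 - s60)


def death_fraction(events) -> float:
    """Raw fraction of children with an observed death (not a life-table rate)."""
    e = np.asarray(events, dtype=float)
    if e.size == 0:
        raise ValueError("empty record set")
    return float(e.mean())
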