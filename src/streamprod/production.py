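"""Secondary production by the instantaneous growth method, with bootstrap.

Interval production of a size class is

    P = g * dt * (B_t + B_{t+dt}) / 2      [mg AFDM m^-2 per interval]

the product of the mass-specific growth rate, the interval length and the
mean standing biomass over the interval.  Size classes are summed to
populations, populations to the community, and intervals to the year —
always replicate-wise, so a single seed propagates one internally
consistent bootstrap sample through every level of aggregation.

Biomass uncertainty comes from resampling the replicate field samples
(Surber samples) with replacement within each date; growth uncertainty
comes from the growth module (cohort resampling, or coefficient uncertainty
of the fitted growth model for taxa without direct measurements).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import BootstrapDistribution

__all__ = [
    "IntervalProduction",
    "interval_production",
    "biomass_from_samples",
    "bootstrap_population_production",
    "aggregate_community",
    "annual_production",
    "annual_mean_biomass",
    "pb_ratio",
]

logger = logging.getLogger(__name__)

#: Surber sampler area in m^2.
SURBER_AREA_M2 = 0.023


def interval_production(g, b_t, b_t_dt, dt_days, allow_negative: bool = False):
    """Interval production ``g * dt * (B_t + B_{t+dt}) / 2`` (mg AFDM m^-2).

    In the population context growth rates are non-negative by construction
    (the cohort bootstrap enforces it); a negative ``g`` is rejected unless
    ``allow_negative`` is set.
    """
    g = np.asarray(g, dtype=float)
    b_t = np.asarray(b_t, dtype=float)
    b_t_dt = np.asarray(b_t_dt, dtype=float)
    if np.any(b_t < 0) or np.any(b_t_dt < 0):
        raise ValueError("biomass must be non-negative")
    if np.asarray(dt_days).min() <= 0:
        raise ValueError("interval length must be strictly positive")
    if not allow_negative and np.any(g < 0):
        raise ValueError("negative growth rate in population context")
    p = g * dt_days * (b_t + b_t_dt) / 2.0
    return float(p) if p.ndim == 0 else p


@dataclass(frozen=True)
class IntervalProduction:
    """Bootstrap production over one sampling interval at one level."""

    stream_id: str
    date_t: object
    date_t_dt: object
    dt_days: float
    level: str  # size_class | population | community
    taxon_id: str | None
    P: BootstrapDistribution          # mg AFDM m^-2 per interval
    P_daily: BootstrapDistribution    # mg AFDM m^-2 d^-1
    B_mean: BootstrapDistribution     # mg AFDM m^-2


def _expanded_density(records: pd.DataFrame) -> pd.Series:
    """Individuals m^-2 after sub-sample expansion (count / split / area)."""
    return (
        records["count"]
        / records["split_fraction"].astype(float)
        / records["area_m2"].astype(float)
    )


def biomass_from_samples(
    records: pd.DataFrame,
    date,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[tuple, np.ndarray]:
    """Bootstrap biomass per taxon x size class on one date (mg AFDM m^-2).

    Each bootstrap iteration resamples the replicate field samples with
    replacement (n = number of field replicates present on the date) and
    averages the expanded biomass density.  One resampling of replicates is
    shared across all taxa and size classes, preserving the spatial
    covariance between them within an iteration.

    Parameters
    ----------
    records
        SizeClassRecord table for one stream: columns ``date``,
        ``replicate``, ``taxon_id``, ``length_bin_mm``, ``count``,
        ``split_fraction``, ``area_m2``, ``mass_mg``.

    Returns
    -------
    dict mapping ``(taxon_id, length_bin_mm)`` to a replicate vector of
    length ``n_boot``.  An empty community yields an empty dict.
    """
    day = records[records["date"] == date]
    if date not in set(records["date"]):
        raise ValueError(f"no samples on date {date!r}")
    rng = np.random.default_rng(seed) if rng is None else rng
    reps = sorted(day["replicate"].unique())
    n_rep = len(reps)
    draw = rng.integers(0, n_rep, size=(n_boot, n_rep))

    out: dict[tuple, np.ndarray] = {}
    if day.empty:
        return out
    dens = _expanded_density(day) * day["mass_mg"].astype(float)
    day = day.assign(_bio=dens)
    # per (taxon, bin): vector of per-replicate-sample biomass densities
    for (taxon, length_bin), sub in day.groupby(["taxon_id", "length_bin_mm"], sort=True):
        per_rep = np.zeros(n_rep)
        pos = {r: i for i, r in enumerate(reps)}
        for r, v in zip(sub["replicate"], sub["_bio"]):
            per_rep[pos[r]] += v
        out[(taxon, length_bin)] = per_rep[draw].mean(axis=1)
    return out


def community_biomass(per_class: dict[tuple, np.ndarray], n_boot: int) -> np.ndarray:
    """Replicate-wise community biomass from a per-class biomass dict."""
    if not per_class:
        return np.zeros(n_boot)
    return np.sum(list(per_class.values()), axis=0)


def _resample_to(arr, n_boot: int, rng: np.random.Generator, resample: bool) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(arr, dtype=float))
    if not resample:
        if arr.size == 1:
            return np.full(n_boot, arr[0])
        if arr.size != n_boot:
            raise ValueError(
                f"paired input has {arr.size} replicates, expected {n_boot}"
            )
        return arr
    return arr[rng.integers(0, arr.size, size=n_boot)]


def bootstrap_population_production(
    growth: dict,
    biomass_t: dict,
    biomass_t_dt: dict,
    dt_days: float,
    stream_id: str = "",
    taxon_id: str | None = None,
    date_t=None,
    date_t_dt=None,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    resample_inputs: bool = False,
) -> IntervalProduction:
    """Paired bootstrap of population production over one interval.

    Parameters
    ----------
    growth, biomass_t, biomass_t_dt
        Mappings from size-class key to replicate vectors: growth rates
        (d^-1) and endpoint biomasses (mg AFDM m^-2).  Keys must agree
        between the two biomass dicts; each class must have a growth entry.
        Vectors of length ``n_boot`` are consumed as already-paired
        replicates; with ``resample_inputs=True`` arbitrary-length input
        distributions are resampled with replacement instead (used by
        enumeration oracles and small exact cases).

    Returns
    -------
    IntervalProduction at the population level: size classes are summed
    within each replicate.

    Raises
    ------
    KeyError
        A size class without a growth source (no silent fill-in).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    classes = sorted(set(biomass_t) | set(biomass_t_dt))
    missing = [c for c in classes if c not in growth]
    if missing:
        raise KeyError(
            f"no growth source for size class(es) {missing} "
            f"of taxon {taxon_id!r} in stream {stream_id!r}"
        )
    p_total = np.zeros(n_boot)
    b_total = np.zeros(n_boot)
    for c in classes:
        g = _resample_to(growth[c], n_boot, rng, resample_inputs)
        bt = _resample_to(biomass_t.get(c, 0.0), n_boot, rng, resample_inputs)
        btd = _resample_to(biomass_t_dt.get(c, 0.0), n_boot, rng, resample_inputs)
        if np.any(g < 0):
            raise ValueError(
                f"negative growth replicate for class {c} of taxon {taxon_id!r}"
            )
        p_total += g * dt_days * (bt + btd) / 2.0
        b_total += (bt + btd) / 2.0
    return IntervalProduction(
        stream_id=stream_id,
        date_t=date_t,
        date_t_dt=date_t_dt,
        dt_days=float(dt_days),
        level="population",
        taxon_id=taxon_id,
        P=BootstrapDistribution(p_total, seed),
        P_daily=BootstrapDistribution(p_total / dt_days, seed),
        B_mean=BootstrapDistribution(b_total, seed),
    )


def aggregate_community(populations: list[IntervalProduction]) -> IntervalProduction:
    """Replicate-wise sum of population production into community production.

    All inputs must share the interval and ``n_boot``; the replicate order is
    the pairing key and is never permuted.
    """
    if not populations:
        raise ValueError("no populations to aggregate")
    first = populations[0]
    n = first.P.n_boot
    for p in populations[1:]:
        if p.P.n_boot != n:
            raise ValueError("mismatched n_boot across populations")
        if (p.date_t, p.date_t_dt) != (first.date_t, first.date_t_dt):
            raise ValueError("mismatched intervals across populations")
    return IntervalProduction(
        stream_id=first.stream_id,
        date_t=first.date_t,
        date_t_dt=first.date_t_dt,
        dt_days=first.dt_days,
        level="community",
        taxon_id=None,
        P=BootstrapDistribution.sum([p.P for p in populations]),
        P_daily=BootstrapDistribution.sum([p.P_daily for p in populations]),
        B_mean=BootstrapDistribution.sum([p.B_mean for p in populations]),
    )


def annual_production(
    intervals: list[IntervalProduction],
    max_gap_days: float = 45.0,
    unit: str = "g",
) -> BootstrapDistribution:
    """Replicate-wise sum of interval production over the year.

    Intervals must not overlap; gaps longer than ``max_gap_days`` between
    consecutive samples are logged as warnings (field schedules slip) but do
    not abort the estimate.

    Returns production in g AFDM m^-2 y^-1 by default (``unit="mg"`` keeps
    milligrams).
    """
    if not intervals:
        raise ValueError("no intervals")
    ordered = sorted(intervals, key=lambda iv: pd.Timestamp(iv.date_t))
    for a, b in zip(ordered, ordered[1:]):
        if pd.Timestamp(b.date_t) < pd.Timestamp(a.date_t_dt):
            raise ValueError(
                f"overlapping intervals: {a.date_t}-{a.date_t_dt} and "
                f"{b.date_t}-{b.date_t_dt}"
            )
        if a.dt_days > max_gap_days:
            logger.warning(
                "sampling gap of %.0f d (%s to %s) exceeds %.0f d",
                a.dt_days, a.date_t, a.date_t_dt, max_gap_days,
            )
    if ordered[-1].dt_days > max_gap_days:
        logger.warning(
            "sampling gap of %.0f d (%s to %s) exceeds %.0f d",
            ordered[-1].dt_days, ordered[-1].date_t, ordered[-1].date_t_dt, max_gap_days,
        )
    total = BootstrapDistribution.sum([iv.P for iv in ordered])
    if unit == "g":
        return total * (1.0 / 1000.0)
    if unit == "mg":
        return total
    raise ValueError("unit must be 'g' or 'mg'")


def annual_mean_biomass(intervals: list[IntervalProduction]) -> BootstrapDistribution:
    """Time-weighted annual mean biomass (mg AFDM m^-2), replicate-wise.

    Weights each interval's mean biomass by its length so irregular sampling
    schedules do not bias the annual mean.
    """
    if not intervals:
        raise ValueError("no intervals")
    w = np.array([iv.dt_days for iv in intervals], dtype=float)
    w /= w.sum()
    stacked = np.stack([iv.B_mean.replicates for iv in intervals])
    return BootstrapDistribution(w @ stacked, intervals[0].B_mean.seed)


def pb_ratio(p: BootstrapDistribution, b: BootstrapDistribution) -> BootstrapDistribution:
    """Replicate-wise biomass turnover P:B (units follow the inputs).

    Both distributions must be paired (same seed path, same ``n_boot``) and
    every biomass replicate strictly positive.
    """
    if p.n_boot != b.n_boot:
        raise ValueError("P and B distributions are not paired (n_boot differs)")
    if np.any(b.replicates <= 0):
        raise ValueError(
            "zero biomass replicate: compute P:B at an aggregation level "
            "where biomass is always positive (e.g. community)"
        )
    return p / b
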