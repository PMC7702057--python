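"""Boltzmann-Arrhenius temperature scaling of community quantities.

Rates and stocks in metabolic ecology scale as ``exp(-E / kT)``.  Regressing
a log-transformed quantity on the *standardised inverse Boltzmann
temperature*

    x(T) = 1/(k T_ref) - 1/(k T)        [eV^-1, T in Kelvin]

makes the slope an apparent activation energy ``E`` (eV) directly: positive
``E`` means the quantity increases with temperature.  ``x`` is centred so
that ``x(T_ref) = 0`` with ``T_ref = 15 °C`` by default.

Community biomass ``B`` and turnover ``P:B`` additionally carry theoretical
body-size effects (``M^0.25`` and ``M^-0.25``).  Before estimating their
temperature dependence we remove the expected mass effect using the
biomass-weighted mean individual body mass of the community, so the fitted
slopes are comparable across communities of different size structure.

Activation energies are estimated with a two-level bootstrap: each outer
replicate draws one inner bootstrap replicate of the quantity per unit
(stream, or sampling interval within a stream) and fits an OLS slope of the
log quantity on ``x``; the outer distribution of slopes supplies the mean
and percentile confidence bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bootstrap import BootstrapDistribution

__all__ = [
    "BOLTZMANN_EV",
    "T_REF_C",
    "ActivationEnergyEstimate",
    "standardize_temperature",
    "unstandardize_temperature",
    "weighted_community_mass",
    "mass_correct",
    "fit_activation_energy",
    "within_stream_E",
    "percent_change_per_degree",
    "elasticity_percent",
]

#: Boltzmann constant in eV per Kelvin (conventional 3-digit value used
#: throughout the metabolic-ecology literature).
BOLTZMANN_EV = 8.62e-5

#: Default centring temperature for the standardised Boltzmann axis (°C).
T_REF_C = 15.0


def standardize_temperature(temp_c, t_ref_c: float = T_REF_C):
    """Standardised inverse Boltzmann temperature, ``1/(kT_ref) - 1/(kT)``.

    Parameters
    ----------
    temp_c
        Temperature(s) in °C.  Must exceed absolute zero.
    t_ref_c
        Centring temperature in °C; ``x(t_ref_c) = 0``.

    Returns
    -------
    x : float or ndarray, eV^-1.  Strictly increasing in temperature.
    """
    temp_c = np.asarray(temp_c, dtype=float)
    if np.any(temp_c <= -273.15):
        raise ValueError("temperature at or below absolute zero")
    t_k = temp_c + 273.15
    t_ref_k = float(t_ref_c) + 273.15
    x = 1.0 / (BOLTZMANN_EV * t_ref_k) - 1.0 / (BOLTZMANN_EV * t_k)
    return x if x.ndim else float(x)


def unstandardize_temperature(x, t_ref_c: float = T_REF_C):
    """Invert :func:`standardize_temperature`, returning °C."""
    x = np.asarray(x, dtype=float)
    t_ref_k = float(t_ref_c) + 273.15
    inv = 1.0 / (BOLTZMANN_EV * t_ref_k) - x
    t_k = 1.0 / (BOLTZMANN_EV * inv)
    out = t_k - 273.15
    return out if out.ndim else float(out)


def weighted_community_mass(biomass, mass):
    """Biomass-weighted mean individual body mass of the community.

    Parameters
    ----------
    biomass : (n_taxa,) or (n_taxa, n_boot) array
        Annual mean biomass per taxon (mg AFDM m^-2); replicate columns are
        paired across taxa.
    mass : (n_taxa,) or (n_taxa, n_boot) array
        Annual mean individual body mass per taxon (mg AFDM).

    Returns
    -------
    M_c : float or (n_boot,) ndarray, mg AFDM.
    """
    b = np.atleast_1d(np.asarray(biomass, dtype=float))
    m = np.atleast_1d(np.asarray(mass, dtype=float))
    if b.ndim == 1 and m.ndim == 2:
        b = b[:, None] * np.ones_like(m)
    if m.ndim == 1 and b.ndim == 2:
        m = m[:, None] * np.ones_like(b)
    total = b.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("community biomass is zero in at least one replicate")
    mc = (b * m).sum(axis=0) / total
    return float(mc) if np.ndim(mc) == 0 else mc


def mass_correct(value, m_c, exponent: float, direction: str = "remove"):
    """Remove (or apply) the theoretical body-size effect from B or P:B.

    Theory expects biomass to scale as ``M^+0.25`` and turnover as
    ``M^-0.25``.  With ``direction="remove"`` (default) the expected mass
    effect is divided out: ``corrected = value / M_c**exponent``, so that the
    corrections on B and P:B cancel in their product and corrected-B times
    corrected-P:B still equals P.  ``direction="multiply"`` applies
    ``value * M_c**exponent`` instead.

    Parameters
    ----------
    value : scalar, array or BootstrapDistribution
    m_c : scalar, array or BootstrapDistribution
        Biomass-weighted community body mass (mg AFDM); must be positive.
    exponent
        Theoretical exponent: +0.25 for biomass, -0.25 for P:B.  Other
        magnitudes are allowed but flagged with a warning.
    """
    if abs(abs(exponent) - 0.25) > 1e-12:
        warnings.warn(
            f"non-standard body-size exponent {exponent}; proceeding anyway",
            stacklevel=2,
        )
    if direction not in ("remove", "multiply"):
        raise ValueError("direction must be 'remove' or 'multiply'")
    mc = m_c.replicates if isinstance(m_c, BootstrapDistribution) else np.asarray(m_c, dtype=float)
    if np.any(np.asarray(mc) <= 0):
        raise ValueError("community mass must be positive")
    factor = mc ** exponent
    if direction == "remove":
        return value / factor if not isinstance(value, BootstrapDistribution) else value * (1.0 / factor)
    return value * factor


@dataclass(frozen=True)
class ActivationEnergyEstimate:
    """Apparent activation energy with bootstrap uncertainty.

    ``E_mean`` is the mean OLS slope of the log quantity on the standardised
    Boltzmann temperature over the outer bootstrap; ``r2`` comes from the
    single point fit on unit means.
    """

    E_mean: float
    ci_low: float
    ci_high: float
    r2: float
    n_boot: int
    scope: str
    quantity: str
    slopes: BootstrapDistribution
    seed: int | None = None

    def summary(self) -> dict:
        return {
            "quantity": self.quantity,
            "scope": self.scope,
            "E_mean": self.E_mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "r2": self.r2,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def _as_replicate_matrix(values: Sequence) -> list[np.ndarray]:
    out = []
    for v in values:
        arr = v.replicates if isinstance(v, BootstrapDistribution) else np.atleast_1d(np.asarray(v, dtype=float))
        out.append(arr)
    return out


def fit_activation_energy(
    values: Sequence,
    x,
    n_boot: int = 10_000,
    seed: int | None = None,
    unit_resample: bool = False,
    scope: str = "among",
    quantity: str = "P",
) -> ActivationEnergyEstimate:
    """Bootstrap the OLS slope of ``ln(value)`` on standardised temperature.

    Each of the ``n_boot`` outer replicates draws one inner bootstrap
    replicate per unit and fits an ordinary least-squares line of the log
    value on ``x``.  The same ``seed`` therefore yields identical inner draw
    indices for any set of distributions with matching shapes — this is what
    makes slope estimates for P, corrected B and corrected P:B additive per
    replicate.

    Parameters
    ----------
    values
        One :class:`BootstrapDistribution` (or replicate array) per unit;
        all replicates must be strictly positive.
    x
        Standardised Boltzmann temperature per unit (eV^-1).
    unit_resample
        Also resample the units with replacement in each outer replicate.
        Off by default: with as few as six units, resampling them produces
        frequent degenerate designs.

    Returns
    -------
    ActivationEnergyEstimate
    """
    reps = _as_replicate_matrix(values)
    x = np.asarray(x, dtype=float)
    n_units = len(reps)
    if n_units < 3 and not (n_units == 2 and all(r.size == 1 for r in reps)):
        raise ValueError(f"need >= 3 units to fit a slope, got {n_units}")
    if x.size != n_units:
        raise ValueError("x must have one entry per unit")
    for i, r in enumerate(reps):
        if np.any(r <= 0):
            raise ValueError(f"non-positive value in unit {i}; cannot log-transform")

    ln = [np.log(r) for r in reps]
    rng = np.random.default_rng(seed)
    # inner draw: one replicate per unit per outer iteration
    y = np.empty((n_boot, n_units))
    for j, lj in enumerate(ln):
        idx = rng.integers(0, lj.size, size=n_boot)
        y[:, j] = lj[idx]

    if unit_resample:
        uidx = rng.integers(0, n_units, size=(n_boot, n_units))
        xb = x[uidx]
        yb = np.take_along_axis(y, uidx, axis=1)
        xc = xb - xb.mean(axis=1, keepdims=True)
        denom = (xc ** 2).sum(axis=1)
        ok = denom > 0
        slopes = np.full(n_boot, np.nan)
        slopes[ok] = ((yb - yb.mean(axis=1, keepdims=True)) * xc).sum(axis=1)[ok] / denom[ok]
        slopes = slopes[np.isfinite(slopes)]
    else:
        xc = x - x.mean()
        denom = float((xc ** 2).sum())
        if denom == 0:
            raise ValueError("all units share one temperature; slope is unidentified")
        slopes = ((y - y.mean(axis=1, keepdims=True)) * xc).sum(axis=1) / denom

    # point fit on unit means for r^2
    ybar = np.array([lj.mean() for lj in ln])
    xc = x - x.mean()
    denom = float((xc ** 2).sum())
    b = float((ybar - ybar.mean()) @ xc / denom)
    fitted = ybar.mean() + b * xc
    ss_res = float(((ybar - fitted) ** 2).sum())
    ss_tot = float(((ybar - ybar.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    dist = BootstrapDistribution(slopes, seed)
    return ActivationEnergyEstimate(
        E_mean=dist.mean,
        ci_low=dist.ci_low,
        ci_high=dist.ci_high,
        r2=r2,
        n_boot=dist.n_boot,
        scope=scope,
        quantity=quantity,
        slopes=dist,
        seed=seed,
    )


def within_stream_E(
    values: Sequence,
    x,
    stream_id: str,
    n_boot: int = 10_000,
    seed: int | None = None,
    quantity: str = "P",
) -> ActivationEnergyEstimate:
    """Intra-annual apparent activation energy for one stream.

    Same estimator as :func:`fit_activation_energy`, applied to sampling
    intervals within a single stream (daily production against mean interval
    temperature).  Requires at least four intervals.
    """
    if len(values) < 4:
        raise ValueError(
            f"stream {stream_id}: need >= 4 intervals for a within-stream slope"
        )
    return fit_activation_energy(
        values, x, n_boot=n_boot, seed=seed, scope=f"within:{stream_id}", quantity=quantity
    )


def percent_change_per_degree(E: float, t_ref_c: float = T_REF_C) -> float:
    """Fractional change of a quantity per +1 °C implied by activation energy E.

    Evaluates ``exp(E * [x(T_ref+1) - x(T_ref)]) - 1`` at the reference
    temperature; e.g. E = 0.67 eV at 15 °C gives about +9.8 % per °C.
    """
    dx = standardize_temperature(t_ref_c + 1.0, t_ref_c)
    return float(np.exp(E * dx) - 1.0)


def elasticity_percent(slope: float, fraction: float = 0.10) -> float:
    """Fractional response to a fractional resource increase on a log-log slope.

    A log-log slope ``b`` implies a ``(1+fraction)^b - 1`` change in the
    response for a ``fraction`` increase in the predictor (e.g. slope 1.2 and
    a 10 % chlorophyll increase give about +12 %).
    """
    return float((1.0 + fraction) ** slope - 1.0)
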