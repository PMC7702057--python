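"""Individual mass-specific growth rates and the mass-temperature growth model.

Two field designs feed this module.  *Chamber* incubations follow marked
groups of individuals over 7-15 days, giving paired initial/final mean
masses.  *Size-frequency* series follow synchronously developing cohorts:
the body-size distribution of a taxon on consecutive dates is resampled with
replacement to propagate measurement uncertainty into the growth rate, with
the biological constraint that a cohort does not shrink.

All growth rates are instantaneous (exponential) rates

    g = ln(W_{t+dt} / W_t) / dt        [d^-1]

and the community-level growth model is the log-linear metabolic form

    ln g = ln g0 + a * ln M + E_ind * x(T)

with body mass M (mg AFDM), standardised Boltzmann temperature x and an
apparent activation energy E_ind (eV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bootstrap import BootstrapDistribution
from .scaling import standardize_temperature

__all__ = [
    "GrowthModel",
    "NoValidCohortError",
    "instantaneous_growth",
    "bootstrap_cohort_growth",
    "fit_growth_model",
    "fit_stream_growth_models",
    "predict_growth",
    "sample_predicted_growth",
]


class NoValidCohortError(RuntimeError):
    """Raised when resampling cannot produce a growing cohort."""


def instantaneous_growth(w_t, w_t_dt, dt_days):
    """Instantaneous growth rate ``ln(W_{t+dt}/W_t) / dt`` in d^-1.

    Negative rates are legitimate for chamber incubations (individuals can
    lose mass); masses and the interval must be strictly positive.
    """
    w_t = np.asarray(w_t, dtype=float)
    w_t_dt = np.asarray(w_t_dt, dtype=float)
    dt = np.asarray(dt_days, dtype=float)
    if np.any(w_t <= 0) or np.any(w_t_dt <= 0):
        raise ValueError("masses must be strictly positive")
    if np.any(dt <= 0):
        raise ValueError("interval length must be strictly positive")
    g = np.log(w_t_dt / w_t) / dt
    return float(g) if g.ndim == 0 else g


def bootstrap_cohort_growth(
    masses_t,
    masses_t_dt,
    dt_days: float,
    n_boot: int = 500,
    seed: int | None = None,
    resample_size: tuple[int, int] | None = None,
    max_attempts: int = 1000,
) -> BootstrapDistribution:
    """Bootstrap a cohort growth rate from two size-frequency distributions.

    Each replicate resamples both dates' individual masses with replacement
    (sample sizes default to the observed counts), takes the mean mass on
    each date, and computes the instantaneous growth rate.  Replicates where
    the resampled final mean does not exceed the initial mean are rejected
    and both dates are redrawn — a growing cohort cannot have negative
    growth — up to ``max_attempts`` times per replicate.

    Parameters
    ----------
    masses_t, masses_t_dt
        Individual body masses (mg AFDM) on the earlier and later date.
    resample_size
        Optional (n_t, n_t_dt) override of the per-date resample sizes.

    Returns
    -------
    BootstrapDistribution of strictly positive growth rates (d^-1).

    Raises
    ------
    NoValidCohortError
        If a replicate cannot satisfy the growth constraint within
        ``max_attempts`` redraws (e.g. the final distribution sits entirely
        below the initial one).
    """
    m0 = np.sort(np.asarray(masses_t, dtype=float))
    m1 = np.sort(np.asarray(masses_t_dt, dtype=float))
    if m0.size == 0 or m1.size == 0:
        raise ValueError("both size-frequency distributions must be non-empty")
    if np.any(m0 <= 0) or np.any(m1 <= 0):
        raise ValueError("masses must be strictly positive")
    if dt_days <= 0:
        raise ValueError("interval length must be strictly positive")
    n0, n1 = (m0.size, m1.size) if resample_size is None else resample_size

    rng = np.random.default_rng(seed)
    g = np.empty(n_boot)
    for i in range(n_boot):
        for _ in range(max_attempts):
            w0 = m0[rng.integers(0, m0.size, size=n0)].mean()
            w1 = m1[rng.integers(0, m1.size, size=n1)].mean()
            if w1 > w0:
                g[i] = np.log(w1 / w0) / dt_days
                break
        else:
            raise NoValidCohortError(
                "could not resample a growing cohort "
                f"(max {max_attempts} attempts); check cohort direction"
            )
    return BootstrapDistribution(g, seed)


@dataclass(frozen=True)
class GrowthModel:
    """Fitted log-linear mass-temperature growth model.

    ``intercept`` is ln g at M = 1 mg and the reference temperature; ``a``
    is the dimensionless mass exponent; ``E_ind`` the apparent activation
    energy of growth (eV).  ``cov`` is the coefficient covariance in the
    order (intercept, a, E_ind).
    """

    intercept: float
    a: float
    E_ind: float
    cov: np.ndarray
    r2: float
    scope: str
    n_used: int
    n_excluded_nonpositive: int
    t_ref_c: float = 15.0

    def conf_int(self, alpha: float = 0.05) -> dict:
        from scipy import stats

        se = np.sqrt(np.diag(self.cov))
        dof = max(self.n_used - 3, 1)
        tq = stats.t.ppf(1 - alpha / 2, dof)
        names = ("intercept", "a", "E_ind")
        est = (self.intercept, self.a, self.E_ind)
        return {n: (e - tq * s, e + tq * s) for n, e, s in zip(names, est, se)}


def fit_growth_model(
    observations: pd.DataFrame,
    scope: str = "global",
    t_ref_c: float = 15.0,
) -> GrowthModel:
    """OLS fit of ln g on ln M and standardised Boltzmann temperature.

    Parameters
    ----------
    observations
        Table with columns ``W_t_mg``, ``W_t_dt_mg``, ``dt_days``,
        ``temp_C``.  Rows whose growth rate is non-positive cannot enter the
        log-linear fit; they are excluded and counted in the result.
    scope
        Label recorded on the model ("global" or a stream id).

    Raises
    ------
    ValueError
        Fewer than three usable observations, or a rank-deficient design
        (e.g. a single temperature, making E unidentifiable).
    """
    req = {"W_t_mg", "W_t_dt_mg", "dt_days", "temp_C"}
    missing = req - set(observations.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    g = instantaneous_growth(
        observations["W_t_mg"].to_numpy(),
        observations["W_t_dt_mg"].to_numpy(),
        observations["dt_days"].to_numpy(),
    )
    g = np.atleast_1d(g)
    keep = g > 0
    n_excluded = int((~keep).sum())
    if keep.sum() < 3:
        raise ValueError(
            f"need >= 3 observations with positive growth, got {int(keep.sum())}"
        )
    # initial mass is the size covariate: it is what is known at the start
    # of an interval when the model is used predictively
    m = observations["W_t_mg"].to_numpy()[keep]
    x = standardize_temperature(observations["temp_C"].to_numpy()[keep], t_ref_c)
    X = np.column_stack([np.ones(keep.sum()), np.log(m), np.atleast_1d(x)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(
            "rank-deficient design: mass and temperature do not vary "
            "independently (collinear or constant regressors)"
        )
    res = sm.OLS(np.log(g[keep]), X).fit()
    return GrowthModel(
        intercept=float(res.params[0]),
        a=float(res.params[1]),
        E_ind=float(res.params[2]),
        cov=np.asarray(res.cov_params()),
        r2=float(res.rsquared),
        scope=scope,
        n_used=int(keep.sum()),
        n_excluded_nonpositive=n_excluded,
        t_ref_c=t_ref_c,
    )


def fit_stream_growth_models(
    observations: pd.DataFrame, t_ref_c: float = 15.0
) -> dict[str, GrowthModel]:
    """Stream-specific growth models, for taxa without direct measurements.

    Falls back to nothing: streams whose own data cannot support a fit
    (too few observations or a single temperature) are simply absent from
    the result, and callers should use the global model instead.
    """
    models: dict[str, GrowthModel] = {}
    for stream, sub in observations.groupby("stream_id"):
        try:
            models[str(stream)] = fit_growth_model(sub, scope=str(stream), t_ref_c=t_ref_c)
        except ValueError:
            continue
    return models


def predict_growth(model: GrowthModel, mass_mg, temp_c):
    """Predicted growth rate (d^-1) at a body mass and temperature."""
    mass_mg = np.asarray(mass_mg, dtype=float)
    if np.any(mass_mg <= 0):
        raise ValueError("mass must be strictly positive")
    x = standardize_temperature(temp_c, model.t_ref_c)
    g = np.exp(model.intercept + model.a * np.log(mass_mg) + model.E_ind * np.asarray(x))
    return float(g) if g.ndim == 0 else g


def sample_predicted_growth(
    model: GrowthModel,
    mass_mg: float,
    temp_c: float,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw growth-rate replicates from the model's coefficient uncertainty.

    Coefficients are sampled from their asymptotic multivariate normal
    distribution, so predicted growth carries fit uncertainty into the
    production bootstrap just as resampled measured rates do.
    """
    if mass_mg <= 0:
        raise ValueError("mass must be strictly positive")
    mean = np.array([model.intercept, model.a, model.E_ind])
    draws = rng.multivariate_normal(mean, model.cov, size=n_boot, method="cholesky")
    x = standardize_temperature(temp_c, model.t_ref_c)
    ln_g = draws[:, 0] + draws[:, 1] * np.log(mass_mg) + draws[:, 2] * x
    return np.exp(ln_g)
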