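"""Resource supply and the temperature-vs-resource model competition.

Chlorophyll *a* standing stock (mg m^-2) proxies resource supply among
streams; within streams, where the chlorophyll-production link weakens
seasonally, light and temperature enter alongside it.  The module asks the
study's central question: once resource supply is in the model, does
temperature still explain secondary production?

Two model competitions are run, both ranked by AICc and both repeated on
resampled bootstrap estimates so that selection is robust to estimation
uncertainty:

* among streams — OLS candidates up to ``ln P ~ temp * ln chla`` on annual
  values; the *resource-corrected* temperature dependence is the
  temperature coefficient of the additive temp + chla model;
* within streams — linear mixed models with random stream intercepts and
  fixed-effect candidates up to ``temp * ln chla * ln light`` on sampling
  intervals; fixed structures are compared with maximum likelihood and the
  modal winner refit with REML.

The within-stream temperature dependence of production is corrected by
subtracting the temperature dependence of gross primary production (GPP),
itself estimated from a log-linear model of GPP on temperature, light and
chlorophyll.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bootstrap import BootstrapDistribution
from .scaling import fit_activation_energy, ActivationEnergyEstimate

__all__ = [
    "SelectionResult",
    "MixedModelFit",
    "GPPModel",
    "annual_chla_bootstrap",
    "fit_chla_temperature",
    "aicc",
    "among_stream_selection",
    "within_stream_selection",
    "fit_gpp_model",
    "resource_correct_within",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# chlorophyll a
# ---------------------------------------------------------------------------

def annual_chla_bootstrap(
    samples: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict[str, BootstrapDistribution]:
    """Bootstrap annual mean chlorophyll a per stream (mg m^-2).

    Each replicate resamples sampling dates with replacement, then stones
    within each drawn date, and averages — a two-stage bootstrap matching
    the sampling hierarchy (dates within streams, stones within dates).

    Parameters
    ----------
    samples
        Columns ``stream_id``, ``date``, ``stone_id``, ``chla_mg_m2``.
    """
    req = {"stream_id", "date", "chla_mg_m2"}
    if not req <= set(samples.columns):
        raise ValueError(f"chla table missing columns: {sorted(req - set(samples.columns))}")
    if np.any(samples["chla_mg_m2"].to_numpy() < 0):
        raise ValueError("negative chlorophyll a value")
    rng = np.random.default_rng(seed)
    out: dict[str, BootstrapDistribution] = {}
    for stream, sub in samples.groupby("stream_id", sort=True):
        by_date = [g["chla_mg_m2"].to_numpy(dtype=float) for _, g in sub.groupby("date", sort=True)]
        n_dates = len(by_date)
        if n_dates == 0:
            raise ValueError(f"stream {stream!r} has no chlorophyll samples")
        if n_dates < 3:
            raise ValueError(f"stream {stream!r}: need >= 3 sampling dates, got {n_dates}")
        # stone-level resampled means, one per date per replicate
        date_means = np.empty((n_boot, n_dates))
        for d, stones in enumerate(by_date):
            idx = rng.integers(0, stones.size, size=(n_boot, stones.size))
            date_means[:, d] = stones[idx].mean(axis=1)
        # date-level resampling
        didx = rng.integers(0, n_dates, size=(n_boot, n_dates))
        annual = np.take_along_axis(date_means, didx, axis=1).mean(axis=1)
        out[str(stream)] = BootstrapDistribution(annual, seed)
    return out


def fit_chla_temperature(
    annual_chla: dict[str, BootstrapDistribution] | list,
    x,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> ActivationEnergyEstimate:
    """Apparent activation energy of annual chlorophyll a among streams.

    Bootstrapped OLS of ln(annual chlorophyll) on standardised Boltzmann
    temperature; delegates to :func:`streamprod.scaling.fit_activation_energy`.
    """
    values = list(annual_chla.values()) if isinstance(annual_chla, dict) else list(annual_chla)
    return fit_activation_energy(
        values, x, n_boot=n_boot, seed=seed, scope="among", quantity="chla"
    )


# ---------------------------------------------------------------------------
# information criteria and batched OLS machinery
# ---------------------------------------------------------------------------

def aicc(loglik: float, k_params: int, n_obs: int) -> float:
    """Small-sample Akaike information criterion.

    ``AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)``; undefined when
    ``n <= k+1`` (the correction divides by zero or goes negative).
    """
    if n_obs <= k_params + 1:
        raise ValueError(
            f"AICc undefined: n_obs={n_obs} must exceed k_params+1={k_params + 1}"
        )
    return float(-2.0 * loglik + 2 * k_params + 2 * k_params * (k_params + 1) / (n_obs - k_params - 1))


def _aicc_or_inf(loglik: float, k: int, n: int) -> float:
    try:
        return aicc(loglik, k, n)
    except ValueError:
        return np.inf


def _batched_ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS over a batch of small problems: y (R,n), X (R,n,p) -> beta, rss."""
    xtx = np.einsum("rnp,rnq->rpq", X, X)
    xty = np.einsum("rnp,rn->rp", X, y)
    beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
    resid = y - np.einsum("rnp,rp->rn", X, beta)
    return beta, (resid ** 2).sum(axis=1)


def _gauss_loglik(rss: np.ndarray, n: int) -> np.ndarray:
    rss = np.maximum(rss, 1e-300)
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


@dataclass
class SelectionResult:
    """Outcome of a bootstrap-replicated AICc model competition."""

    frequencies: dict[str, float]
    winner: str
    n_rep: int
    seed: int | None
    coefficients: dict[str, BootstrapDistribution] = field(default_factory=dict)
    apparent_E: BootstrapDistribution | None = None
    corrected_E: BootstrapDistribution | None = None
    n_dropped: int = 0


# candidate fixed-effect structures; term symbols: t = standardised
# temperature, c = ln chla, l = ln light, products are interactions
_AMONG_CANDIDATES: list[tuple[str, list[str]]] = [
    ("null", []),
    ("temp", ["t"]),
    ("chla", ["c"]),
    ("temp+chla", ["t", "c"]),
    ("temp*chla", ["t", "c", "tc"]),
]

_WITHIN_CANDIDATES: list[tuple[str, list[str]]] = [
    ("null", []),
    ("temp", ["t"]),
    ("chla", ["c"]),
    ("light", ["l"]),
    ("temp+chla", ["t", "c"]),
    ("temp+light", ["t", "l"]),
    ("chla+light", ["c", "l"]),
    ("temp+chla+light", ["t", "c", "l"]),
    ("temp*chla", ["t", "c", "tc"]),
    ("temp*chla+light", ["t", "c", "l", "tc"]),
    ("temp*chla*light", ["t", "c", "l", "tc", "tl", "cl", "tcl"]),
]

_TERM_NAMES = {"t": "temp", "c": "ln_chla", "l": "ln_light",
               "tc": "temp:ln_chla", "tl": "temp:ln_light",
               "cl": "ln_chla:ln_light", "tcl": "temp:ln_chla:ln_light"}


def _design(terms: list[str], t: np.ndarray, c: np.ndarray, l: np.ndarray | None) -> np.ndarray:
    """Stack the design for a batch: t (n,), c (R,n), l (n,) -> X (R,n,p)."""
    R, n = c.shape
    cols = [np.ones((R, n))]
    lookup = {
        "t": np.broadcast_to(t, (R, n)),
        "c": c,
        "l": None if l is None else np.broadcast_to(l, (R, n)),
    }
    lookup["tc"] = lookup["t"] * c
    if l is not None:
        lookup["tl"] = lookup["t"] * lookup["l"]
        lookup["cl"] = c * lookup["l"]
        lookup["tcl"] = lookup["t"] * c * lookup["l"]
    for term in terms:
        cols.append(lookup[term])
    return np.stack(cols, axis=2)


def _draw_log_replicates(
    dists: list, n_rep: int, rng: np.random.Generator, what: str
) -> np.ndarray:
    """(n_rep, n_units) matrix of log-transformed inner bootstrap draws."""
    n = len(dists)
    out = np.empty((n_rep, n))
    for j, d in enumerate(dists):
        arr = d.replicates if isinstance(d, BootstrapDistribution) else np.atleast_1d(np.asarray(d, dtype=float))
        if np.any(arr <= 0):
            raise ValueError(f"non-positive {what} replicate in unit {j}")
        out[:, j] = np.log(arr[rng.integers(0, arr.size, size=n_rep)])
    return out


def among_stream_selection(
    annual_p: list,
    x,
    annual_chla: list,
    n_rep: int = 1000,
    seed: int | None = None,
) -> SelectionResult:
    """Temperature-vs-resource model competition for annual production.

    Candidates for ``ln P``: intercept-only, temperature-only, chlorophyll-
    only, additive, and full interaction.  Each of ``n_rep`` replicates
    draws one inner bootstrap estimate of annual P and annual chlorophyll
    per stream (temperature is a fixed covariate), fits all candidates by
    OLS and tallies the lowest AICc (ties go to the smaller model; a
    candidate whose AICc correction is undefined at this sample size is
    never selected).  The modal winner is refit on fresh resamples to give
    coefficient distributions; the additive model's temperature coefficient
    is the *resource-corrected* temperature dependence and the temp-only
    coefficient the *apparent* one.
    """
    x = np.asarray(x, dtype=float)
    n = len(annual_p)
    if n < 4:
        raise ValueError(f"need >= 4 streams for model selection, got {n}")
    if len(annual_chla) != n or x.size != n:
        raise ValueError("annual_p, annual_chla and x must align per stream")
    rng = np.random.default_rng(seed)
    lnp = _draw_log_replicates(annual_p, n_rep, rng, "production")
    lnc = _draw_log_replicates(annual_chla, n_rep, rng, "chlorophyll")

    names = [nm for nm, _ in _AMONG_CANDIDATES]
    aiccs = np.empty((n_rep, len(names)))
    for i, (nm, terms) in enumerate(_AMONG_CANDIDATES):
        X = _design(terms, x, lnc, None)
        k = X.shape[2] + 1  # + residual variance
        if n <= k + 1:
            aiccs[:, i] = np.inf
            continue
        _, rss = _batched_ols(lnp, X)
        aiccs[:, i] = -2.0 * _gauss_loglik(rss, n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    # candidates are ordered by increasing complexity; argmin is stable,
    # so ties break toward the smaller model
    win_idx = np.argmin(aiccs, axis=1)
    counts = np.bincount(win_idx, minlength=len(names))
    freqs = {nm: counts[i] / n_rep for i, nm in enumerate(names)}
    winner = names[int(np.argmax(counts))]

    # refit winner + reference models on fresh resamples for coefficients
    lnp2 = _draw_log_replicates(annual_p, n_rep, rng, "production")
    lnc2 = _draw_log_replicates(annual_chla, n_rep, rng, "chlorophyll")

    def _coef_draws(terms: list[str]) -> dict[str, BootstrapDistribution]:
        X = _design(terms, x, lnc2, None)
        beta, _ = _batched_ols(lnp2, X)
        cols = ["intercept"] + [_TERM_NAMES[tm] for tm in terms]
        return {cname: BootstrapDistribution(beta[:, j], seed) for j, cname in enumerate(cols)}

    winner_terms = dict(_AMONG_CANDIDATES)[winner]
    coefficients = _coef_draws(winner_terms)
    apparent = _coef_draws(["t"])["temp"]
    corrected = _coef_draws(["t", "c"])["temp"]
    return SelectionResult(
        frequencies=freqs,
        winner=winner,
        n_rep=n_rep,
        seed=seed,
        coefficients=coefficients,
        apparent_E=apparent,
        corrected_E=corrected,
    )


# ---------------------------------------------------------------------------
# within-stream mixed models
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    """REML summary of the winning within-stream mixed model."""

    model: str
    fixed_effects: dict[str, float]
    random_intercept_var: float
    resid_var: float
    n_obs: int
    n_groups: int
    method: str = "REML"


def log_with_floor(values, floor: float | None = None) -> np.ndarray:
    """Natural log with a floor for non-positive entries (e.g. polar-night light).

    The default floor is half the smallest positive value; applications of
    the floor are logged.
    """
    v = np.asarray(values, dtype=float)
    pos = v > 0
    if not np.any(pos):
        raise ValueError("no positive values to set a log floor from")
    f = floor if floor is not None else v[pos].min() / 2.0
    n_floored = int((~pos).sum())
    if n_floored:
        logger.info("log floor %.3g applied to %d non-positive values", f, n_floored)
    return np.log(np.where(pos, v, f))


@dataclass
class _MixedFit:
    llf: float
    fe_params: np.ndarray
    re_var: float
    resid_var: float
    boundary: bool = False


def _fit_mixed_ml(y, Xcols, groups, reml: bool) -> _MixedFit:
    """Random-intercept linear mixed model via the profiled likelihood.

    With a single random intercept the covariance is
    ``sigma^2 (I + lambda Z Z')`` and both the fixed effects and ``sigma^2``
    profile out, leaving a one-dimensional (RE)ML criterion in the variance
    ratio ``lambda = tau^2 / sigma^2``.  The GLS step is the classic
    partial demeaning ``y - theta_g * ybar_g`` with
    ``theta_g = 1 - 1/sqrt(1 + lambda m_g)`` per group of size ``m_g``,
    so each evaluation is a small least-squares solve.  The zero-variance
    boundary (``lambda = 0``, i.e. plain OLS) is always evaluated and
    returned when the profile prefers it, rather than failing on a singular
    information matrix there.

    Agrees with the full mixed-model machinery away from the boundary (see
    the test suite's cross-check) and is orders of magnitude faster, which
    matters when model selection is replicated over resampled datasets.
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones(y.size)] + Xcols)
    n, p = X.shape
    codes, _ = pd.factorize(np.asarray(groups))
    sizes = np.bincount(codes).astype(float)

    xbar = np.vstack([np.bincount(codes, X[:, j]) for j in range(p)]).T / sizes[:, None]
    ybar = np.bincount(codes, y) / sizes

    def criterion(lam: float) -> tuple[float, np.ndarray, float]:
        theta = 1.0 - 1.0 / np.sqrt(1.0 + lam * sizes)
        yt = y - theta[codes] * ybar[codes]
        Xt = X - theta[codes, None] * xbar[codes]
        beta, rss, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        rss = float(((yt - Xt @ beta) ** 2).sum())
        rss = max(rss, 1e-300)
        logdet_v = float(np.log1p(lam * sizes).sum())
        if reml:
            sig2 = rss / (n - p)
            sign, logdet_xvx = np.linalg.slogdet(Xt.T @ Xt)
            m2ll = (n - p) * np.log(2 * np.pi * sig2) + logdet_v + logdet_xvx + (n - p)
        else:
            sig2 = rss / n
            m2ll = n * np.log(2 * np.pi * sig2) + logdet_v + n
        return m2ll, beta, sig2

    from scipy import optimize as _opt

    # profile over log-lambda; include the OLS boundary explicitly
    obj = lambda u: criterion(np.exp(u))[0]
    res = _opt.minimize_scalar(obj, bounds=(-10.0, 10.0), method="bounded",
                               options={"xatol": 1e-6})
    m2ll_b, beta_b, sig2_b = criterion(0.0)
    lam_hat = float(np.exp(res.x))
    m2ll_i, beta_i, sig2_i = criterion(lam_hat)
    if m2ll_b <= m2ll_i:
        return _MixedFit(llf=-0.5 * m2ll_b, fe_params=beta_b, re_var=0.0,
                         resid_var=sig2_b, boundary=True)
    return _MixedFit(llf=-0.5 * m2ll_i, fe_params=beta_i,
                     re_var=lam_hat * sig2_i, resid_var=sig2_i)


def within_stream_selection(
    p_daily: list,
    x,
    chla: list,
    light,
    streams,
    n_rep: int = 1000,
    seed: int | None = None,
    max_dropped_frac: float = 0.10,
) -> tuple[SelectionResult, MixedModelFit | None]:
    """Mixed-model competition for seasonal (within-stream) production.

    One row per sampling interval: daily production and chlorophyll carry
    bootstrap distributions, temperature (standardised) and light are fixed
    interval means, and every candidate includes a random intercept per
    stream.  Fixed structures — all sub-models of temp * ln chla * ln light
    — are compared by ML + AICc on each of ``n_rep`` resampled datasets; the
    modal winner is refit ``n_rep`` times by REML on fresh resamples, and
    its temperature coefficient distribution is the within-stream apparent
    temperature dependence of production.

    Returns the selection result (with ``coefficients['temp']`` as the
    E_p_within distribution when temperature is in the winner) and a REML
    fit summary on the unresampled means.

    Replicates whose mixed-model fit is singular are dropped and counted;
    more than ``max_dropped_frac`` dropped replicates aborts.
    """
    x = np.asarray(x, dtype=float)
    streams = np.asarray(streams)
    light = np.asarray(light, dtype=float)
    n = len(p_daily)
    if len(chla) != n or x.size != n or light.size != n or streams.size != n:
        raise ValueError("per-interval inputs must align")
    uniq = np.unique(streams)
    if uniq.size < 2:
        raise ValueError("need >= 2 streams for a random stream intercept")
    for s in uniq:
        if (streams == s).sum() < 4:
            raise ValueError(f"stream {s!r} has < 4 intervals")
    rng = np.random.default_rng(seed)
    ln_light = log_with_floor(light)

    lnp = _draw_log_replicates(p_daily, n_rep, rng, "production")
    lnc = _draw_log_replicates(chla, n_rep, rng, "chlorophyll")

    def _cols(terms, c_row):
        lookup = {"t": x, "c": c_row, "l": ln_light}
        lookup["tc"] = x * c_row
        lookup["tl"] = x * ln_light
        lookup["cl"] = c_row * ln_light
        lookup["tcl"] = x * c_row * ln_light
        return [lookup[tm] for tm in terms]

    names = [nm for nm, _ in _WITHIN_CANDIDATES]
    counts = dict.fromkeys(names, 0)
    dropped = 0
    for r in range(n_rep):
        best_name, best_aicc, best_k = None, np.inf, np.inf
        try:
            for nm, terms in _WITHIN_CANDIDATES:
                k = len(terms) + 1 + 2  # fixed effects + RE variance + residual
                if n <= k + 1:
                    continue
                res = _fit_mixed_ml(lnp[r], _cols(terms, lnc[r]), streams, reml=False)
                a = _aicc_or_inf(res.llf, k, n)
                if a < best_aicc - 1e-12 or (abs(a - best_aicc) <= 1e-12 and k < best_k):
                    best_name, best_aicc, best_k = nm, a, k
        except (np.linalg.LinAlgError, ValueError):
            dropped += 1
            continue
        if best_name is None:
            dropped += 1
            continue
        counts[best_name] += 1
    if dropped > max_dropped_frac * n_rep:
        raise RuntimeError(
            f"{dropped}/{n_rep} selection replicates dropped (singular fits)"
        )
    n_ok = n_rep - dropped
    freqs = {nm: counts[nm] / n_ok for nm in names}
    winner = max(names, key=lambda nm: counts[nm])
    winner_terms = dict(_WITHIN_CANDIDATES)[winner]

    # REML refits of the winner on fresh resamples
    lnp2 = _draw_log_replicates(p_daily, n_rep, rng, "production")
    lnc2 = _draw_log_replicates(chla, n_rep, rng, "chlorophyll")
    coef_names = ["intercept"] + [_TERM_NAMES[tm] for tm in winner_terms]
    draws = {cn: [] for cn in coef_names}
    refit_dropped = 0
    for r in range(n_rep):
        try:
            res = _fit_mixed_ml(lnp2[r], _cols(winner_terms, lnc2[r]), streams, reml=True)
        except (np.linalg.LinAlgError, ValueError):
            refit_dropped += 1
            continue
        for j, cn in enumerate(coef_names):
            draws[cn].append(float(res.fe_params[j]))
    if refit_dropped > max_dropped_frac * n_rep:
        raise RuntimeError(f"{refit_dropped}/{n_rep} REML refits dropped")
    coefficients = {cn: BootstrapDistribution(np.array(v), seed) for cn, v in draws.items()}

    # point REML fit on unresampled means for reporting
    mean_lnp = np.log([np.mean(np.atleast_1d(getattr(d, "replicates", d))) for d in p_daily])
    mean_lnc = np.log([np.mean(np.atleast_1d(getattr(d, "replicates", d))) for d in chla])
    fit_summary = None
    try:
        res = _fit_mixed_ml(mean_lnp, _cols(winner_terms, np.asarray(mean_lnc)), streams, reml=True)
        fit_summary = MixedModelFit(
            model=winner,
            fixed_effects={cn: float(res.fe_params[j]) for j, cn in enumerate(coef_names)},
            random_intercept_var=res.re_var,
            resid_var=res.resid_var,
            n_obs=n,
            n_groups=int(uniq.size),
        )
    except (np.linalg.LinAlgError, ValueError):
        pass

    result = SelectionResult(
        frequencies=freqs,
        winner=winner,
        n_rep=n_rep,
        seed=seed,
        coefficients=coefficients,
        apparent_E=coefficients.get("temp"),
        n_dropped=dropped + refit_dropped,
    )
    return result, fit_summary


# ---------------------------------------------------------------------------
# GPP and resource correction
# ---------------------------------------------------------------------------

@dataclass
class GPPModel:
    """Log-linear GPP model: ln GPP ~ x + ln light + ln chla."""

    coefficients: dict[str, float]
    resid_sd: float
    r2: float
    n_obs: int
    E_gpp: BootstrapDistribution

    @property
    def E_gpp_mean(self) -> float:
        return self.E_gpp.mean


def fit_gpp_model(
    gpp,
    chla,
    light,
    x,
    n_boot: int = 1000,
    seed: int | None = None,
) -> GPPModel:
    """Within-stream temperature dependence of gross primary production.

    Fits ``ln GPP = b0 + E_gpp * x + b_l * ln light + b_c * ln chla`` by OLS
    on monthly observations and bootstraps the rows (case resampling) for
    the uncertainty of the temperature coefficient.
    """
    gpp = np.asarray(gpp, dtype=float)
    if np.any(gpp <= 0):
        raise ValueError("non-positive GPP value")
    if gpp.size < 8:
        raise ValueError(f"need >= 8 monthly observations, got {gpp.size}")
    x = np.asarray(x, dtype=float)
    ln_light = log_with_floor(light)
    ln_chla = log_with_floor(chla)
    X = np.column_stack([np.ones(gpp.size), x, ln_light, ln_chla])
    y = np.log(gpp)
    res = sm.OLS(y, X).fit()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, gpp.size, size=(n_boot, gpp.size))
    Xb = X[idx]
    yb = y[idx]
    beta, _ = _batched_ols(yb, Xb)
    names = ["intercept", "temp", "ln_light", "ln_chla"]
    return GPPModel(
        coefficients={nm: float(res.params[j]) for j, nm in enumerate(names)},
        resid_sd=float(np.sqrt(res.scale)),
        r2=float(res.rsquared),
        n_obs=int(gpp.size),
        E_gpp=BootstrapDistribution(beta[:, 1], seed),
    )


def resource_correct_within(
    ep_dist: BootstrapDistribution,
    egpp_dist: BootstrapDistribution,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> ActivationEnergyEstimate:
    """Resource-corrected within-stream temperature dependence, Ep - Egpp.

    Draws independently from the two coefficient distributions and reports
    the mean difference with percentile confidence bounds: the temperature
    dependence of consumer production left over after removing that of its
    basal resource flux.
    """
    rng = np.random.default_rng(seed)
    a = ep_dist.replicates[rng.integers(0, ep_dist.n_boot, size=n_boot)]
    b = egpp_dist.replicates[rng.integers(0, egpp_dist.n_boot, size=n_boot)]
    diff = BootstrapDistribution(a - b, seed)
    return ActivationEnergyEstimate(
        E_mean=diff.mean,
        ci_low=diff.ci_low,
        ci_high=diff.ci_high,
        r2=float("nan"),
        n_boot=n_boot,
        scope="within",
        quantity="P_resource_corrected",
        slopes=diff,
        seed=seed,
    )
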