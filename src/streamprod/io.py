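"""Tabular readers/writers, study configuration and the full pipeline.

All exchange formats are plain CSV with documented headers; dates are
ISO-8601, masses mg AFDM, areas m^2, temperatures °C.  The pipeline is
deterministic given (inputs, seed): every stage derives its own seed from
the global one, and each output table carries the seed and bootstrap sizes
that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import production as prod
from . import resources as res
from .bootstrap import BootstrapDistribution
from .growth import (
    GrowthModel,
    fit_growth_model,
    fit_stream_growth_models,
    instantaneous_growth,
    sample_predicted_growth,
)
from .scaling import (
    fit_activation_energy,
    mass_correct,
    standardize_temperature,
    weighted_community_mass,
    within_stream_E,
)

__all__ = [
    "SchemaError",
    "StudyConfig",
    "PipelineResult",
    "read_samples",
    "read_growth",
    "read_chla",
    "read_environment",
    "derive_seed",
    "production_stage",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

_ALLOWED_SPLITS = {1.0, 0.5, 0.25, 0.125, 0.0625}


class SchemaError(ValueError):
    """An input table violates its schema; the message names the rows."""


def derive_seed(seed: int, *tags: int) -> int:
    """A reproducible child seed (< 2^31) for one pipeline stage."""
    state = np.random.SeedSequence([int(seed), *[int(t) for t in tags]]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: set[str], optional: set[str], what: str) -> None:
    cols = set(df.columns)
    missing = required - cols
    unknown = cols - required - optional
    if missing:
        raise SchemaError(f"{what}: missing columns {sorted(missing)}")
    if unknown:
        raise SchemaError(f"{what}: unknown columns {sorted(unknown)}")


def _check_dates(df: pd.DataFrame, col: str, what: str) -> None:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    bad = df.index[parsed.isna()].tolist()
    if bad:
        raise SchemaError(f"{what}: non-ISO dates in column {col!r}, rows {bad[:10]}")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and validate a size-class sample table (samples.csv).

    Columns: stream_id, date, replicate, taxon_id, length_bin_mm, count,
    split_fraction, area_m2, mass_mg.  Adds ``density_m2``, the sub-sample-
    expanded density count / split_fraction / area.
    """
    df = pd.read_csv(path)
    req = {"stream_id", "date", "replicate", "taxon_id", "length_bin_mm",
           "count", "split_fraction", "area_m2", "mass_mg"}
    _check_columns(df, req, set(), "samples")
    _check_dates(df, "date", "samples")
    neg = df.index[df["count"] < 0].tolist()
    if neg:
        raise SchemaError(f"samples: negative counts in rows {neg[:10]}")
    badsplit = df.index[~df["split_fraction"].isin(_ALLOWED_SPLITS)].tolist()
    if badsplit:
        raise SchemaError(
            f"samples: split_fraction outside {{1, 1/2, ..., 1/16}} in rows {badsplit[:10]}"
        )
    if (df["area_m2"] <= 0).any():
        raise SchemaError("samples: non-positive sample area")
    if (df["mass_mg"] <= 0).any():
        raise SchemaError("samples: non-positive body mass")
    df = df.copy()
    df["density_m2"] = df["count"] / df["split_fraction"] / df["area_m2"]
    return df


def read_growth(path: str | Path) -> pd.DataFrame:
    """Read and validate a growth-observation table (growth.csv)."""
    df = pd.read_csv(path)
    req = {"taxon_id", "stream_id", "method", "date_t", "date_t_dt",
           "W_t_mg", "W_t_dt_mg", "dt_days", "temp_C"}
    _check_columns(df, req, set(), "growth")
    _check_dates(df, "date_t", "growth")
    _check_dates(df, "date_t_dt", "growth")
    bad = df.index[(df["W_t_mg"] <= 0) | (df["W_t_dt_mg"] <= 0) | (df["dt_days"] <= 0)].tolist()
    if bad:
        raise SchemaError(f"growth: non-positive mass or duration in rows {bad[:10]}")
    return df


def read_chla(path: str | Path) -> pd.DataFrame:
    """Read and validate a chlorophyll a sample table (chla.csv)."""
    df = pd.read_csv(path)
    req = {"stream_id", "date", "stone_id", "chla_mg_m2"}
    _check_columns(df, req, set(), "chla")
    _check_dates(df, "date", "chla")
    neg = df.index[df["chla_mg_m2"] < 0].tolist()
    if neg:
        raise SchemaError(f"chla: negative values in rows {neg[:10]}")
    return df


def read_environment(path: str | Path) -> pd.DataFrame:
    """Read and validate a daily temperature/light table (environment.csv)."""
    df = pd.read_csv(path)
    req = {"stream_id", "date", "temp_C", "light"}
    _check_columns(df, req, {"day"}, "environment")
    _check_dates(df, "date", "environment")
    if (df["temp_C"] < -273.15).any():
        raise SchemaError("environment: temperature below absolute zero")
    return df


def read_gpp(path: str | Path) -> pd.DataFrame:
    """Read and validate a monthly GPP table (gpp.csv)."""
    df = pd.read_csv(path)
    req = {"stream_id", "date", "gpp", "light", "temp_C", "chla"}
    _check_columns(df, req, set(), "gpp")
    _check_dates(df, "date", "gpp")
    if (df["gpp"] <= 0).any():
        raise SchemaError("gpp: non-positive GPP values")
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Configuration of a full pipeline run.

    Bootstrap sizes default to the field's conventional choices: 500 for
    cohort growth, 1000 for production, 10 000 for activation-energy
    slopes and 1000 for model-selection replication.
    """

    input_dir: str
    out_dir: str = "results"
    seed: int = 1
    t_ref_c: float = 15.0
    n_boot_growth: int = 500
    n_boot_production: int = 1000
    n_boot_slopes: int = 10_000
    n_rep_selection: int = 1000
    unit_resample: bool = False
    mass_correction_direction: str = "remove"
    run_within_selection: bool = True
    growth_assignment: str = "model"   # or "measured": pooled measured rates
    min_measured_growth: int = 10

    def __post_init__(self) -> None:
        for nm in ("n_boot_growth", "n_boot_production", "n_boot_slopes", "n_rep_selection"):
            if getattr(self, nm) < 100:
                raise ValueError(f"{nm} must be >= 100")
        if self.growth_assignment not in ("model", "measured"):
            raise ValueError("growth_assignment must be 'model' or 'measured'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """In-memory results of a full run (also written as CSV/JSON)."""

    config: StudyConfig
    growth_model: GrowthModel
    stream_growth_models: dict[str, GrowthModel]
    stream_x: dict[str, float]
    interval_production: list
    annual_production: dict[str, BootstrapDistribution]     # g AFDM m^-2 y^-1
    annual_biomass: dict[str, BootstrapDistribution]        # mg AFDM m^-2
    pb: dict[str, BootstrapDistribution]                    # y^-1
    community_mass: dict[str, np.ndarray]
    activation_energies: list
    annual_chla: dict[str, BootstrapDistribution]
    among_selection: res.SelectionResult | None = None
    within_selection: res.SelectionResult | None = None
    within_mixed_fit: res.MixedModelFit | None = None
    gpp_model: res.GPPModel | None = None
    corrected_within: object = None
    manifest: dict = field(default_factory=dict)


def _growth_replicates_for_taxon(
    taxon: str,
    stream: str,
    mass_mg: float,
    temp_c: float,
    growth_df: pd.DataFrame,
    models: dict[str, GrowthModel],
    global_model: GrowthModel,
    n_boot: int,
    rng: np.random.Generator,
    min_measured: int,
    assignment: str = "model",
) -> np.ndarray:
    """Growth-rate replicates for one taxon x size class x interval.

    The default assignment predicts from the stream-specific (falling back
    to global) mass-temperature growth model with coefficient-uncertainty
    draws: size classes need size-specific rates, and pooled raw rates
    ignore the strong mass dependence of growth.  ``assignment="measured"``
    resamples the taxon's own pooled measured rates where at least
    ``min_measured`` positive observations exist in the stream.
    """
    sub = growth_df[(growth_df["taxon_id"] == taxon) & (growth_df["stream_id"] == stream)]
    if assignment == "measured" and len(sub) >= min_measured:
        g = instantaneous_growth(
            sub["W_t_mg"].to_numpy(), sub["W_t_dt_mg"].to_numpy(), sub["dt_days"].to_numpy()
        )
        g = np.atleast_1d(g)
        g = g[g > 0]
        if g.size >= min_measured:
            return g[rng.integers(0, g.size, size=n_boot)]
    model = models.get(stream, global_model)
    return sample_predicted_growth(model, mass_mg, temp_c, n_boot, rng)



def production_stage(
    samples: pd.DataFrame,
    growth_df: pd.DataFrame,
    env: pd.DataFrame,
    *,
    n_boot: int = 1000,
    seed: int = 1,
    t_ref_c: float = 15.0,
    growth_assignment: str = "model",
    min_measured_growth: int = 10,
    mass_correction_direction: str = "remove",
    global_model: GrowthModel | None = None,
    stream_models: dict[str, GrowthModel] | None = None,
) -> dict:
    """Bootstrap biomass, production and derived annual quantities.

    The reusable core of the pipeline: per stream it bootstraps per-date
    biomass from the replicate field samples, pairs it with growth-rate
    replicates per size class and interval, aggregates to community,
    annual production, annual mean biomass, P:B, and mass-corrected
    quantities.  Returns a dict of results keyed by quantity; streams are
    processed in sorted order and all randomness derives from ``seed``.
    """
    if global_model is None:
        global_model = fit_growth_model(growth_df, scope="global", t_ref_c=t_ref_c)
    if stream_models is None:
        stream_models = fit_stream_growth_models(growth_df, t_ref_c=t_ref_c)
    if "density_m2" not in samples.columns:
        samples = samples.assign(
            density_m2=samples["count"] / samples["split_fraction"] / samples["area_m2"]
        )
    env = env.copy()
    env["_d"] = pd.to_datetime(env["date"])
    streams = sorted(samples["stream_id"].unique())
    stream_x = {
        s: float(standardize_temperature(
            env.loc[env["stream_id"] == s, "temp_C"].mean(), t_ref_c))
        for s in streams
    }

    interval_results: list[prod.IntervalProduction] = []
    annual_p: dict[str, BootstrapDistribution] = {}
    annual_b: dict[str, BootstrapDistribution] = {}
    pb: dict[str, BootstrapDistribution] = {}
    mc: dict[str, np.ndarray] = {}
    b_corr: dict[str, BootstrapDistribution] = {}
    pb_corr: dict[str, BootstrapDistribution] = {}
    within_rows: dict[str, dict] = {}

    for s_idx, stream in enumerate(streams):
        s_samples = samples[samples["stream_id"] == stream]
        s_env = env[env["stream_id"] == stream].set_index("_d")
        dates = sorted(s_samples["date"].unique())
        if len(dates) < 2:
            raise RuntimeError(f"production stage: stream {stream} has < 2 sampling dates")
        rng = np.random.default_rng(derive_seed(seed, 10, s_idx))

        # per-date biomass bootstrap, shared across taxa (spatial pairing)
        per_date = {
            d: prod.biomass_from_samples(s_samples, d, n_boot=n_boot, rng=rng)
            for d in dates
        }
        taxa = sorted(s_samples["taxon_id"].unique())
        mass_lookup = (
            s_samples.groupby(["taxon_id", "length_bin_mm"])["mass_mg"].first()
        )

        community_intervals = []
        pop_intervals: dict[str, list] = {t: [] for t in taxa}
        x_intervals, pd_intervals = [], []
        for d0, d1 in zip(dates, dates[1:]):
            dt = (pd.Timestamp(d1) - pd.Timestamp(d0)).days
            mask = (s_env.index >= pd.Timestamp(d0)) & (s_env.index <= pd.Timestamp(d1))
            t_mean = float(s_env.loc[mask, "temp_C"].mean())
            pops = []
            for taxon in taxa:
                bt = {k[1]: v for k, v in per_date[d0].items() if k[0] == taxon}
                btd = {k[1]: v for k, v in per_date[d1].items() if k[0] == taxon}
                classes = sorted(set(bt) | set(btd))
                if not classes:
                    continue
                g_src = {}
                for c in classes:
                    try:
                        g_src[c] = _growth_replicates_for_taxon(
                            taxon, stream, float(mass_lookup[(taxon, c)]), t_mean,
                            growth_df, stream_models, global_model,
                            n_boot, rng, min_measured_growth,
                            assignment=growth_assignment,
                        )
                    except KeyError as e:
                        raise RuntimeError(
                            f"production stage: no growth source for taxon "
                            f"{taxon!r} in stream {stream!r}"
                        ) from e
                pops.append(prod.bootstrap_population_production(
                    g_src, bt, btd, dt, stream_id=stream, taxon_id=taxon,
                    date_t=d0, date_t_dt=d1, n_boot=n_boot, rng=rng,
                ))
                pop_intervals[taxon].append(pops[-1])
            if not pops:
                raise RuntimeError(
                    f"production stage: empty community in stream {stream} "
                    f"interval {d0}..{d1}"
                )
            comm = prod.aggregate_community(pops)
            community_intervals.append(comm)
            interval_results.extend(pops + [comm])
            x_intervals.append(float(standardize_temperature(t_mean, t_ref_c)))
            pd_intervals.append(comm.P_daily)

        annual_p[stream] = prod.annual_production(community_intervals, unit="g")
        annual_b[stream] = prod.annual_mean_biomass(community_intervals)
        pb[stream] = prod.pb_ratio(annual_p[stream] * 1000.0, annual_b[stream])

        # biomass-weighted community body mass from annual per-taxon means
        taxa_used = [t for t in taxa if pop_intervals[t]]
        tb = np.stack([
            prod.annual_mean_biomass(pop_intervals[t]).replicates for t in taxa_used
        ])
        tm = np.array([
            s_samples[s_samples["taxon_id"] == t]
            .pipe(lambda d: np.average(d["mass_mg"], weights=d["density_m2"])
                  if d["density_m2"].sum() > 0 else d["mass_mg"].mean())
            for t in taxa_used
        ])
        mc[stream] = weighted_community_mass(tb, tm)
        b_corr[stream] = mass_correct(
            annual_b[stream], mc[stream], 0.25, direction=mass_correction_direction)
        pb_corr[stream] = mass_correct(
            pb[stream], mc[stream], -0.25, direction=mass_correction_direction)
        within_rows[stream] = {"P_daily": pd_intervals, "x": x_intervals}
    return {
        "streams": streams,
        "stream_x": stream_x,
        "env": env,
        "interval_production": interval_results,
        "annual_production": annual_p,
        "annual_biomass": annual_b,
        "pb": pb,
        "community_mass": mc,
        "b_corrected": b_corr,
        "pb_corrected": pb_corr,
        "within": within_rows,
        "global_model": global_model,
        "stream_models": stream_models,
    }


def run_pipeline(config: StudyConfig) -> PipelineResult:
    """Run the whole analysis and write the results directory.

    Stages: read and validate inputs; fit the mass-temperature growth
    model; bootstrap biomass and production per stream, interval and taxon;
    aggregate to community and annual scales; estimate apparent activation
    energies of production, mass-corrected biomass and P:B among streams
    and of daily production within streams; bootstrap annual chlorophyll
    and its temperature dependence; run the temperature-vs-resource model
    competitions; and, when GPP data are present, compute the resource-
    corrected within-stream temperature dependence.

    Any stage failure propagates with the stage and the offending stream or
    taxon in the message.  Outputs: production_intervals.csv,
    production_annual.csv, activation_energies.csv, selection_report.csv,
    corrected_E.csv and manifest.json under ``config.out_dir``.
    """
    inp = Path(config.input_dir)
    samples = read_samples(inp / "samples.csv")
    growth_df = read_growth(inp / "growth.csv")
    chla_df = read_chla(inp / "chla.csv")
    env = read_environment(inp / "environment.csv")
    gpp_path = inp / "gpp.csv"
    gpp_df = read_gpp(gpp_path) if gpp_path.exists() else None

    # --- growth stage ------------------------------------------------------
    try:
        global_model = fit_growth_model(growth_df, scope="global", t_ref_c=config.t_ref_c)
    except ValueError as e:
        raise RuntimeError(f"growth stage failed: {e}") from e
    stream_models = fit_stream_growth_models(growth_df, t_ref_c=config.t_ref_c)
    if global_model.n_excluded_nonpositive:
        logger.info(
            "growth: excluded %d non-positive rates from the log-linear fit",
            global_model.n_excluded_nonpositive,
        )

    stage = production_stage(
        samples, growth_df, env,
        n_boot=config.n_boot_production,
        seed=config.seed,
        t_ref_c=config.t_ref_c,
        growth_assignment=config.growth_assignment,
        min_measured_growth=config.min_measured_growth,
        mass_correction_direction=config.mass_correction_direction,
        global_model=global_model,
        stream_models=stream_models,
    )
    streams = stage["streams"]
    stream_x = stage["stream_x"]
    interval_results = stage["interval_production"]
    annual_p = stage["annual_production"]
    annual_b = stage["annual_biomass"]
    pb = stage["pb"]
    mc = stage["community_mass"]
    b_corr = stage["b_corrected"]
    pb_corr = stage["pb_corrected"]
    within_rows = stage["within"]
    env = stage["env"]

    # --- scaling stage -----------------------------------------------------
    slope_seed = derive_seed(config.seed, 20)
    x_arr = np.array([stream_x[s] for s in streams])
    energies = []
    try:
        e_p = fit_activation_energy(
            [annual_p[s] for s in streams], x_arr, n_boot=config.n_boot_slopes,
            seed=slope_seed, unit_resample=config.unit_resample, quantity="P")
        e_b = fit_activation_energy(
            [b_corr[s] for s in streams], x_arr, n_boot=config.n_boot_slopes,
            seed=slope_seed, unit_resample=config.unit_resample, quantity="B_corrected")
        e_pb = fit_activation_energy(
            [pb_corr[s] for s in streams], x_arr, n_boot=config.n_boot_slopes,
            seed=slope_seed, unit_resample=config.unit_resample, quantity="PB_corrected")
    except ValueError as e:
        raise RuntimeError(f"scaling stage failed: {e}") from e
    energies.extend([e_p, e_b, e_pb])
    for s in streams:
        rows = within_rows[s]
        if len(rows["P_daily"]) >= 4:
            energies.append(within_stream_E(
                rows["P_daily"], np.array(rows["x"]), s,
                n_boot=config.n_boot_slopes, seed=derive_seed(config.seed, 21),
            ))

    # --- resources stage ---------------------------------------------------
    try:
        annual_chla = res.annual_chla_bootstrap(
            chla_df, n_boot=config.n_boot_production, seed=derive_seed(config.seed, 30))
    except ValueError as e:
        raise RuntimeError(f"resources stage failed: {e}") from e
    chla_streams = [s for s in streams if s in annual_chla]
    if set(chla_streams) != set(streams):
        raise RuntimeError(
            "resources stage: chlorophyll missing for streams "
            f"{sorted(set(streams) - set(chla_streams))}"
        )
    e_chla = res.fit_chla_temperature(
        [annual_chla[s] for s in streams], x_arr,
        n_boot=config.n_boot_slopes, seed=derive_seed(config.seed, 31))
    energies.append(e_chla)

    among = res.among_stream_selection(
        [annual_p[s] for s in streams], x_arr, [annual_chla[s] for s in streams],
        n_rep=config.n_rep_selection, seed=derive_seed(config.seed, 32))

    within_sel = within_fit = None
    gpp_model = corrected_within = None
    if config.run_within_selection:
        chla_date_means = chla_df.groupby(["stream_id", "date"])["chla_mg_m2"].mean()
        p_rows, x_rows, c_rows, l_rows, s_rows = [], [], [], [], []
        for s in streams:
            s_env = env[env["stream_id"] == s].set_index("_d")
            s_chla = chla_date_means.loc[s]
            for comm_iv, x_iv in zip(
                [iv for iv in interval_results
                 if iv.level == "community" and iv.stream_id == s],
                within_rows[s]["x"],
            ):
                d0, d1 = comm_iv.date_t, comm_iv.date_t_dt
                mask = (s_env.index >= pd.Timestamp(d0)) & (s_env.index <= pd.Timestamp(d1))
                light = float(s_env.loc[mask, "light"].mean())
                # interval chlorophyll: mean of endpoint date means
                c_vals = [s_chla[d] for d in (d0, d1) if d in s_chla.index]
                if not c_vals:
                    continue
                p_rows.append(comm_iv.P_daily)
                x_rows.append(x_iv)
                c_rows.append(np.atleast_1d(float(np.mean(c_vals))))
                l_rows.append(light)
                s_rows.append(s)
        try:
            within_sel, within_fit = res.within_stream_selection(
                p_rows, np.array(x_rows), c_rows, np.array(l_rows), np.array(s_rows),
                n_rep=config.n_rep_selection, seed=derive_seed(config.seed, 33))
        except (RuntimeError, ValueError) as e:
            raise RuntimeError(f"resources stage (within-stream selection): {e}") from e

    if gpp_df is not None:
        gpp_model = res.fit_gpp_model(
            gpp_df["gpp"], gpp_df["chla"], gpp_df["light"],
            standardize_temperature(gpp_df["temp_C"].to_numpy(), config.t_ref_c),
            n_boot=config.n_boot_production, seed=derive_seed(config.seed, 34))
        ep_within = within_sel.apparent_E if within_sel is not None else None
        if ep_within is not None:
            corrected_within = res.resource_correct_within(
                ep_within, gpp_model.E_gpp,
                n_boot=config.n_boot_slopes, seed=derive_seed(config.seed, 35))

    # --- outputs -----------------------------------------------------------
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_outputs(
        out, config, interval_results, annual_p, annual_b, pb, energies,
        among, within_sel, corrected_within,
    )
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_boot": {
            "growth": config.n_boot_growth,
            "production": config.n_boot_production,
            "slopes": config.n_boot_slopes,
            "selection": config.n_rep_selection,
        },
        "package": "streamprod 0.1.0",
        "growth_fit": {
            "n_used": global_model.n_used,
            "n_excluded_nonpositive": global_model.n_excluded_nonpositive,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=config,
        growth_model=global_model,
        stream_growth_models=stream_models,
        stream_x=stream_x,
        interval_production=interval_results,
        annual_production=annual_p,
        annual_biomass=annual_b,
        pb=pb,
        community_mass=mc,
        activation_energies=energies,
        annual_chla=annual_chla,
        among_selection=among,
        within_selection=within_sel,
        within_mixed_fit=within_fit,
        gpp_model=gpp_model,
        corrected_within=corrected_within,
        manifest=manifest,
    )


def _write_outputs(out, config, intervals, annual_p, annual_b, pb, energies,
                   among, within_sel, corrected_within) -> None:
    rows = []
    for iv in intervals:
        rows.append({
            "stream_id": iv.stream_id, "level": iv.level, "taxon_id": iv.taxon_id,
            "date_t": iv.date_t, "date_t_dt": iv.date_t_dt, "dt_days": iv.dt_days,
            "P_mean": iv.P.mean, "P_ci_low": iv.P.ci_low, "P_ci_high": iv.P.ci_high,
            "P_daily_mean": iv.P_daily.mean,
            "B_mean": iv.B_mean.mean,
            "n_boot": iv.P.n_boot, "seed": config.seed,
        })
    pd.DataFrame(rows).to_csv(out / "production_intervals.csv", index=False)

    rows = []
    for s in annual_p:
        rows.append({
            "stream_id": s,
            "P_annual_g_m2_y": annual_p[s].mean,
            "P_ci_low": annual_p[s].ci_low, "P_ci_high": annual_p[s].ci_high,
            "B_annual_mg_m2": annual_b[s].mean,
            "PB_y": pb[s].mean, "PB_ci_low": pb[s].ci_low, "PB_ci_high": pb[s].ci_high,
            "n_boot": annual_p[s].n_boot, "seed": config.seed,
        })
    pd.DataFrame(rows).to_csv(out / "production_annual.csv", index=False)

    pd.DataFrame([e.summary() for e in energies]).to_csv(
        out / "activation_energies.csv", index=False)

    sel_rows = []
    if among is not None:
        for name, f in among.frequencies.items():
            sel_rows.append({"scope": "among", "model": name, "frequency": f,
                             "winner": among.winner, "n_rep": among.n_rep,
                             "seed": among.seed})
    if within_sel is not None:
        for name, f in within_sel.frequencies.items():
            sel_rows.append({"scope": "within", "model": name, "frequency": f,
                             "winner": within_sel.winner, "n_rep": within_sel.n_rep,
                             "seed": within_sel.seed})
    pd.DataFrame(sel_rows).to_csv(out / "selection_report.csv", index=False)

    corr_rows = []
    if among is not None and among.corrected_E is not None:
        corr_rows.append({
            "scope": "among", "E_mean": among.corrected_E.mean,
            "ci_low": among.corrected_E.ci_low, "ci_high": among.corrected_E.ci_high,
            "n_boot": among.corrected_E.n_boot, "seed": among.seed,
        })
    if corrected_within is not None:
        corr_rows.append({
            "scope": "within", "E_mean": corrected_within.E_mean,
            "ci_low": corrected_within.ci_low, "ci_high": corrected_within.ci_high,
            "n_boot": corrected_within.n_boot, "seed": corrected_within.seed,
        })
    pd.DataFrame(corr_rows).to_csv(out / "corrected_E.csv", index=False)
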