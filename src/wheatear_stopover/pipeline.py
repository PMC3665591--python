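"""End-to-end orchestration: energetics -> design -> two-step CJS fit ->
stopover Monte Carlo -> departure analysis, with a run manifest.

Every run is reproducible from its manifest: the configuration snapshot,
input-file digests, seeds and per-stage status are recorded as JSON next to
the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, circstats, energetics, solarwind
from .cjs import MCMCConfig, build_design, impute_efl, two_step_fit
from .stopover import simulate_stopover, summarize_stopover
from .synthdata import SimulationConfig, simulate_study

log = logging.getLogger("wheatear_stopover")

__all__ = ["run_departure_analysis", "run_full_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def run_departure_analysis(
    departures: pd.DataFrame, declination: float | None = None, seed: int | None = None
) -> dict:
    """Summaries of nocturnal departures: circular direction statistics and
    linear statistics of departure time and sun elevation.

    Accepts any table in the departures dialect (``minutes_after_sunset``,
    ``sun_elevation_deg``, ``direction_deg`` columns; other columns ignored).
    Malformed rows are skipped with a logged warning.  With ``declination``
    given, a declination-shifted direction summary (geographic frame) is
    reported alongside the raw one.
    """
    if departures is None or len(departures) == 0:
        raise ValueError("empty departures table")
    df = departures.copy()
    for col in ("minutes_after_sunset", "sun_elevation_deg", "direction_deg"):
        if col in df.columns:
            before = df[col].notna().sum()
            df[col] = pd.to_numeric(df[col], errors="coerce")
            dropped = before - df[col].notna().sum()
            if dropped:
                log.warning("dropped %d malformed values in %s", dropped, col)

    report: dict = {"n_rows": int(len(df))}

    def _linear(x: pd.Series) -> dict:
        x = x.dropna().to_numpy(dtype=float)
        out = {"n": int(x.size)}
        if x.size:
            out["mean"] = float(x.mean())
            out["sd"] = float(x.std(ddof=1)) if x.size > 1 else None
            out["range"] = [float(x.min()), float(x.max())]
        return out

    report["minutes_after_sunset"] = _linear(df["minutes_after_sunset"])
    report["sun_elevation_deg"] = _linear(df["sun_elevation_deg"])

    def _circ(values: np.ndarray) -> dict:
        sample = circstats.AngleSample(values)
        s = circstats.summarize(sample, seed=seed)
        return {
            "n": s.n,
            "mean_direction": s.mean_direction,
            "R": s.R,
            "ci95": list(s.ci95) if s.ci95 else None,
            "rayleigh_p": s.rayleigh_p,
        }

    dirs = df["direction_deg"].dropna().to_numpy(dtype=float)
    report["direction"] = _circ(dirs) if dirs.size else {"n": 0}
    if declination is not None and dirs.size:
        report["direction_geographic"] = _circ((dirs + declination) % 360.0)
        report["declination"] = declination
    return report


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_full_pipeline(
    outdir,
    simulate: SimulationConfig | None = None,
    input_dir=None,
    mcmc: MCMCConfig | None = None,
    declination: float | None = None,
    n_sim_stopover: int = 1000,
    stopover_horizon: int = 30,
    abort_rhat: float = 1.10,
    seed: int = 0,
) -> dict:
    """Run every stage on simulated or user-supplied tables.

    Either ``simulate`` (a :class:`SimulationConfig`) or ``input_dir`` (a
    directory holding birds/encounters/masses/covariates/departures CSVs)
    must be given.  Outputs: ``fuel_profiles.csv``, ``posterior.csv`` (both
    fit steps), ``stopover.csv``, ``departure_summary.json``,
    ``manifest.json``.  Deterministic given the seeds.  Any stage failure
    raises :class:`PipelineError` after writing a partial manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mcmc = mcmc or MCMCConfig(seed=seed)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "mcmc": asdict(mcmc),
        "stages": {},
        "defaults": {
            "airspeed_kmh": energetics.DEFAULT_AIRSPEED_KMH,
            "transmitter_mass_g": energetics.DEFAULT_TRANSMITTER_MASS_G,
            "sunset_elevation_deg": solarwind.SUNSET_ELEVATION,
            "stopover_horizon_days": stopover_horizon,
            "efl_cap": 1.3,
            "prior_sd": 31.62,
        },
    }
    for k, v in manifest["defaults"].items():
        log.info("default in effect: %s = %s", k, v)

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                status = "ok" if exc is None else f"failed: {exc}"
                manifest["stages"][name] = {"status": status, "seconds": round(dt, 3)}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, str(exc)) from exc
                return False

        return _Ctx()

    with _stage("inputs"):
        if simulate is not None:
            study = simulate_study(replace(simulate, seed=seed))
            study.write(out / "inputs")
            input_dir = out / "inputs"
            manifest["simulate"] = {
                k: v for k, v in asdict(simulate).items() if k != "coeffs"
            }
        elif input_dir is None:
            raise ValueError("need either a simulation config or an input directory")
        input_dir = Path(input_dir)
        tables = {}
        for name in ("birds", "encounters", "masses", "covariates", "departures"):
            path = input_dir / f"{name}.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing input table {path}")
            tables[name] = pd.read_csv(path)
            manifest.setdefault("inputs", {})[name] = _digest(path)
        covariates = solarwind.read_covariates(input_dir / "covariates.csv")

    with _stage("energetics"):
        lat, lon = (simulate.lat, simulate.lon) if simulate else solarwind.WALES
        days = pd.to_datetime(covariates["date"]).dt.date
        sunsets = {d: solarwind.sun_events(lat, lon, d).sunset_utc for d in days}
        profiles = energetics.build_fuel_profiles(tables["birds"], tables["masses"], sunsets)
        profiles.to_csv(out / "fuel_profiles.csv", index=False)
        efl_long = energetics.evening_fuel_loads(tables["birds"], tables["masses"], sunsets)

    with _stage("design"):
        with_efl_ids = set(efl_long["ring_id"])
        enc = tables["encounters"]
        birds = tables["birds"]
        fp = profiles[["ring_id", "afl"]]
        enc_efl = enc[enc["ring_id"].isin(with_efl_ids)]
        enc_noefl = enc[~enc["ring_id"].isin(with_efl_ids)]
        if enc_noefl.empty or enc_efl.empty:
            raise ValueError("need birds both with and without evening fuel loads")
        design1 = build_design(enc_noefl, birds, fp, covariates)
        design2 = build_design(enc_efl, birds, fp, covariates, efl=efl_long)
        completed, efl_model = impute_efl(design2.efl, design2.history.first)
        design2.efl = np.where(
            np.arange(design2.efl.shape[1]) >= design2.history.first[:, None],
            completed, 0.0,
        )
        design2.efl = np.nan_to_num(design2.efl, nan=0.0)

    with _stage("fit"):
        step1, step2, priors2 = two_step_fit(design1, design2, mcmc, abort_rhat=abort_rhat)
        post = pd.concat(
            [
                step1.summary.assign(step=1, model="with_afl"),
                step2.summary.assign(step=2, model="with_efl"),
            ]
        )
        post.to_csv(out / "posterior.csv")
        draws = step2.flat_draws
        pd.DataFrame(draws, columns=step2.param_names).to_csv(
            out / "posterior_draws_step2.csv", index=False
        )
        manifest["fit"] = {
            "step1_converged": bool(step1.converged),
            "step2_converged": bool(step2.converged),
        }

    with _stage("stopover"):
        durations, truncated = simulate_stopover(
            design2, step2.draws, model="with_efl", n_sim=n_sim_stopover,
            horizon_days=stopover_horizon, efl_model=efl_model, seed=seed + 7,
        )
        est = summarize_stopover(
            durations, design2.history.Y, design2.history.ring_ids, truncated
        )
        est.per_bird.to_csv(out / "stopover.csv", index=False)
        manifest["stopover"] = {
            "population_mean_days": est.population_mean,
            "population_se": est.population_se,
            "population_cri": list(est.population_cri),
            "across_bird_se": est.across_bird_se,
            "n_truncated_draws": est.n_truncated,
        }

    with _stage("departures"):
        report = run_departure_analysis(
            tables["departures"], declination=declination, seed=seed + 11
        )
        (out / "departure_summary.json").write_text(json.dumps(report, indent=1))
        manifest["departures"] = report

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
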