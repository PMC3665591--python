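"""Synthetic stopover studies with the statistical structure the pipeline assumes.

The generator emulates a 21-day Arctic ringing season: birds arrive staggered
through the season with arrival fuel loads around 0.21 +/- 0.09, gain fuel at
about 0.04 per day, stay or depart each night according to the logit-linear
staging model (with the published coefficient means as the default truth),
are detected according to the logit-linear detection model (radio-tagged
birds near-certainly), and radio-tagged departers emit a departure time
(truncated normal, 85 +/- 29 min after sunset) and a direction (von Mises
around 233 deg with concentration matched to R = 0.87).  All five pipeline
tables are produced in their exact dialects, together with the latent truth
for parameter-recovery tests.

The individual radio-tracking table of the field study is shipped verbatim as
:func:`table1_fixture`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from . import solarwind
from .cjs import CoefficientSet, _sigmoid
from .energetics import DEFAULT_TRANSMITTER_MASS_G, lean_body_mass

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "generate_covariates",
    "simulate_study",
    "vonmises_kappa_from_R",
    "table1_fixture",
    "TABLE1_RING_IDS",
]

#: Published staging/detection coefficient means (evening-fuel-load model)
#: used as the default data-generating truth.
DEFAULT_TRUE_COEFFS = CoefficientSet(
    alpha=np.array([4.500, -0.474, -0.108, 0.787, -0.118, 0.236, -0.830, -3.915, 0.328]),
    beta=np.array([2.946, 30.796, -0.143]),
)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic season.

    Defaults mirror the field study: 105 birds over 21 days from 11 Aug 2010
    at the Bering Strait site, arrival fuel load ~ N(0.21, 0.09) truncated
    positive, fuel deposition ~ N(0.04, 0.02) per day, departure time
    ~ N(85, 29) min after sunset (truncated to the night), direction
    von Mises around 233 deg at concentration R = 0.87, 30/105 birds
    radio-tagged and 30/105 on the balances.
    """

    n_birds: int = 105
    n_days: int = 21
    start_date: date = date(2010, 8, 11)
    lat: float = solarwind.WALES[0]
    lon: float = solarwind.WALES[1]
    afl_mean: float = 0.21
    afl_sd: float = 0.09
    fdr_mean: float = 0.04
    fdr_sd: float = 0.02
    efl_noise_sd: float = 0.02
    efl_cap: float = 1.3
    wing_mean: float = 95.0
    wing_sd: float = 2.0
    wing_range: tuple = (85.0, 105.0)
    coeffs: CoefficientSet = field(default_factory=lambda: DEFAULT_TRUE_COEFFS)
    departure_time_mean: float = 85.0
    departure_time_sd: float = 29.0
    direction_mean: float = 233.0
    direction_R: float = 0.87
    tag_fraction: float = 30.0 / 105.0
    balance_fraction: float = 30.0 / 105.0
    efl_obs_prob: float = 0.85
    goal_direction: float = 233.0
    temp_mean_C: float = 6.0
    temp_sd_C: float = 2.5
    temp_ar1: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("afl_sd", "fdr_sd", "efl_noise_sd", "departure_time_sd",
                     "wing_sd", "temp_sd_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("tag_fraction", "balance_fraction", "efl_obs_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.direction_R < 1.0:
            raise ValueError("direction_R must lie in [0, 1)")
        if self.n_days < 2 or self.n_birds < 1:
            raise ValueError("need at least 2 days and 1 bird")


@dataclass
class SyntheticTruth:
    """Latent ground truth of a simulated study."""

    coeffs: CoefficientSet
    arrival_day: np.ndarray  # (N,) 0-based study-day index
    z: np.ndarray  # (N, T) latent presence
    efl_true: np.ndarray  # (N, T) noiseless+noise trajectory actually used
    departure_night: np.ndarray  # (N,) day index of last presence; -1 if at end
    departure_minutes: np.ndarray  # (N,) min after sunset, NaN if unobserved
    departure_direction: np.ndarray  # (N,) deg, NaN if unobserved

    def to_json(self, path) -> None:
        obj = {
            "alpha": self.coeffs.alpha.tolist(),
            "beta": self.coeffs.beta.tolist(),
            "arrival_day": self.arrival_day.tolist(),
            "z": self.z.tolist(),
            "departure_night": self.departure_night.tolist(),
            "departure_minutes": np.where(
                np.isfinite(self.departure_minutes), self.departure_minutes, None
            ).tolist(),
            "departure_direction": np.where(
                np.isfinite(self.departure_direction), self.departure_direction, None
            ).tolist(),
        }
        Path(path).write_text(json.dumps(obj))


@dataclass
class SyntheticStudy:
    birds: pd.DataFrame
    encounters: pd.DataFrame
    masses: pd.DataFrame
    covariates: pd.DataFrame
    departures: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.birds.to_csv(out / "birds.csv", index=False)
        self.encounters.to_csv(out / "encounters.csv", index=False)
        self.masses.to_csv(out / "masses.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.departures.to_csv(out / "departures.csv", index=False)
        self.truth.to_json(out / "truth.json")


def vonmises_kappa_from_R(R: float) -> float:
    """Concentration kappa of a von Mises with mean resultant length R.

    Inverts A(kappa) = I1(kappa)/I0(kappa) = R numerically; kappa = 0 at
    R = 0, diverges as R -> 1.
    """
    if not 0.0 <= R < 1.0:
        raise ValueError("R must lie in [0, 1)")
    if R == 0.0:
        return 0.0

    def f(k: float) -> float:
        return i1e(k) / i0e(k) - R

    hi = 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise ArithmeticError("kappa search exceeded bounds")
    kappa = brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-12)
    assert abs(f(kappa)) < 1e-8
    return float(kappa)


def generate_covariates(
    n_days: int,
    seed: int | np.random.Generator = 0,
    temp_mean: float = 6.0,
    temp_sd: float = 2.5,
    ar1: float = 0.6,
    goal_direction: float = 233.0,
    start_date: date = date(2010, 8, 11),
    wind_scale: float = 1.0,
) -> pd.DataFrame:
    """Daily weather table: AR(1) temperature, multi-level winds, midnight twc.

    Surface and four pressure-level winds get independent random directions
    and gamma-distributed speeds that increase with altitude; the midnight
    tailwind column is the level maximum toward ``goal_direction``.
    Reproducible from the seed.
    """
    if n_days < 2:
        raise ValueError("need at least 2 days")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    innov_sd = temp_sd * np.sqrt(max(1.0 - ar1**2, 1e-12)) if abs(ar1) < 1 else temp_sd
    temp = np.empty(n_days)
    temp[0] = temp_mean + temp_sd * rng.standard_normal()
    for t in range(1, n_days):
        temp[t] = temp_mean + ar1 * (temp[t - 1] - temp_mean) + innov_sd * rng.standard_normal()
    level_scale = {"surface": 1.0, "1000": 1.3, "925": 1.6, "850": 1.9, "700": 2.2}
    speeds = {
        lvl: rng.gamma(2.0, 2.5, size=n_days) * s * wind_scale
        for lvl, s in level_scale.items()
    }
    dirs = {lvl: rng.uniform(0, 360, size=n_days) for lvl in level_scale}
    dates = [start_date + timedelta(days=i) for i in range(n_days)]
    df = pd.DataFrame(
        {
            "date": dates,
            "temp_surface_C": temp,
            "wind_surface_ms": speeds["surface"],
            "wind_surface_dir_to": dirs["surface"],
        }
    )
    for lvl in ("1000", "925", "850", "700"):
        df[f"wind_{lvl}_ms"] = speeds[lvl]
        df[f"wind_{lvl}_dir_to"] = dirs[lvl]
    twc = []
    for i in range(n_days):
        obs = [
            solarwind.WindObservation(dates[i], lvl, speeds[lvl][i], dirs[lvl][i])
            for lvl in level_scale
        ]
        twc.append(solarwind.max_tailwind(obs, goal_direction))
    df["twc_midnight_ms"] = twc
    return df


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from the configured conditions."""
    cfg = config
    master = np.random.default_rng(cfg.seed)
    rng_cov, rng_birds, rng_state, rng_det, rng_mass, rng_dep = master.spawn(6)

    T, N = cfg.n_days, cfg.n_birds
    dates = [cfg.start_date + timedelta(days=i) for i in range(T)]
    covariates = generate_covariates(
        T, rng_cov, cfg.temp_mean_C, cfg.temp_sd_C, cfg.temp_ar1,
        cfg.goal_direction, cfg.start_date,
    )

    # --- birds
    ring_ids = [f"SIM{k:05d}" for k in range(N)]
    arrival = rng_birds.integers(0, T, size=N)
    wing = np.clip(
        cfg.wing_mean + cfg.wing_sd * rng_birds.standard_normal(N), *cfg.wing_range
    )
    lean = np.array([lean_body_mass(w) for w in wing])
    afl = cfg.afl_mean + cfg.afl_sd * rng_birds.standard_normal(N)
    while np.any(afl <= 0.005):  # truncate: arriving birds carry some fuel
        bad = afl <= 0.005
        afl[bad] = cfg.afl_mean + cfg.afl_sd * rng_birds.standard_normal(bad.sum())
    fdr = cfg.fdr_mean + cfg.fdr_sd * rng_birds.standard_normal(N)
    tagged = rng_birds.random(N) < cfg.tag_fraction
    tag_mass = np.where(tagged, DEFAULT_TRANSMITTER_MASS_G, 0.0)
    balance = rng_birds.random(N) < cfg.balance_fraction
    arrival_mass = lean * (1.0 + afl) + tag_mass
    birds = pd.DataFrame(
        {
            "ring_id": ring_ids,
            "first_capture_date": [dates[a].isoformat() for a in arrival],
            "wing_mm": np.round(wing * 2) / 2,  # measured to 0.5 mm
            "arrival_mass_g": np.round(arrival_mass, 1),
            "radio_tagged": tagged,
            "transmitter_mass_g": tag_mass,
        }
    )

    # --- true fuel trajectories and latent presence
    t_grid = np.arange(T)
    daysa = np.where(t_grid >= arrival[:, None], t_grid - arrival[:, None] + 1, 0.0)
    indfirst = (t_grid == arrival[:, None]).astype(float)
    day_c = (t_grid + 1) - (T + 1) / 2.0
    efl_true = afl[:, None] + fdr[:, None] * (t_grid - arrival[:, None])
    efl_true = efl_true + cfg.efl_noise_sd * rng_state.standard_normal((N, T))
    efl_true = np.clip(efl_true, -0.2, cfg.efl_cap)
    efl_true = np.where(t_grid >= arrival[:, None], efl_true, 0.0)

    def _z(x):
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    temp_z = _z(covariates["temp_surface_C"].to_numpy())
    wind_z = _z(covariates["wind_surface_ms"].to_numpy())
    twc_z = _z(covariates["twc_midnight_ms"].to_numpy())
    a = cfg.coeffs.alpha
    lp = (
        a[0]
        + a[1] * daysa
        + a[2] * day_c[None, :]
        + a[3] * temp_z[None, :]
        + a[4] * wind_z[None, :]
        + a[5] * twc_z[None, :]
        + a[6] * indfirst
        + a[7] * efl_true
        + a[8] * efl_true * day_c[None, :]
    )
    phi = _sigmoid(lp)
    z = np.zeros((N, T), dtype=int)
    for i in range(N):
        z[i, arrival[i]] = 1
        for t in range(arrival[i] + 1, T):
            if z[i, t - 1] and rng_state.random() < phi[i, t - 1]:
                z[i, t] = 1
            else:
                break
    last_present = np.array(
        [np.flatnonzero(z[i])[-1] if z[i].any() else arrival[i] for i in range(N)]
    )
    departed_in_study = last_present < T - 1
    departure_night = np.where(departed_in_study, last_present, -1)

    # --- detections
    b = cfg.coeffs.beta
    p = _sigmoid(b[0] + b[1] * tagged[:, None].astype(float) + b[2] * wind_z[None, :])
    Y = ((rng_det.random((N, T)) < p) & (z == 1)).astype(int)
    Y[np.arange(N), arrival] = 1
    Y[t_grid < arrival[:, None]] = 0
    encounters = pd.DataFrame(
        {
            "ring_id": np.repeat(ring_ids, T),
            "date": [d.isoformat() for _ in range(N) for d in dates],
            "detected": Y.reshape(-1),
        }
    )

    # --- solar events for the season (used by masses and departures)
    events = {d: solarwind.sun_events(cfg.lat, cfg.lon, d) for d in dates}

    # --- balance weighings
    mass_rows = []
    for i in range(N):
        if not balance[i]:
            continue
        for t in range(arrival[i], T):
            if not z[i, t]:
                break
            if rng_mass.random() >= cfg.efl_obs_prob:
                continue
            sunset = events[dates[t]].sunset_utc
            offset = rng_mass.uniform(5.0, 115.0)
            ts = pd.Timestamp(sunset) - pd.Timedelta(minutes=float(offset))
            mass = lean[i] * (1.0 + efl_true[i, t]) + tag_mass[i]
            mass_rows.append(
                {
                    "ring_id": ring_ids[i],
                    "date": ts.date().isoformat(),
                    "time_utc": ts.strftime("%H:%M:%S"),
                    "mass_g": round(float(mass), 1),
                }
            )
    masses = pd.DataFrame(
        mass_rows, columns=["ring_id", "date", "time_utc", "mass_g"]
    )

    # --- radio-tracked departures
    kappa = vonmises_kappa_from_R(cfg.direction_R)
    dep_minutes = np.full(N, np.nan)
    dep_direction = np.full(N, np.nan)
    dep_rows = []
    for i in range(N):
        if not (tagged[i] and departed_in_study[i]):
            continue
        night = dates[departure_night[i]]
        ev = events[night]
        if ev.night_length <= 0:
            raise ValueError("night shorter than any departure offset")
        for _ in range(1000):
            m = cfg.departure_time_mean + cfg.departure_time_sd * rng_dep.standard_normal()
            if 0.0 <= m <= ev.night_length:
                break
        else:
            raise ValueError("could not draw a departure time within the night")
        if kappa > 0:
            d = np.degrees(rng_dep.vonmises(np.radians(cfg.direction_mean), kappa)) % 360
        else:
            d = rng_dep.uniform(0, 360)
        dep_minutes[i], dep_direction[i] = m, d
        when = pd.Timestamp(ev.sunset_utc) + pd.Timedelta(minutes=float(m))
        elev = solarwind.sun_elevation(cfg.lat, cfg.lon, when)
        dep_rows.append(
            {
                "ring_id": ring_ids[i],
                "departure_date": night.isoformat(),
                "minutes_after_sunset": round(float(m), 1),
                "sun_elevation_deg": round(float(elev), 2),
                "direction_deg": round(float(d), 1),
                "frame": "geographic",
            }
        )
    departures = pd.DataFrame(
        dep_rows,
        columns=[
            "ring_id", "departure_date", "minutes_after_sunset",
            "sun_elevation_deg", "direction_deg", "frame",
        ],
    )

    truth = SyntheticTruth(
        coeffs=cfg.coeffs,
        arrival_day=arrival,
        z=z,
        efl_true=efl_true,
        departure_night=departure_night,
        departure_minutes=dep_minutes,
        departure_direction=dep_direction,
    )
    return SyntheticStudy(
        birds=birds,
        encounters=encounters,
        masses=masses,
        covariates=covariates,
        departures=departures,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Field radio-tracking table (verbatim fixture)

_TABLE1 = [
    # ring_id, capture, departure night, min after sunset, sun elev, direction, note
    ("179106207", "2010-08-11", None, None, None, None,
     "loss of signal during the night on 12./13.8.; tracked until 40 min after sunset"),
    ("179106208", "2010-08-11", "2010-08-18", 83, -6.68, 219, ""),
    ("179106210", "2010-08-12", "2010-08-18", 103, -7.87, 194, ""),
    ("179106211", "2010-08-12", "2010-08-12", 85, -6.17, 201, ""),
    ("179106212", "2010-08-12", "2010-08-17", 114, -8.33, 204, ""),
    ("179106214", "2010-08-12", "2010-08-17", 124, -8.80, 209, ""),
    ("179106215", "2010-08-13", None, None, None, None,
     "loss of signal during the night on 13./14.8.; tracked until 305 min after sunset"),
    ("179106224", "2010-08-14", "2010-08-18", 68, -5.70, 239, ""),
    ("179106229", "2010-08-14", None, None, None, None,
     "loss of signal during the night on 20./21.8.; tracked until 165 min after sunset"),
    ("179106236", "2010-08-14", None, None, None, None,
     "no tracking during the night of 14./15.8. due to strong gale and rain; "
     "likely disappeared during the day of 14.8. (transient)"),
    ("179106242", "2010-08-15", "2010-08-18", 128, -9.14, 219, ""),
    ("179106257", "2010-08-19", None, None, None, None,
     "loss of signal during the night on 19./20.8.; tracked until 220 min after sunset"),
    ("179106259", "2010-08-19", None, None, None, None,
     "disappeared during the day; tracked until the morning of 20.8., "
     "but not relocated during the day"),
    ("179106261", "2010-08-20", "2010-08-20", 76, -6.37, 219, ""),
    ("179106262", "2010-08-20", "2010-08-26", 95, -8.11, 277, ""),
    ("179106263", "2010-08-21", None, None, None, None,
     "loss of signal during the night on 21./22.8.; tracked until 270 min after sunset"),
    ("179106264", "2010-08-21", "2010-08-26", 55, -5.49, 264, ""),
    ("179106265", "2010-08-22", "2010-08-26", 99, -8.47, 274, ""),
    ("179106266", "2010-08-22", "2010-08-25", 29, -3.47, None,
     "departure direction could not be determined"),
    ("179106271", "2010-08-22", None, None, None, None,
     "disappeared during the night on 22./23.8.; tracked until 195 min after sunset"),
    ("179106275", "2010-08-22", None, None, None, None,
     "disappeared during the night on 22./23.8.; tracked until 165 min after sunset"),
    ("179106276", "2010-08-22", "2010-08-26", 48, -4.92, 269, ""),
    ("179106277", "2010-08-23", "2010-08-26", 114, -9.45, 274, ""),
    ("179106286", "2010-08-26", None, None, None, None,
     "disappeared during the day (transient); not relocated on the evening of 26.8."),
    ("179106297", "2010-08-29", None, None, None, None,
     "disappeared during the day (transient); not relocated on the evening of 29.8."),
    ("179106298", "2010-08-29", "2010-08-29", 87, -7.90, 204, ""),
    ("179106299", "2010-08-29", None, None, None, None,
     "disappeared during the day (transient); not relocated on the evening of 29.8."),
    ("181108935", "2010-08-29", "2010-08-29", 54, -5.60, 234, ""),
    ("181108944", "2010-08-31", None, None, None, None,
     "disappeared during the day (transient); not relocated on the evening of 31.8."),
    ("181108945", "2010-08-31", None, None, None, None,
     "disappeared during the day (transient); not relocated on the evening of 31.8."),
]

TABLE1_RING_IDS = [r[0] for r in _TABLE1]


def table1_fixture() -> pd.DataFrame:
    """The 30 radio-tracked birds of the autumn 2010 field season, verbatim.

    ``departure_date`` is the calendar date of the sunset opening the
    departure night; 16 rows carry a departure time (minutes after local
    sunset, with the sun's elevation at take-off), 15 of those a departure
    direction (degrees; as printed, i.e. compass bearings not shifted by the
    local declination of +11.19 deg east — the printed direction range
    [205, 288] equals this table's raw range shifted by the declination,
    while the printed mean of 233 deg and R = 0.87 are reproduced by the raw
    values, so both readings are retained downstream).
    """
    df = pd.DataFrame(
        _TABLE1,
        columns=[
            "ring_id", "capture_date", "departure_date", "minutes_after_sunset",
            "sun_elevation_deg", "direction_deg", "note",
        ],
    )
    df["has_departure_time"] = df["minutes_after_sunset"].notna()
    df["has_direction"] = df["direction_deg"].notna()
    return df
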