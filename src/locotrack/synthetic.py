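"""Synthetic pen-movement and growth simulator.

Generates RFID registration logs, weekly weight tables and round metadata
with the statistical structure the downstream analysis assumes, together
with the generating truth, so that every stage of the pipeline can be
exercised and validated without farm data.

The generative model per bird j:

* a declining linear activity trend with AR(1) day-to-day deviations:
  ``target_d = max(0, a_j + b_j * d + eps_d)`` where eps is stationary
  AR(1) with marginal SD ``sigma_j`` and lag-1 correlation ``rho_j``;
* within a day, a two-state (active/inactive) bout process over minutes
  whose regularity knob ``reg_j`` interpolates bout durations between a
  fixed period (1: rigidly periodic) and a geometric law (0: memoryless);
* movement as nearest-neighbour (4-connected) antenna hops at 1 Hz during
  active seconds, with the hop count calibrated so the kinematics module
  recovers the day's target DADM; movement is damped during dark periods;
* weekly weights on a linear growth line with
  ``ADG_true = beta0 + beta_sw * W0_j + beta_rmse * sigma_j + noise``,
  rounded to the recording precision (1 g at the start, 5 g later).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    SECONDS_PER_DAY,
    DaySchedule,
    Priors,
    RoundSpec,
    SimConfig,
    metadata_to_yaml,
)
from .kinematics import AntennaGrid, build_antenna_grid

__all__ = [
    "BirdParams",
    "SimulationError",
    "sample_bird_parameters",
    "simulate_daily_activity_targets",
    "simulate_rfid_day",
    "simulate_day_switch_minutes",
    "simulate_weights",
    "generate_dataset",
]


class SimulationError(RuntimeError):
    """A requested simulation is physically or numerically impossible."""


@dataclass(frozen=True)
class BirdParams:
    """Generating truth for one bird."""

    bird_id: str
    round_id: int
    a: float        # activity trend intercept, m/h
    b: float        # activity trend slope, m/h per day
    sigma: float    # marginal SD of day-to-day deviations, m/h
    rho: float      # lag-1 autocorrelation of deviations
    reg: float      # within-day bout regularity in [0, 1]
    w0: float       # start weight, g
    adg_true: float  # generating average daily gain, g/day

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if not 0 <= self.reg <= 1:
            raise ValueError("reg must be in [0, 1]")


def sample_bird_parameters(config: SimConfig, priors: Priors | None = None) -> list[BirdParams]:
    """Draw one parameter set per bird, deterministically from config.seed."""
    priors = priors or Priors()
    rng = np.random.default_rng(config.seed)
    out: list[BirdParams] = []
    for r in config.rounds:
        for i in range(r.n_birds):
            a = rng.normal(priors.a_mean, priors.a_sd)
            b = rng.normal(priors.b_mean, priors.b_sd)
            sigma = float(rng.lognormal(priors.sigma_log_mean, priors.sigma_log_sd))
            rho = float(np.clip(rng.normal(priors.rho_mean, priors.rho_sd),
                                -priors.rho_bound, priors.rho_bound))
            reg = float(rng.uniform(priors.reg_low, priors.reg_high))
            w0 = float(max(20.0, rng.normal(priors.w0_mean, priors.w0_sd)))
            adg = priors.beta0 + priors.beta_sw * w0 + priors.beta_rmse * sigma
            adg += float(rng.normal(0.0, priors.adg_noise_sd)) if priors.adg_noise_sd else 0.0
            out.append(BirdParams(f"R{r.round_id}B{i:03d}", r.round_id,
                                  float(a), float(b), sigma, rho, reg, w0, float(adg)))
    return out


def simulate_daily_activity_targets(p: BirdParams, days, rng: np.random.Generator) -> np.ndarray:
    """Target DADM per day: linear trend plus stationary AR(1) deviations,
    truncated at zero (activity cannot be negative)."""
    days = np.asarray(days, dtype=float)
    if days.size == 0:
        raise ValueError("days must be non-empty")
    if p.sigma == 0:
        eps = np.zeros(days.size)
    else:
        innov_sd = p.sigma * np.sqrt(1.0 - p.rho ** 2)
        eps = np.empty(days.size)
        eps[0] = rng.normal(0.0, p.sigma)  # stationary initialization
        shocks = rng.normal(0.0, innov_sd, size=days.size - 1)
        for i in range(1, days.size):
            eps[i] = p.rho * eps[i - 1] + shocks[i - 1]
    return np.maximum(0.0, p.a + p.b * days + eps)


def _bout_states(reg: float, rng: np.random.Generator, n_minutes: int,
                 mean_active: float, mean_inactive: float) -> np.ndarray:
    """Alternating active/inactive bouts over minutes.

    Bout durations interpolate between the fixed mean (reg = 1) and a
    geometric draw with that mean (reg = 0), so reg maps monotonically
    from rigid periodicity to memoryless switching.
    """
    start_active = bool(rng.random() < mean_active / (mean_active + mean_inactive))
    # every bout lasts >= 1 min, so n_minutes bouts always suffice
    n_bouts = n_minutes
    half = (n_bouts + 1) // 2
    dur_a = np.maximum(1, np.round(
        reg * mean_active + (1.0 - reg) * rng.geometric(1.0 / mean_active, size=half)))
    dur_i = np.maximum(1, np.round(
        reg * mean_inactive + (1.0 - reg) * rng.geometric(1.0 / mean_inactive, size=half)))
    durs = np.empty(2 * half, dtype=np.int64)
    pattern = np.empty(2 * half, dtype=bool)
    if start_active:
        durs[0::2], durs[1::2] = dur_a, dur_i
        pattern[0::2], pattern[1::2] = True, False
    else:
        durs[0::2], durs[1::2] = dur_i, dur_a
        pattern[0::2], pattern[1::2] = False, True
    k = int(np.searchsorted(np.cumsum(durs), n_minutes)) + 1
    return np.repeat(pattern[:k], durs[:k])[:n_minutes]


def _plan_day(target: float, reg: float, grid: AntennaGrid,
              schedule: DaySchedule, rng: np.random.Generator,
              mean_active: float, mean_inactive: float):
    """Bout states for all 1440 minutes plus per-minute hop counts within
    the light period, calibrated so the recovered DADM matches ``target``.

    Hop seconds are uniform without replacement over the active light
    seconds; drawing per-minute counts from the equivalent multivariate
    hypergeometric keeps the plan cheap for minute-resolution consumers.
    """
    if target < 0:
        raise SimulationError("target DADM must be non-negative")
    states = _bout_states(reg, rng, SECONDS_PER_DAY // 60, mean_active, mean_inactive)
    light_s, light_e = schedule.light_period
    minute_idx = np.arange(SECONDS_PER_DAY // 60)
    light_min = (minute_idx * 60 >= light_s) & (minute_idx * 60 < light_e)
    active_light_min = np.flatnonzero(states & light_min)
    n_active_s = active_light_min.size * 60
    light_hours = (light_e - light_s) / 3600.0
    step = grid.mean_step_length()
    n_moves = int(round(target * light_hours / step)) if step > 0 else 0
    if n_moves > n_active_s:
        raise SimulationError(
            f"target {target:.1f} m/h needs {n_moves} hops but only "
            f"{n_active_s} active light seconds are available")
    if n_moves:
        counts = rng.multivariate_hypergeometric([60] * active_light_min.size, n_moves)
    else:
        counts = np.zeros(active_light_min.size, dtype=np.int64)
    return states, active_light_min, counts, n_active_s


def _move_seconds(active_light_min: np.ndarray, counts: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Expand per-minute hop counts into distinct seconds of day."""
    secs = []
    for minute, c in zip(active_light_min[counts > 0], counts[counts > 0]):
        secs.append(minute * 60 + rng.choice(60, size=int(c), replace=False))
    if not secs:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(secs)).astype(np.int64)


def simulate_day_switch_minutes(target: float, reg: float, grid: AntennaGrid,
                                schedule: DaySchedule, rng: np.random.Generator,
                                mean_active: float = 5.0,
                                mean_inactive: float = 5.0) -> np.ndarray:
    """Fast path for entropy studies: per-minute antenna-switch flags over
    the light period, without materialising the 1 Hz walk."""
    _, active_min, counts, _ = _plan_day(target, reg, grid, schedule, rng,
                                         mean_active, mean_inactive)
    light_s, light_e = schedule.light_period
    flags = np.zeros((light_e - light_s) // 60, dtype=bool)
    moved = active_min[counts > 0] - light_s // 60
    flags[moved] = True
    return flags


def simulate_rfid_day(target: float, reg: float, grid: AntennaGrid,
                      schedule: DaySchedule, rng: np.random.Generator,
                      mode: str = "sparse", dark_move_factor: float = 0.05,
                      mean_active: float = 5.0, mean_inactive: float = 5.0):
    """One bird-day of registrations: (seconds_of_day, antenna_ids).

    Light-window hops are drawn as an exact calibrated count; outside the
    light window, active minutes move at the same per-second rate, damped
    by ``dark_move_factor`` during dark periods. ``mode`` "full" emits the
    1 Hz presence stream for all 86,400 s; "sparse" emits one registration
    per antenna switch plus a once-a-minute heartbeat (all quantities
    computed downstream are identical between the two).
    """
    states, active_min, counts, n_active_s = _plan_day(
        target, reg, grid, schedule, rng, mean_active, mean_inactive)
    move_secs = _move_seconds(active_min, counts, rng)
    light_s, light_e = schedule.light_period
    rate = move_secs.size / n_active_s if n_active_s else 0.0

    # movement outside the light window: Bernoulli at the (damped) rate
    active_min_out = np.flatnonzero(states)
    out_min = active_min_out[(active_min_out * 60 < light_s) | (active_min_out * 60 >= light_e)]
    extra = []
    if out_min.size and rate > 0:
        secs = (out_min[:, None] * 60 + np.arange(60)).ravel()
        dark = np.array([schedule.is_dark(int(s)) for s in secs])
        p = np.where(dark, rate * dark_move_factor, rate)
        extra = secs[rng.random(secs.size) < p]
    all_moves = np.sort(np.concatenate([move_secs, np.asarray(extra, dtype=np.int64)]))

    # nearest-neighbour walk over the move seconds
    neigh = [None] + [grid.neighbours(i).tolist() for i in range(1, grid.n_antennas + 1)]
    start_pos = pos = int(rng.integers(1, grid.n_antennas + 1))
    u = rng.random(all_moves.size)
    path = np.empty(all_moves.size, dtype=np.int64)
    for k in range(all_moves.size):
        nb = neigh[pos]
        pos = nb[int(u[k] * len(nb))]
        path[k] = pos

    # position held at each second: start antenna until the first move,
    # then the post-move antenna of the latest move
    positions = np.concatenate([[start_pos], path])

    if mode == "full":
        times = np.arange(SECONDS_PER_DAY, dtype=np.int64)
        ants = positions[np.searchsorted(all_moves, times, side="right")]
        return times, ants
    if mode != "sparse":
        raise ValueError("mode must be 'sparse' or 'full'")

    heartbeat_t = np.arange(0, SECONDS_PER_DAY, 60, dtype=np.int64)
    hb_ant = positions[np.searchsorted(all_moves, heartbeat_t, side="right")]
    times = np.concatenate([heartbeat_t, all_moves])
    ants = np.concatenate([hb_ant, path])
    order = np.argsort(times, kind="stable")
    return times[order], ants[order]


def simulate_weights(p: BirdParams, weigh_days, rng: np.random.Generator | None = None,
                     start_precision_g: float = 1.0, later_precision_g: float = 5.0):
    """Weekly weight table on the bird's linear growth line.

    Returns (DataFrame[bird_id, age_days, weight_g], adg_true). The start
    weight is rounded to ``start_precision_g``, every later weight to
    ``later_precision_g`` (scale precision differs at hatch). A negative
    generated weight raises :class:`SimulationError`.
    """
    days = list(weigh_days)
    if not days:
        raise ValueError("weigh_days must be non-empty")
    start = days[0]
    rows = []
    for d in days:
        w = p.w0 + p.adg_true * (d - start)
        if w < 0:
            raise SimulationError(f"negative weight for {p.bird_id} at age {d}")
        prec = start_precision_g if d == start else later_precision_g
        rows.append({"bird_id": p.bird_id, "age_days": int(d),
                     "weight_g": float(np.round(w / prec) * prec)})
    return pd.DataFrame(rows), p.adg_true


def _inject_group_gaps(df: pd.DataFrame, round_spec: RoundSpec, config: SimConfig,
                       rng: np.random.Generator, max_age: int) -> pd.DataFrame:
    """Delete all birds' registrations in Poisson-arriving outage windows."""
    gm = config.gap_model
    if gm.rate_per_day <= 0 or df.empty:
        return df
    light_s, light_e = config.schedule.light_period
    drop = np.zeros(len(df), dtype=bool)
    t = df["time"].to_numpy()
    for age in range(round_spec.start_age, max_age + 1):
        date = round_spec.date_of_age(age)
        for _ in range(rng.poisson(gm.rate_per_day)):
            start_s = rng.uniform(light_s, light_e)
            dur = gm.min_duration_s + rng.exponential(gm.mean_excess_s)
            t0 = np.datetime64(pd.Timestamp(date) + pd.Timedelta(seconds=start_s))
            t1 = np.datetime64(pd.Timestamp(date) + pd.Timedelta(seconds=start_s + dur))
            drop |= (t >= t0) & (t < t1)
    return df.loc[~drop].reset_index(drop=True)


def generate_dataset(config: SimConfig, priors: Priors | None = None,
                     outdir=None) -> dict:
    """Simulate the full experiment and (optionally) write it to disk.

    Produces per-round RFID logs, a pooled weight table, round metadata
    (YAML, with per-round tag rosters and handling windows) and the
    generating truth. Identical config and seed give byte-identical files.

    Returns a dict with keys ``rfid`` (round_id -> DataFrame), ``weights``,
    ``truth``, ``rounds``, ``roster``, ``handling_windows`` and, when
    ``outdir`` is given, ``paths``.
    """
    priors = priors or Priors()
    params = sample_bird_parameters(config, priors)
    grid = build_antenna_grid(config.grid_cols, config.grid_rows,
                              config.pen_width_m, config.pen_length_m)
    rng = np.random.default_rng([config.seed, 1])

    by_round: dict[int, list[BirdParams]] = {}
    for p in params:
        by_round.setdefault(p.round_id, []).append(p)

    rfid: dict[int, pd.DataFrame] = {}
    weight_frames = []
    handling = []
    roster = {}
    for r in config.rounds:
        birds = by_round[r.round_id]
        roster[r.round_id] = [p.bird_id for p in birds]
        max_age = min(r.end_age, config.rfid_max_age)
        ages = np.arange(r.start_age, max_age + 1)
        frames = []
        for p in birds:
            targets = simulate_daily_activity_targets(p, ages, rng)
            for age, target in zip(ages, targets):
                times, ants = simulate_rfid_day(
                    float(target), p.reg, grid, config.schedule, rng,
                    mode=config.registration_mode,
                    dark_move_factor=config.dark_move_factor,
                    mean_active=config.mean_active_bout_min,
                    mean_inactive=config.mean_inactive_bout_min)
                stamp = pd.Timestamp(r.date_of_age(int(age)))
                frames.append(pd.DataFrame({
                    "time": stamp + pd.to_timedelta(times, unit="s"),
                    "tag_id": p.bird_id,
                    "antenna_id": ants,
                }))
            table, _ = simulate_weights(p, config.weigh_days(r))
            weight_frames.append(table)
        df = pd.concat(frames, ignore_index=True)
        df = df.sort_values(["time", "tag_id"], kind="stable").reset_index(drop=True)
        df = _inject_group_gaps(df, r, config, rng, max_age)
        # handling: birds out of the pen during weighing / band checks
        hs, he = config.handling_window
        for age in config.weigh_days(r):
            if r.start_age < age <= max_age:
                date = pd.Timestamp(r.date_of_age(age))
                t0, t1 = date + pd.Timedelta(seconds=hs), date + pd.Timedelta(seconds=he)
                t = df["time"].to_numpy()
                df = df.loc[~((t >= np.datetime64(t0)) & (t < np.datetime64(t1)))]
                handling.append({"start": t0.isoformat(), "end": t1.isoformat(),
                                 "reason": "handling"})
        rfid[r.round_id] = df.reset_index(drop=True)

    weights = pd.concat(weight_frames, ignore_index=True)
    truth = pd.DataFrame([dataclasses.asdict(p) for p in params])

    result = {"rfid": rfid, "weights": weights, "truth": truth,
              "rounds": config.rounds, "roster": roster,
              "handling_windows": handling}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for rid, df in rfid.items():
            path = outdir / f"rfid_round{rid}.csv"
            out = df.copy()
            out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
            out.to_csv(path, index=False)
            paths[f"rfid_round{rid}"] = path
        weights.to_csv(outdir / "weights.csv", index=False)
        truth.to_csv(outdir / "sim_truth.csv", index=False)
        metadata_to_yaml(config.rounds, outdir / "rounds.yaml", roster=roster,
                         handling_windows=handling)
        paths.update({"weights": outdir / "weights.csv",
                      "truth": outdir / "sim_truth.csv",
                      "rounds": outdir / "rounds.yaml"})
        result["paths"] = paths
    return result
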