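"""Configuration objects shared across the pipeline.

Times of day are expressed as integer seconds since midnight; ages as
integer days. Defaults mirror a commercial broiler setup: a 1.8 x 2.6 m
pen carpeted with a 5 x 6 grid of floor antennas, a 07:00-23:00 main
light period, and dark periods 23:00-03:00 and 05:00-07:00.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import yaml

SECONDS_PER_DAY = 86_400

#: Main light period used for all activity computation (07:00-23:00).
LIGHT_START_S = 7 * 3600
LIGHT_END_S = 23 * 3600
LIGHT_SECONDS = LIGHT_END_S - LIGHT_START_S  # 57,600 s

#: Dark intervals within a single calendar day (23:00-03:00 wraps midnight).
DEFAULT_DARK_PERIODS = ((0, 3 * 3600), (5 * 3600, 7 * 3600), (23 * 3600, SECONDS_PER_DAY))


@dataclass(frozen=True)
class DaySchedule:
    """Light/dark structure of one day.

    ``light_period`` is the analysis window; ``dark_periods`` are the
    intervals during which birds are near-inactive (movement damped by
    :attr:`SimConfig.dark_move_factor` in the simulator).
    """

    light_period: tuple[int, int] = (LIGHT_START_S, LIGHT_END_S)
    dark_periods: tuple[tuple[int, int], ...] = DEFAULT_DARK_PERIODS

    def __post_init__(self) -> None:
        s, e = self.light_period
        if not (0 <= s < e <= SECONDS_PER_DAY):
            raise ValueError(f"invalid light period {self.light_period}")
        periods = sorted(self.dark_periods)
        for (s0, e0), (s1, e1) in zip(periods, periods[1:]):
            if e0 > s1:
                raise ValueError("dark periods overlap")
        for s0, e0 in periods:
            if not (0 <= s0 < e0 <= SECONDS_PER_DAY):
                raise ValueError(f"dark period {(s0, e0)} outside 00:00-24:00")

    @property
    def light_seconds(self) -> int:
        return self.light_period[1] - self.light_period[0]

    def is_dark(self, second_of_day: int) -> bool:
        return any(s <= second_of_day < e for s, e in self.dark_periods)


@dataclass(frozen=True)
class RoundSpec:
    """One production round: its age span, headcount and calendar anchor."""

    round_id: int
    start_age: int
    end_age: int
    n_birds: int
    start_date: dt.date

    def __post_init__(self) -> None:
        if self.end_age <= self.start_age:
            raise ValueError("end_age must exceed start_age")
        if self.n_birds <= 0:
            raise ValueError("n_birds must be positive")

    def date_of_age(self, age: int) -> dt.date:
        return self.start_date + dt.timedelta(days=age - self.start_age)

    def age_of_date(self, date: dt.date) -> int:
        return self.start_age + (date - self.start_date).days


def default_rounds() -> tuple[RoundSpec, ...]:
    """Five consecutive rounds of male broilers (start age, end age, n)."""
    base = dt.date(2021, 3, 1)
    table = [(1, 1, 36, 80), (2, 1, 33, 82), (3, 0, 35, 82), (4, 1, 35, 78), (5, 1, 33, 80)]
    return tuple(
        RoundSpec(rid, sa, ea, n, base + dt.timedelta(days=49 * (rid - 1)))
        for rid, sa, ea, n in table
    )


@dataclass(frozen=True)
class GapModel:
    """Group-level sensor outages: Poisson arrivals, exponential excess length.

    Durations are ``min_duration_s`` plus an exponential excess, keeping every
    injected outage above the 300 s exclusion threshold so it is detectable.
    ``rate_per_day`` = 0 disables injection.
    """

    rate_per_day: float = 0.15
    min_duration_s: float = 330.0
    mean_excess_s: float = 300.0

    def __post_init__(self) -> None:
        if self.rate_per_day < 0 or self.min_duration_s < 0 or self.mean_excess_s < 0:
            raise ValueError("gap model parameters must be non-negative")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of a simulated multi-round experiment."""

    rounds: tuple[RoundSpec, ...] = field(default_factory=default_rounds)
    pen_width_m: float = 1.8
    pen_length_m: float = 2.6
    grid_cols: int = 5
    grid_rows: int = 6
    schedule: DaySchedule = field(default_factory=DaySchedule)
    seed: int = 0
    gap_model: GapModel = field(default_factory=GapModel)
    weigh_interval_days: int = 7
    #: RFID is only generated up to this age; the activity descriptors use
    #: ages <= 15 d only, so later days would only inflate the fixtures.
    rfid_max_age: int = 15
    #: "sparse" emits a registration per antenna switch plus a once-a-minute
    #: heartbeat; "full" emits the true 1 Hz stream for every antenna.
    registration_mode: str = "sparse"
    dark_move_factor: float = 0.05
    mean_active_bout_min: float = 5.0
    mean_inactive_bout_min: float = 5.0
    #: Handling window (band checks / weighing) applied on weigh days.
    handling_window: tuple[int, int] = (10 * 3600, 11 * 3600)

    def __post_init__(self) -> None:
        if self.grid_cols <= 0 or self.grid_rows <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pen_width_m <= 0 or self.pen_length_m <= 0:
            raise ValueError("pen dimensions must be positive")
        if self.registration_mode not in ("sparse", "full"):
            raise ValueError("registration_mode must be 'sparse' or 'full'")
        if not (0 <= self.dark_move_factor <= 1):
            raise ValueError("dark_move_factor must be in [0, 1]")
        ids = {r.round_id for r in self.rounds}
        if len(ids) != len(self.rounds):
            raise ValueError("duplicate round ids")

    @property
    def n_antennas(self) -> int:
        return self.grid_cols * self.grid_rows

    def weigh_days(self, round_spec: RoundSpec) -> list[int]:
        """Weighing ages for one round: weekly from the start age, plus the
        final day of the round (end weight)."""
        days = list(range(round_spec.start_age, round_spec.end_age + 1, self.weigh_interval_days))
        if days[-1] != round_spec.end_age:
            days.append(round_spec.end_age)
        return days


@dataclass(frozen=True)
class Priors:
    """Population distributions of the per-bird generating parameters.

    Defaults are calibrated so a simulated cohort lands in the realistic
    range for fast-growing male broilers tracked over their first two
    weeks: mean distance moved around 19-20 m/h and declining with age,
    trend-residual SD around 3.5-4 m/h, mildly positive day-to-day
    autocorrelation, and ADG near 77 g/d weakly and negatively coupled to
    activity variability.
    """

    a_mean: float = 24.0     # activity intercept at age 0, m/h
    a_sd: float = 4.0
    b_mean: float = -0.55    # daily decline, m/h per day
    b_sd: float = 0.15
    sigma_log_mean: float = 1.27   # lognormal day-to-day deviation SD, m/h
    sigma_log_sd: float = 0.42
    rho_mean: float = 0.2    # lag-1 AC of deviations, truncated normal
    rho_sd: float = 0.25
    rho_bound: float = 0.9
    reg_low: float = 0.2     # within-day regularity, uniform
    reg_high: float = 0.8
    w0_mean: float = 42.0    # start weight, g
    w0_sd: float = 3.0
    beta0: float = 64.6      # ADG model: beta0 + beta_sw*W0 + beta_rmse*sigma
    beta_sw: float = 0.4
    beta_rmse: float = -1.0
    adg_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        if min(self.a_sd, self.b_sd, self.sigma_log_sd, self.rho_sd, self.w0_sd) < 0:
            raise ValueError("prior SDs must be non-negative")
        if self.adg_noise_sd < 0:
            raise ValueError("adg_noise_sd must be non-negative")
        if not (0 <= self.rho_bound < 1):
            raise ValueError("rho_bound must lie in [0, 1)")
        if not (0 <= self.reg_low <= self.reg_high <= 1):
            raise ValueError("regularity prior must satisfy 0 <= low <= high <= 1")


# ---------------------------------------------------------------------------
# (De)serialization helpers


def _round_to_dict(r: RoundSpec) -> dict:
    d = dataclasses.asdict(r)
    d["start_date"] = r.start_date.isoformat()
    return d


def metadata_to_yaml(rounds: tuple[RoundSpec, ...], path, roster: dict | None = None,
                     handling_windows: list | None = None) -> None:
    """Round table (+ optional tag roster and handling windows) as YAML."""
    doc: dict = {"rounds": [_round_to_dict(r) for r in rounds]}
    if roster is not None:
        doc["roster"] = {int(k): list(v) for k, v in roster.items()}
    if handling_windows is not None:
        doc["handling_windows"] = list(handling_windows)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def metadata_from_yaml(path) -> dict:
    """Read round metadata; returns dict with keys rounds, roster,
    handling_windows (the latter two possibly None)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rounds = []
    for d in raw["rounds"]:
        d = dict(d)
        d["start_date"] = dt.date.fromisoformat(d["start_date"])
        rounds.append(RoundSpec(**d))
    roster = raw.get("roster")
    if roster is not None:
        roster = {int(k): list(v) for k, v in roster.items()}
    return {"rounds": tuple(rounds), "roster": roster,
            "handling_windows": raw.get("handling_windows")}
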