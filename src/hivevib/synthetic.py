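"""Synthetic hive-vibration generator with retrievable ground truth.

The accelerometer signal is modelled as a bee-generated stimulus filtered by
the comb it is embedded in.  The stimulus is a broadband pink floor with two
pronounced harmonic peaks centred on 125 Hz and 250 Hz, modulated diurnally
(quieter at night) and by a small night-to-night jitter.  The comb acts as a
load-dependent transfer function: the local comb load

    L(t) = a*brood(t) + b*honey(t) + c*pollen(t)

attenuates the measured amplitude by 1/(1 + kappa*L) — heavier comb, smaller
acceleration for the same stimulus — and additionally perturbs the spectral
shape (harmonic peaks widen by 20 % and shift down by 1 % per unit load), so
that shape alone carries brood-cycle information even after amplitude
normalization.  Brood near the sensor follows a raised-cosine cycle with a
period slightly above the 21-day worker development time; honey and pollen
follow slow piecewise-linear trajectories.  Colony events (primary swarm,
drone laying, winter broodlessness, failure) interrupt the cycle in the ways
a beekeeper would recognise.  A wall-mounted control sensor sees the raw
stimulus one order of magnitude weaker, with no load modulation at all.

Every simulated quantity is recoverable from the returned ground-truth
table, so downstream estimators (mode extraction, period recovery, the
load-attenuation regression, the discriminant indicator) can be tested
against the values the generator actually used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra_io import FREQ_MAX_HZ, SpectrumFrame, standard_axis

logger = logging.getLogger(__name__)

EVENT_KINDS = ("primary_swarm", "drone_laying", "winter", "failure")

#: Fraction of the day-time stimulus amplitude remaining at midnight.
NIGHT_FACTOR = 0.5
#: Wall channel is one order of magnitude weaker than the comb channel.
WALL_ATTENUATION = 10.0

# Stimulus shape constants (dimensionless, scaled by ColonyScenario.stimulus_level)
FLOOR_GAIN = 0.8
FLOOR_REF_HZ = 200.0
FLOOR_EXPONENT = 0.15
PEAK_FREQS_HZ = (125.0, 250.0)
PEAK_GAINS = (4.0, 2.5)
PEAK_WIDTHS_HZ = (12.0, 18.0)

# Transfer-function shape perturbation per unit load
WIDTH_BROADENING_PER_LOAD = 0.20
CENTRE_SHIFT_PER_LOAD = 0.01

# Drone-laying: the coherent cycle is replaced by low-amplitude jitter made of
# two incommensurate slow components with scenario-seeded phases.
DRONE_JITTER_LEVEL = 0.15
DRONE_JITTER_PERIODS_D = (9.3, 15.7)


@dataclass(frozen=True)
class Event:
    """A colony-level disturbance of the brood cycle."""

    kind: str
    start_date: date
    duration_days: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        if self.duration_days <= 0:
            raise ValueError("event duration must be positive")


@dataclass(frozen=True)
class ColonyScenario:
    """Ground-truth description of one simulated colony.

    Trajectories are piecewise-linear in normalised time: sequences of
    ``(fraction_of_span, value)`` with fractions in [0, 1] and values in
    [0, 1].  ``brood_amplitude`` is the peak fraction of near-sensor comb
    area occupied by brood; the brood cycle is a raised cosine of period
    ``brood_period_days`` offset by ``laying_phase_days`` (the paper-level
    observation that the oscillation phase differs between frames).
    """

    colony_id: str = "C01"
    start_date: date = date(2022, 4, 1)
    end_date: date = date(2022, 8, 29)  # 150 nights
    brood_period_days: float = 23.0
    laying_phase_days: float = 0.0
    brood_amplitude: float = 0.8
    honey_trajectory: tuple[tuple[float, float], ...] = ((0.0, 0.05), (1.0, 0.15))
    pollen_trajectory: tuple[tuple[float, float], ...] = ((0.0, 0.05), (1.0, 0.05))
    events: tuple[Event, ...] = ()
    stimulus_level: float = 4e-6  # m/s^2 scale of the bee-generated stimulus
    seed: int = 0
    # comb transfer function
    attenuation: tuple[float, float, float] = (0.6, 0.3, 0.1)  # (a, b, c) for brood/honey/pollen
    kappa: float = 3.0
    # noise
    noise_sigma: float = 0.10  # per-bin multiplicative log-normal sd
    night_jitter_sigma: float = 0.05  # night-to-night stimulus variability (sd of log)
    observer_sigma_pct: float = 5.0  # inspection noise, percentage points
    # per-colony spectral identity
    peak_width_scale: float = 1.0
    peak_gain_ratio: float = 1.0
    floor_tilt: float = 0.0  # additive spectral-slope deviation of the floor

    def __post_init__(self) -> None:
        validate_scenario(self)

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days

    def day_index(self, d: date) -> int:
        return (d - self.start_date).days


def validate_scenario(sc: ColonyScenario) -> None:
    if sc.end_date <= sc.start_date:
        raise ValueError("zero-length or inverted date range")
    if sc.brood_period_days <= 0:
        raise ValueError("brood_period_days must be positive")
    if not 0 <= sc.brood_amplitude <= 1:
        raise ValueError("brood_amplitude must lie in [0, 1]")
    for name, traj in (("honey", sc.honey_trajectory), ("pollen", sc.pollen_trajectory)):
        for frac, val in traj:
            if not (0 <= frac <= 1 and 0 <= val <= 1):
                raise ValueError(f"{name}_trajectory points must lie in [0,1] x [0,1]")
    # fraction budget: brood + honey + pollen must stay <= 1 at all times
    t = np.linspace(0, sc.n_days, 4 * sc.n_days + 1)
    total = (
        sc.brood_amplitude
        + _interp_trajectory(sc.honey_trajectory, t, sc.n_days)
        + _interp_trajectory(sc.pollen_trajectory, t, sc.n_days)
    )
    if np.any(total > 1 + 1e-9):
        raise ValueError("brood + honey + pollen fractions exceed 1 somewhere in the span")
    span = (sc.start_date, sc.end_date)
    for ev in sc.events:
        ev_end = ev.start_date + timedelta(days=ev.duration_days)
        if ev.start_date < span[0] or ev_end > span[1] + timedelta(days=1):
            raise ValueError(f"event {ev.kind} at {ev.start_date} lies outside the scenario dates")
    # overlapping events of different kinds are contradictory
    evs = sorted(sc.events, key=lambda e: e.start_date)
    for e1, e2 in zip(evs, evs[1:]):
        if e2.start_date < e1.start_date + timedelta(days=e1.duration_days) and e1.kind != e2.kind:
            raise ValueError(
                f"contradictory overlapping events: {e1.kind} at {e1.start_date} "
                f"and {e2.kind} at {e2.start_date}"
            )


def _interp_trajectory(
    traj: Sequence[tuple[float, float]], t_days: np.ndarray, n_days: int
) -> np.ndarray:
    pts = sorted(traj)
    xs = np.array([p[0] for p in pts]) * n_days
    ys = np.array([p[1] for p in pts])
    return np.interp(t_days, xs, ys)


# ---------------------------------------------------------------------------
# Ground-truth comb content as a function of time
# ---------------------------------------------------------------------------

def _event_mask(sc: ColonyScenario, t_days: np.ndarray, kind: str) -> np.ndarray:
    """Boolean mask of times (days since start) falling inside events of `kind`.

    ``failure`` extends to the end of the scenario; the event interval itself
    is the die-off ramp.
    """
    mask = np.zeros(t_days.shape, dtype=bool)
    for ev in sc.events:
        if ev.kind != kind:
            continue
        t0 = sc.day_index(ev.start_date)
        t1 = t0 + ev.duration_days
        if kind == "failure":
            mask |= t_days >= t0
        else:
            mask |= (t_days >= t0) & (t_days < t1)
    return mask


def _drone_jitter(sc: ColonyScenario, t_days: np.ndarray) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([sc.seed & 0x7FFFFFFF, 0xD0]))
    phases = rng.uniform(0, 2 * np.pi, size=len(DRONE_JITTER_PERIODS_D))
    x = np.full(t_days.shape, 0.5)
    for period, phase in zip(DRONE_JITTER_PERIODS_D, phases):
        x = x + 0.25 * np.sin(2 * np.pi * t_days / period + phase)
    return DRONE_JITTER_LEVEL * sc.brood_amplitude * np.clip(x, 0, 1)


def brood_fraction(sc: ColonyScenario, t_days: np.ndarray) -> np.ndarray:
    """Near-sensor brood fraction over time, events applied.

    The undisturbed cycle is a raised cosine of period ``brood_period_days``:
    cells fill with brood, are capped, and empty again as workers emerge.
    Winter and failure zero it; a primary swarm leaves a broodless gap for
    the event duration (default three weeks: no laying queen); drone laying
    destroys local synchrony, replacing the cycle with low-amplitude jitter.
    """
    t_days = np.asarray(t_days, dtype=float)
    phase = 2 * np.pi * (t_days - sc.laying_phase_days) / sc.brood_period_days
    brood = sc.brood_amplitude * 0.5 * (1 - np.cos(phase))
    dl = _event_mask(sc, t_days, "drone_laying")
    if dl.any():
        brood = np.where(dl, _drone_jitter(sc, t_days), brood)
    zero = (
        _event_mask(sc, t_days, "winter")
        | _event_mask(sc, t_days, "primary_swarm")
        | _event_mask(sc, t_days, "failure")
    )
    return np.where(zero, 0.0, brood)


def comb_fractions(sc: ColonyScenario, t_days: np.ndarray) -> pd.DataFrame:
    """Ground-truth brood/honey/pollen fractions at the given times (days)."""
    t_days = np.asarray(t_days, dtype=float)
    return pd.DataFrame(
        {
            "brood": brood_fraction(sc, t_days),
            "honey": _interp_trajectory(sc.honey_trajectory, t_days, sc.n_days),
            "pollen": _interp_trajectory(sc.pollen_trajectory, t_days, sc.n_days),
        },
        index=t_days,
    )


def local_load(sc: ColonyScenario, t_days: np.ndarray) -> np.ndarray:
    """Local comb load L(t) = a*brood + b*honey + c*pollen, always >= 0."""
    fr = comb_fractions(sc, t_days)
    a, b, c = sc.attenuation
    return a * fr["brood"].to_numpy() + b * fr["honey"].to_numpy() + c * fr["pollen"].to_numpy()


def _stimulus_scale(sc: ColonyScenario, t_days: np.ndarray) -> np.ndarray:
    """Slow decay of the stimulus itself when a colony fails (bees die off)."""
    scale = np.ones(np.asarray(t_days, dtype=float).shape)
    for ev in sc.events:
        if ev.kind != "failure":
            continue
        t0 = sc.day_index(ev.start_date)
        ramp = np.clip((np.asarray(t_days, dtype=float) - t0) / ev.duration_days, 0, 1)
        scale = scale * (1 - 0.9 * ramp)
    return scale


def diurnal_factor(hour: np.ndarray | float) -> np.ndarray | float:
    """Smooth day/night stimulus modulation: 0.5 at midnight, 1.0 at noon."""
    h = np.asarray(hour, dtype=float)
    out = (1 + NIGHT_FACTOR) / 2 - (1 - NIGHT_FACTOR) / 2 * np.cos(2 * np.pi * h / 24)
    return float(out) if np.isscalar(hour) else out


# ---------------------------------------------------------------------------
# Spectrum synthesis
# ---------------------------------------------------------------------------

def stimulus_floor(freqs: np.ndarray, tilt: float = 0.0) -> np.ndarray:
    """Dimensionless pink broadband floor of the bee-generated stimulus.

    ``tilt`` adds a colony-specific linear slope (in log-frequency) on top
    of the shared pink roll-off: a load-independent component of each
    hive's vibrational identity.  It enters the spectrum linearly, so
    colony identity spans a flat plane in spectrum space."""
    base = FLOOR_GAIN * (1 + freqs / FLOOR_REF_HZ) ** (-FLOOR_EXPONENT)
    ramp = np.log1p(freqs / FLOOR_REF_HZ) / np.log1p(FREQ_MAX_HZ / FLOOR_REF_HZ) - 0.5
    return base * (1 + tilt * ramp)


def _peak_params(sc: ColonyScenario, load: np.ndarray):
    """Per-time harmonic centre/width/gain after the load-shape perturbation."""
    load = np.atleast_1d(np.asarray(load, dtype=float))[:, None]  # (t, 1)
    centres = np.array(PEAK_FREQS_HZ)[None, :] * (1 - CENTRE_SHIFT_PER_LOAD * load)
    widths = (
        np.array(PEAK_WIDTHS_HZ)[None, :]
        * sc.peak_width_scale
        * (1 + WIDTH_BROADENING_PER_LOAD * load)
    )
    gains = np.array(PEAK_GAINS) * np.array([sc.peak_gain_ratio, 1.0])
    return centres, widths, np.broadcast_to(gains[None, :], centres.shape)


def _shape_matrix(sc: ColonyScenario, freqs: np.ndarray, load: np.ndarray) -> np.ndarray:
    """Dimensionless stimulus-as-measured shape, one row per time point."""
    centres, widths, gains = _peak_params(sc, load)
    shape = np.broadcast_to(
        stimulus_floor(freqs, sc.floor_tilt)[None, :], (centres.shape[0], freqs.size)
    ).copy()
    for k in range(centres.shape[1]):
        shape += gains[:, k, None] * np.exp(
            -((freqs[None, :] - centres[:, k, None]) ** 2) / (2 * widths[:, k, None] ** 2)
        )
    return shape


def clean_comb_amplitude(
    sc: ColonyScenario, freqs: np.ndarray, t_days: float, night_jitter: float = 1.0
) -> np.ndarray:
    """Noise-free comb spectrum at one instant, directly from ground truth.

    This closed form — stimulus_level x jitter x diurnal x shape(f, L) /
    (1 + kappa*L), evaluated outside the simulation loop — is the oracle the
    test suite compares simulated frames against.
    """
    L = local_load(sc, np.array([t_days]))
    hour = (t_days % 1.0) * 24
    g = diurnal_factor(hour)
    stim = sc.stimulus_level * _stimulus_scale(sc, np.array([t_days]))[0] * night_jitter * g
    return (stim * _shape_matrix(sc, freqs, L) / (1 + sc.kappa * L[:, None]))[0]


def _day_rng(sc: ColonyScenario, day_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([sc.seed & 0x7FFFFFFF, day_idx]))


def simulate_day_window(
    sc: ColonyScenario,
    day: date,
    sensor: str = "comb",
    hours: tuple[float, float] = (0.0, 24.0),
    freqs: np.ndarray | None = None,
) -> list[SpectrumFrame]:
    """Frames at 3-minute cadence for one civil day restricted to ``hours``.

    Seeding is hierarchical per (colony seed, day index), so simulating day
    by day or all at once yields the same night-to-night jitter stream.
    """
    if sensor not in ("comb", "wall"):
        raise ValueError("sensor must be 'comb' or 'wall'")
    if freqs is None:
        freqs = standard_axis()
    day_idx = sc.day_index(day)
    if not 0 <= day_idx < sc.n_days:
        raise ValueError(f"{day} outside scenario range")
    rng = _day_rng(sc, day_idx)
    jitter = float(np.exp(rng.normal(0.0, sc.night_jitter_sigma))) if sc.night_jitter_sigma > 0 else 1.0

    minutes = np.arange(hours[0] * 60, hours[1] * 60, 3.0)
    t_days = day_idx + minutes / (60 * 24)
    L = local_load(sc, t_days)
    g = diurnal_factor(minutes / 60)
    stim = sc.stimulus_level * jitter * _stimulus_scale(sc, t_days) * g

    if sensor == "comb":
        shape = _shape_matrix(sc, freqs, L)
        amps = stim[:, None] * shape / (1 + sc.kappa * L[:, None])
    else:
        shape = _shape_matrix(sc, freqs, np.zeros_like(L))
        amps = stim[:, None] * shape / WALL_ATTENUATION

    if sc.noise_sigma > 0:
        z = rng.standard_normal(amps.shape)
        amps = amps * np.exp(sc.noise_sigma * z - 0.5 * sc.noise_sigma**2)

    base = datetime.combine(day, time(0, 0))
    return [
        SpectrumFrame(
            timestamp=base + timedelta(minutes=float(m)),
            colony_id=sc.colony_id,
            sensor=sensor,
            freqs=freqs,
            amps=amps[i],
        )
        for i, m in enumerate(minutes)
    ]


def ground_truth(sc: ColonyScenario, night_hour: float = 3.0) -> pd.DataFrame:
    """Per-night ground-truth table (indexed by date, evaluated at 03:00).

    Columns: brood/honey/pollen fractions, load L, stimulus scale, the
    night's jitter draw, the diurnal factor at the evaluation hour, and the
    active event kind (empty string if none).  Generator constants needed to
    reconstruct amplitudes in closed form are stored in ``df.attrs``.
    """
    dates = [sc.start_date + timedelta(days=i) for i in range(sc.n_days)]
    t = np.arange(sc.n_days) + night_hour / 24
    fr = comb_fractions(sc, t)
    df = pd.DataFrame(
        {
            "brood": fr["brood"].to_numpy(),
            "honey": fr["honey"].to_numpy(),
            "pollen": fr["pollen"].to_numpy(),
            "load": local_load(sc, t),
            "stimulus_scale": _stimulus_scale(sc, t),
            "night_jitter": [
                float(np.exp(_day_rng(sc, i).normal(0.0, sc.night_jitter_sigma)))
                if sc.night_jitter_sigma > 0
                else 1.0
                for i in range(sc.n_days)
            ],
            "g_night": diurnal_factor(np.full(sc.n_days, night_hour)),
        },
        index=pd.Index(dates, name="date"),
    )
    df["event"] = ""
    for ev in sc.events:
        end = (
            sc.end_date
            if ev.kind == "failure"
            else ev.start_date + timedelta(days=int(np.ceil(ev.duration_days)))
        )
        in_ev = [(ev.start_date <= d < end) for d in dates]
        df.loc[in_ev, "event"] = ev.kind
    df.attrs.update(
        stimulus_level=sc.stimulus_level,
        kappa=sc.kappa,
        attenuation=sc.attenuation,
        floor_gain=FLOOR_GAIN,
        floor_ref_hz=FLOOR_REF_HZ,
        floor_exponent=FLOOR_EXPONENT,
        peak_freqs_hz=PEAK_FREQS_HZ,
        peak_gains=PEAK_GAINS,
        peak_widths_hz=PEAK_WIDTHS_HZ,
    )
    return df


def simulate_colony(
    scenario: ColonyScenario,
    sensor: str = "comb",
    hours: tuple[float, float] = (0.0, 24.0),
) -> tuple[list[SpectrumFrame], pd.DataFrame]:
    """Simulate every day of a scenario; returns (frames, ground-truth table).

    ``hours`` restricts each day to a clock window (e.g. ``(0, 6)`` for the
    night window only), which keeps long runs memory-light without changing
    any generated value inside the window.
    """
    frames: list[SpectrumFrame] = []
    for i in range(scenario.n_days):
        day = scenario.start_date + timedelta(days=i)
        frames.extend(simulate_day_window(scenario, day, sensor=sensor, hours=hours))
    return frames, ground_truth(scenario)


# ---------------------------------------------------------------------------
# Apiaries
# ---------------------------------------------------------------------------

def _maximin_points(n: int) -> np.ndarray:
    """n points in the unit square with large minimum pairwise distance.

    Greedy farthest-point selection over a fine grid, started from the
    corners; deterministic in n."""
    g = np.linspace(0.0, 1.0, 21)
    cand = np.array([(x, y) for x in g for y in g])
    chosen = [np.array([0.0, 0.0]), np.array([1.0, 1.0]), np.array([1.0, 0.0]), np.array([0.0, 1.0])]
    chosen = chosen[:n]
    while len(chosen) < n:
        d = np.min(
            np.linalg.norm(cand[:, None, :] - np.array(chosen)[None, :, :], axis=2), axis=1
        )
        chosen.append(cand[int(np.argmax(d))])
    return np.array(chosen[:n])


def _colony_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31))


def make_apiary_scenarios(
    n_colonies: int,
    master_seed: int,
    scenario_overrides: Mapping[int, Mapping[str, object]] | None = None,
    base: ColonyScenario | None = None,
) -> list[ColonyScenario]:
    """Deterministically draw ``n_colonies`` scenario variants.

    Colonies differ in brood period (uniform over 21.5-25.5 d), phase, peak
    brood coverage, overall vibrational strength and spectral identity
    (harmonic width/gain-ratio), emulating the between-hive spread of a
    monitored apiary.  ``scenario_overrides`` maps colony index -> field
    overrides (e.g. to give one colony a swarm event).
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    base = base or ColonyScenario()
    # Spectral-identity dimensions (harmonic gain ratio, floor tilt) are laid
    # out on a maximin point set rather than drawn i.i.d.: every pair of
    # colonies is then well separated in the identity plane, emulating the
    # distinct per-hive vibrational fingerprints of a real apiary instead of
    # letting two hives coincide spectrally by chance.
    perm_rng = np.random.default_rng(np.random.SeedSequence([master_seed, 101]))
    ident_perm = perm_rng.permutation(n_colonies)
    ident_points = _maximin_points(n_colonies)

    out = []
    for i in range(n_colonies):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, i, 7]))
        period = rng.uniform(21.5, 25.5)
        fields: dict[str, object] = dict(
            colony_id=f"C{i + 1:02d}",
            seed=_colony_seed(master_seed, i),
            brood_period_days=float(period),
            laying_phase_days=float(rng.uniform(0, period)),
            brood_amplitude=float(rng.uniform(0.60, 0.84)),
            stimulus_level=float(base.stimulus_level * np.exp(rng.normal(0.0, 0.3))),
            honey_trajectory=((0.0, float(rng.uniform(0.04, 0.07))), (1.0, float(rng.uniform(0.09, 0.12)))),
            pollen_trajectory=((0.0, float(rng.uniform(0.01, 0.02))), (1.0, float(rng.uniform(0.01, 0.02)))),
            # Identity spread: gain ratio and floor tilt are load-independent,
            # so they can be wide; the width scale confounds the load axis
            # (load broadens the harmonics), so its spread stays well below
            # the load broadening.
            peak_width_scale=float(rng.uniform(0.9975, 1.0025)),
            peak_gain_ratio=float(0.70 + 0.6 * ident_points[int(ident_perm[i]), 0]),
            floor_tilt=float(-0.40 + 0.8 * ident_points[int(ident_perm[i]), 1]),
        )
        if scenario_overrides and i in scenario_overrides:
            fields.update(scenario_overrides[i])
        out.append(replace(base, **fields))
    return out


def simulate_apiary(
    n_colonies: int,
    master_seed: int,
    scenario_overrides: Mapping[int, Mapping[str, object]] | None = None,
    sensor: str = "comb",
    hours: tuple[float, float] = (0.0, 24.0),
    base: ColonyScenario | None = None,
) -> dict[str, tuple[list[SpectrumFrame], pd.DataFrame]]:
    """Simulate a whole apiary; same master_seed => bit-identical dataset."""
    scenarios = make_apiary_scenarios(n_colonies, master_seed, scenario_overrides, base)
    return {
        sc.colony_id: simulate_colony(sc, sensor=sensor, hours=hours) for sc in scenarios
    }


# ---------------------------------------------------------------------------
# Frame inspections
# ---------------------------------------------------------------------------

def simulate_inspections(
    scenario: ColonyScenario,
    dates: Iterable[date],
    side_noise_correlation: float = 0.8,
) -> pd.DataFrame:
    """Visual frame-condition records (both sides) at the given dates.

    Recorded percentages are the ground-truth fractions x 100 plus seeded
    observer noise (sd ``scenario.observer_sigma_pct``, clipped to [0, 100]).
    The two sides of a frame share most of their noise, reproducing the
    close side-to-side agreement of real inspections.
    """
    rows = []
    rho = side_noise_correlation
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed & 0x7FFFFFFF, 0x1A5]))
    for d in dates:
        idx = scenario.day_index(d)
        if not 0 <= idx < scenario.n_days:
            raise ValueError(f"inspection date {d} outside scenario range")
        fr = comb_fractions(scenario, np.array([float(idx)])).iloc[0]
        for side in ("A", "B"):
            rows.append({"colony_id": scenario.colony_id, "date": d, "side": side})
        for quantity in ("brood", "honey", "pollen"):
            z_common = rng.standard_normal()
            z_sides = rng.standard_normal(2)
            for j, side_row in enumerate(rows[-2:]):
                noise = scenario.observer_sigma_pct * (
                    rho * z_common + np.sqrt(1 - rho**2) * z_sides[j]
                )
                side_row[f"{quantity}_pct"] = float(np.clip(100 * fr[quantity] + noise, 0, 100))
    return pd.DataFrame(rows)


def default_inspection_dates(scenario: ColonyScenario, n: int = 7) -> list[date]:
    """Evenly spaced inspection dates across the scenario span (default 7,
    mirroring a March-October visual-assessment campaign)."""
    idx = np.linspace(0, scenario.n_days - 1, n).round().astype(int)
    return [scenario.start_date + timedelta(days=int(i)) for i in idx]
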