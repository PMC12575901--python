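"""Synthetic key-press simulator.

No response model is published for this task; the simulator is an artifact
convention that produces press logs with the statistical structure the
analysis assumes — a shared, change-driven component (participants tend to
mark boundaries where the map's global value moves) plus individual-level
variability, empty trials, and post-video contaminant presses. Its
parameters are not estimates of human behavior.

The per-second press hazard is linear-clipped:

    hazard_t = clip(base_rate + s * (change_gain * |dg_t|
                                     + congruence_gain * c_t), 0, 1)

where dg_t is the one-second change of the stimulus's global value series,
c_t = |dg_t| when the stimulus trend direction matches the framing
expectation (invasive -> increase, endangered -> decrease) and 0 otherwise,
and s is a salience multiplier (< 1 in the low-salience condition: hue color
scales or spatially distributed change). The multiplier scales both gain
terms so that the congruence effect is salience-dependent, which is what
lets the inference stage exhibit the trend x framing x salience interaction
on synthetic cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .stimgen import (
    RegionMap,
    StimulusDesign,
    ValueSeries,
    build_region_map,
    enumerate_design,
    generate_series,
    select_changing_regions,
)
from shapely.geometry import box

__all__ = [
    "ResponseModelParams",
    "ResponseLog",
    "press_hazard",
    "simulate_cohort",
    "make_paper_fixture",
    "PaperFixture",
]

_LOW_SALIENCE = ("hue", "distributed")


@dataclass(frozen=True)
class ResponseModelParams:
    """Simulator parameters (artifact conventions, not behavioral estimates).

    base_rate        per-second press hazard with no stimulus drive, in (0, 1)
    change_gain      weight on |one-second change of the global value|
    congruence_gain  weight on the framing-congruent change term
    participant_sd   sd of the per-participant log-hazard intercept
    refractory_s     minimum inter-press gap (matches the 0.5 s debounce)
    low_salience_multiplier  factor on both gains under low salience
    """

    base_rate: float = 0.06
    change_gain: float = 2.0
    congruence_gain: float = 2.0
    participant_sd: float = 0.4
    refractory_s: float = 0.5
    low_salience_multiplier: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.base_rate < 1.0:
            raise ValueError("base_rate must be in (0, 1)")
        if self.change_gain < 0 or self.participant_sd < 0:
            raise ValueError("change_gain and participant_sd must be >= 0")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")


@dataclass(frozen=True)
class ResponseLog:
    """Ordered press times of one participant on one stimulus."""

    participant_id: str
    stimulus_id: str
    group: str
    press_times_s: tuple[float, ...]

    def __post_init__(self):
        t = self.press_times_s
        if any(b <= a for a, b in zip(t, t[1:])) or (t and t[0] < 0):
            raise ValueError("press times must be non-negative and strictly increasing")

    @property
    def n_presses(self) -> int:
        return len(self.press_times_s)


def _congruent(design: StimulusDesign) -> bool:
    if design.framing == "invasive":
        return design.trend_level > 0
    if design.framing == "endangered":
        return design.trend_level < 0
    return False


def press_hazard(series: ValueSeries, design: StimulusDesign,
                 params: ResponseModelParams) -> np.ndarray:
    """Per-second press hazard, length ``duration_s``."""
    if series.duration_s != design.duration_s:
        raise ValueError("series and design durations do not match")
    dg = np.abs(np.diff(series.global_series))
    c = dg if _congruent(design) else np.zeros_like(dg)
    s = (params.low_salience_multiplier
         if design.salience_factor in _LOW_SALIENCE else 1.0)
    hazard = params.base_rate + s * (params.change_gain * dg
                                     + params.congruence_gain * c)
    return np.clip(hazard, 0.0, 1.0)


def _thin_refractory(times: np.ndarray, gap: float) -> list[float]:
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= gap:
            kept.append(float(t))
    return kept


def simulate_cohort(designs: list[StimulusDesign],
                    series_by_stimulus: dict[str, ValueSeries],
                    n_participants: int,
                    params: ResponseModelParams,
                    seed: int = 0,
                    group: str = "all",
                    participant_prefix: str = "p") -> list[ResponseLog]:
    """Simulate one cohort of press logs, fully seed-deterministic.

    Each participant gets a lognormal hazard multiplier exp(N(0, sd)); per
    stimulus second a press is a Bernoulli draw from the clipped adjusted
    hazard, placed uniformly within its second, then thinned to respect the
    refractory gap.
    """
    missing = [d.stimulus_id for d in designs if d.stimulus_id not in series_by_stimulus]
    if missing:
        raise ValueError(f"no series for stimuli: {missing}")
    if n_participants < 2:
        warnings.warn("agreement needs at least 2 participants", stacklevel=2)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 11])
    hazards = {d.stimulus_id: press_hazard(series_by_stimulus[d.stimulus_id], d, params)
               for d in designs}
    logs: list[ResponseLog] = []
    for i in range(n_participants):
        delta = rng.normal(0.0, params.participant_sd)
        pid = f"{participant_prefix}{i:04d}"
        for d in designs:
            h = np.clip(hazards[d.stimulus_id] * np.exp(delta), 0.0, 1.0)
            fired = rng.random(d.duration_s) < h
            offsets = rng.random(d.duration_s)
            times = (np.nonzero(fired)[0] + offsets[fired]).astype(float)
            kept = _thin_refractory(np.sort(times), params.refractory_s)
            logs.append(ResponseLog(participant_id=pid, stimulus_id=d.stimulus_id,
                                    group=group, press_times_s=tuple(kept)))
    return logs


# ---------------------------------------------------------------------------
# Fixtures with the published trial accounting
# ---------------------------------------------------------------------------

# (n_participants, n_stimuli, empty trials, post-end trials) per experiment
_FIXTURE_SHAPE = {2: (117, 31, 267, 11), 3: (176, 32, 395, 13)}


@dataclass(frozen=True)
class PaperFixture:
    designs: list[StimulusDesign]
    series_by_stimulus: dict[str, ValueSeries]
    logs: list[ResponseLog]
    region_map: RegionMap | None = None


def make_paper_fixture(experiment: int, seed: int = 0,
                       params: ResponseModelParams | None = None) -> PaperFixture:
    """Cohort with the published trial bookkeeping.

    Experiment 2: 117 participants x 31 stimuli (one factorial cell was lost
    to a presentation error, so the trend 1 / hue / invasive stimulus is
    dropped) with exactly 267 empty logs and 11 logs whose only presses fall
    after the video end. Experiment 3: 176 x 32 with 395 empty and 13
    post-end logs. Defective-log placement is seed-random; counts are exact
    by construction.
    """
    if experiment not in _FIXTURE_SHAPE:
        raise ValueError("experiment must be 2 or 3")
    n_part, n_stim, n_empty, n_postend = _FIXTURE_SHAPE[experiment]
    params = params or ResponseModelParams()
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 12])

    designs = enumerate_design(experiment)
    region_map = None
    if experiment == 2:
        designs = [d for d in designs
                   if not (d.trend_level == 1.0 and d.salience_factor == "hue"
                           and d.framing == "invasive")]
    else:
        region_map = build_region_map(box(0, 0, 1, 1), 10,
                                      seed=int(rng.integers(2**31)))
        designs = [
            d.with_regions(select_changing_regions(
                region_map, d.salience_factor, d.n_changing,
                seed=int(rng.integers(2**31))))
            for d in designs
        ]
    assert len(designs) == n_stim
    designs = [replace(d, seed=int(rng.integers(2**31))) for d in designs]
    series = {d.stimulus_id: generate_series(d, region_map) for d in designs}
    logs = simulate_cohort(designs, series, n_part, params,
                           seed=int(rng.integers(2**31)))

    # Reconcile to the exact defective-log counts: the simulator produces
    # natural empty trials too, so surplus empties get one injected press and
    # any shortfall is cleared, before the post-end contaminants are placed.
    dur = designs[0].duration_s
    fixed: list[ResponseLog] = list(logs)
    empty_idx = [i for i, lg in enumerate(fixed) if not lg.press_times_s]
    nonempty_idx = [i for i, lg in enumerate(fixed) if lg.press_times_s]
    if len(empty_idx) > n_empty:
        surplus = rng.choice(empty_idx, size=len(empty_idx) - n_empty,
                             replace=False)
        for idx in surplus:
            t0 = round(float(rng.uniform(0.0, dur - 0.01)), 3)
            fixed[idx] = replace(fixed[idx], press_times_s=(t0,))
    elif len(empty_idx) < n_empty:
        extra = rng.choice(nonempty_idx, size=n_empty - len(empty_idx),
                           replace=False)
        for idx in extra:
            fixed[idx] = replace(fixed[idx], press_times_s=())
    nonempty_idx = [i for i, lg in enumerate(fixed) if lg.press_times_s]
    for idx in rng.choice(nonempty_idx, size=n_postend, replace=False):
        t0 = dur + float(rng.uniform(0.1, 2.0))
        fixed[idx] = replace(fixed[idx], press_times_s=(round(t0, 3),))
    assert sum(not lg.press_times_s for lg in fixed) == n_empty
    assert sum(bool(lg.press_times_s) and max(lg.press_times_s) > dur
               for lg in fixed) == n_postend
    return PaperFixture(designs=designs, series_by_stimulus=series, logs=fixed,
                        region_map=region_map)
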