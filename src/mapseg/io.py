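"""Formats, configuration and the end-to-end pipeline.

Storage conventions: long (tidy) CSV everywhere — one row per press in the
log file, one row per trial in the trial manifest, one row per record in
the agreement table; JSON for design manifests and null/power summaries;
GeoJSON for region geometry. Times are seconds as decimals.

``run_pipeline`` executes generate -> simulate -> filter -> agreement ->
null/specificity -> fit for one experiment and writes every intermediate
artifact plus a machine-readable audit (filter counts, seeds, parameters),
so any downstream table can be regenerated from the run directory alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement as agr
from . import inference as inf
from .responses import (PaperFixture, ResponseLog, ResponseModelParams,
                        make_paper_fixture, simulate_cohort)
from .stimgen import (RegionMap, StimulusDesign, build_region_map,
                      enumerate_design, generate_exp1_series, generate_series,
                      select_changing_regions)
from shapely.geometry import box

__all__ = [
    "PipelineConfig",
    "read_response_logs",
    "write_response_logs",
    "write_designs",
    "read_designs",
    "write_values",
    "run_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs; defaults match the analysis
    constants (1-s bins, 0.5-s debounce, 10,000 null iterations, alpha .05).
    """

    experiment: int = 2
    seed: int = 0
    out_dir: str = "mapseg_run"
    n_participants: int | None = None  # default: 80 / 117 / 176 per experiment
    n_stimuli_exp1: int = 15
    duration_exp1_s: int = 60
    noise_sd: float = 0.1
    use_fixture: bool = True  # experiments 2/3: published trial bookkeeping
    null_iterations: int = 10_000
    debounce_window_s: float = agr.DEBOUNCE_WINDOW_S
    alpha: float = 0.05
    response_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def params(self) -> ResponseModelParams:
        return ResponseModelParams(**self.response_params)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_LOG_COLS = ["participant_id", "stimulus_id", "group", "press_time_s"]
_TRIAL_COLS = ["participant_id", "stimulus_id", "group"]


def write_response_logs(logs: list[ResponseLog], log_path, manifest_path) -> None:
    press_rows, trial_rows = [], []
    for lg in logs:
        trial_rows.append({"participant_id": lg.participant_id,
                           "stimulus_id": lg.stimulus_id, "group": lg.group})
        for t in lg.press_times_s:
            press_rows.append({"participant_id": lg.participant_id,
                               "stimulus_id": lg.stimulus_id,
                               "group": lg.group, "press_time_s": t})
    pd.DataFrame(press_rows, columns=_LOG_COLS).to_csv(log_path, index=False)
    pd.DataFrame(trial_rows, columns=_TRIAL_COLS).to_csv(manifest_path, index=False)


def read_response_logs(log_path, manifest_path=None) -> list[ResponseLog]:
    """Read a press-log CSV (+ trial manifest) back into ResponseLogs.

    Trials present in the manifest but absent from the presses are
    materialized as empty logs. Malformed rows raise with line numbers.
    """
    df = pd.read_csv(log_path) if Path(log_path).stat().st_size else pd.DataFrame(columns=_LOG_COLS)
    if df.empty and list(df.columns) != _LOG_COLS:
        df = pd.DataFrame(columns=_LOG_COLS)
    missing = [c for c in _LOG_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"log file missing columns: {missing}")
    times = pd.to_numeric(df["press_time_s"], errors="coerce")
    bad = df.index[times.isna() & df["press_time_s"].notna()]
    if len(bad):
        raise ValueError(f"non-numeric press_time_s at CSV lines {[i + 2 for i in bad]}")
    df["press_time_s"] = times
    dup = df.duplicated(subset=_LOG_COLS, keep=False)
    if dup.any():
        raise ValueError(
            f"duplicate (participant, stimulus, time) rows at CSV lines "
            f"{[i + 2 for i in df.index[dup]]}")

    grouped: dict[tuple[str, str, str], list[float]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.participant_id), str(row.stimulus_id), str(row.group))
        grouped.setdefault(key, []).append(float(row.press_time_s))
    if manifest_path is not None:
        man = pd.read_csv(manifest_path)
        for row in man.itertuples(index=False):
            grouped.setdefault(
                (str(row.participant_id), str(row.stimulus_id), str(row.group)), [])
    return [ResponseLog(participant_id=p, stimulus_id=s, group=g,
                        press_times_s=tuple(sorted(ts)))
            for (p, s, g), ts in sorted(grouped.items())]


def write_designs(designs: list[StimulusDesign], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(d) for d in designs], fh, indent=1)


def read_designs(path) -> list[StimulusDesign]:
    with open(path) as fh:
        raw = json.load(fh)
    return [StimulusDesign(**{**d, "changing_regions": tuple(d["changing_regions"])})
            for d in raw]


def write_values(series_by_stimulus, path) -> None:
    rows = []
    for sid, series in sorted(series_by_stimulus.items()):
        for r in range(series.n_regions):
            for t in range(series.duration_s + 1):
                rows.append({"stimulus_id": sid, "region_id": r, "second": t,
                             "value": series.values[r, t]})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _sub(seed: int, k: int) -> int:
    return int(np.random.default_rng([seed & 0x7FFFFFFF, k]).integers(2**31))


def _exp1_materials(cfg: PipelineConfig):
    rmap = build_region_map(box(0, 0, 1, 1), 10, seed=_sub(cfg.seed, 41))
    designs, series = [], {}
    for i in range(cfg.n_stimuli_exp1):
        sid = f"e1_s{i:02d}"
        d = StimulusDesign(experiment=1, stimulus_id=sid,
                           duration_s=cfg.duration_exp1_s,
                           noise_sd=cfg.noise_sd, seed=_sub(cfg.seed, 100 + i))
        designs.append(d)
        series[sid] = generate_exp1_series(duration_s=d.duration_s,
                                           noise_sd=d.noise_sd, seed=d.seed)
    return rmap, designs, series


def _materials(cfg: PipelineConfig):
    if cfg.experiment == 1:
        return _exp1_materials(cfg)
    if cfg.use_fixture:
        fx = make_paper_fixture(cfg.experiment, seed=cfg.seed, params=cfg.params())
        return fx.region_map, fx.designs, fx.series_by_stimulus, fx.logs
    rmap = None
    designs = enumerate_design(cfg.experiment)
    if cfg.experiment == 3:
        rmap = build_region_map(box(0, 0, 1, 1), 10, seed=_sub(cfg.seed, 42))
        designs = [d.with_regions(select_changing_regions(
            rmap, d.salience_factor, d.n_changing, seed=_sub(cfg.seed, 200 + i)))
            for i, d in enumerate(designs)]
    designs = [replace(d, seed=_sub(cfg.seed, 300 + i), noise_sd=cfg.noise_sd)
               for i, d in enumerate(designs)]
    series = {d.stimulus_id: generate_series(d, rmap) for d in designs}
    n = cfg.n_participants or {2: 117, 3: 176}[cfg.experiment]
    logs = simulate_cohort(designs, series, n, cfg.params(), seed=_sub(cfg.seed, 43))
    return rmap, designs, series, logs


def _design_frame(designs: list[StimulusDesign]) -> pd.DataFrame:
    return pd.DataFrame([{"stimulus_id": d.stimulus_id, "trend": d.trend_level,
                          "framing": d.framing,
                          "salience_factor": d.salience_factor}
                         for d in designs])


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis for one experiment; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit: dict = {"experiment": config.experiment, "seed": config.seed,
                   "config": asdict(config), "stages": []}
    stage = audit["stages"].append

    try:
        # generate + simulate ------------------------------------------------
        if config.experiment == 1:
            rmap, designs, series = _materials(config)
            n = config.n_participants or 80
            half = n // 2
            params = config.params()
            logs = simulate_cohort(designs, series, half, params,
                                   seed=_sub(config.seed, 44), group="days",
                                   participant_prefix="d")
            logs += simulate_cohort(designs, series, n - half, params,
                                    seed=_sub(config.seed, 45), group="years",
                                    participant_prefix="y")
        else:
            rmap, designs, series, logs = _materials(config)
        write_designs(designs, out / "designs.json")
        write_values(series, out / "values.csv")
        if rmap is not None:
            with open(out / "geometry.geojson", "w") as fh:
                json.dump(rmap.to_geojson(), fh)
        write_response_logs(logs, out / "logs.csv", out / "trials.csv")
        stage({"stage": "simulate", "n_trials": len(logs)})

        # filter + agreement -------------------------------------------------
        durations = {d.stimulus_id: d.duration_s for d in designs}
        binned, filter_audit = agr.bin_cohort(logs, durations,
                                              config.debounce_window_s)
        stage({"stage": "filter", **filter_audit})
        table = agr.agreement_table(binned)
        n_degenerate = int(table["agreement"].isna().sum())
        table.to_csv(out / "agreement.csv", index=False)
        stage({"stage": "agreement", "records": len(table),
               "degenerate": n_degenerate})

        # null + specificity -------------------------------------------------
        null_summaries = {}
        observed = table.dropna(subset=["agreement"])
        for group in sorted({g for g, _ in binned}):
            sub = {k: v for k, v in binned.items() if k[0] == group}
            null = agr.permutation_null(sub, iterations=config.null_iterations,
                                        seed=_sub(config.seed, 46))
            obs = float(observed.loc[observed.group == group, "agreement"].mean())
            null_summaries[group] = {**null.summary(), "observed_mean": obs,
                                     "p": agr.two_tailed_p(null, obs)}
        with open(out / "null.json", "w") as fh:
            json.dump(null_summaries, fh, indent=1)
        stage({"stage": "null", "groups": list(null_summaries)})

        spec_mode = "cross_stimulus" if config.experiment == 1 else "cross_stimulus"
        spec_tab = agr.specificity_table(binned, mode=spec_mode)
        spec_tab.to_csv(out / "specificity.csv", index=False)
        if config.experiment == 1:
            cross_group = agr.specificity_table(binned, mode="cross_group")
            cross_group.to_csv(out / "specificity_groups.csv", index=False)
        stage({"stage": "specificity", "records": len(spec_tab)})

        # models --------------------------------------------------------------
        if config.experiment == 1:
            _fit_exp1_models(spec_tab, logs, designs, series, out, stage)
        else:
            merged = observed.merge(_design_frame(designs), on="stimulus_id")
            levels = (("hue", "saturation") if config.experiment == 2
                      else ("distributed", "clustered"))
            res = inf.fit_factorial(merged, salience_levels=levels)
            res.coefficients.to_csv(out / "model_factorial.csv")
            ames = [inf.ame_trend(res, f, s)
                    for f in ("endangered", "invasive") for s in levels]
            pd.DataFrame([asdict(a) for a in ames]).to_csv(
                out / "ame_trend.csv", index=False)
            stage({"stage": "fit", "model": "factorial",
                   "three_way_p": float(res.coefficients["p"].iloc[-1])})
    except Exception as err:
        audit["error"] = f"{type(err).__name__}: {err}"
        with open(out / "audit.json", "w") as fh:
            json.dump(audit, fh, indent=1, default=str)
        raise

    with open(out / "audit.json", "w") as fh:
        json.dump(audit, fh, indent=1, default=str)
    return out


def _fit_exp1_models(spec_tab, logs, designs, series, out: Path, stage) -> None:
    # same- vs cross-stimulus contrast, per group (reference: cross-stimuli)
    for group in sorted(spec_tab.group.unique()):
        sub = spec_tab[(spec_tab.group == group)
                       & spec_tab.agreement.notna()].copy()
        sub["contrast_same"] = (sub.comparison == "same_stimulus").astype(float)
        spec = inf.LMMSpec(outcome="agreement",
                           fixed=((), ("contrast_same",)),
                           random=inf.CrossedIntercepts(("participant_id",
                                                         "stimulus_id")))
        res = inf.fit_lmm(sub, spec)
        res.coefficients.to_csv(out / f"model_contrast_{group}.csv")
        stage({"stage": "fit", "model": f"contrast_{group}",
               "beta_contrast": res.coef("contrast_same")})

    # timeline-unit model on response counts
    counts = []
    for lg in logs:
        if lg.press_times_s and max(lg.press_times_s) <= max(
                d.duration_s for d in designs):
            counts.append({"participant_id": lg.participant_id,
                           "stimulus_id": lg.stimulus_id, "group": lg.group,
                           "n_responses": len(agr.debounce(lg.press_times_s))})
    counts = pd.DataFrame(counts)
    counts["unit_days"] = (counts.group == "days").astype(float)
    spec = inf.LMMSpec(outcome="n_responses", fixed=((), ("unit_days",)),
                       random=inf.CrossedIntercepts(("participant_id",
                                                     "stimulus_id")))
    res = inf.fit_lmm(counts, spec)
    res.coefficients.to_csv(out / "model_timeunit.csv")
    stage({"stage": "fit", "model": "timeunit",
           "beta_unit": res.coef("unit_days")})

    # exploratory descriptor model
    desc = pd.DataFrame([{"stimulus_id": sid, "trend": s.trend,
                          "summed_values": s.summed_values,
                          "max_slope": s.max_slope}
                         for sid, s in series.items()])
    same = spec_tab[(spec_tab.comparison == "same_stimulus")
                    & spec_tab.agreement.notna()]
    merged = same.merge(desc, on="stimulus_id")
    res = inf.exploratory_descriptor_model(merged)
    res.coefficients.to_csv(out / "model_descriptors.csv")
    stage({"stage": "fit", "model": "descriptors",
           "beta_trend": res.coef("trend")})
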