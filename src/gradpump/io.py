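"""Run specifications, bundled fixture configs, file writers and the pipeline.

A :class:`RunSpec` is the single serializable record describing a run: the
target profile, the physical setup (:class:`~gradpump.program.ExperimentConfig`)
and which artifacts to write.  Specs round-trip through YAML (JSON is a YAML
subset and also accepted); unknown fields are rejected with the offending
field path.

All CSV output is RFC-4180 with a header row, '.' decimal separator and
explicit units in the column names (min, mL, µL/min, M) — the setups mix
M/mM and mL/µL on the bench, and silent unit drift is the main foreseeable
user error.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .exceptions import ConfigError
from .metrics import compare_variants, percent_error
from .profile import DiscretizedProfile, TargetProfile, discretize, make_profile
from .program import ExperimentConfig, PumpProgram, build_program
from .simulate import SimulationResult, simulate_discrete, simulate_ode

__all__ = [
    "ProfileSpec",
    "OutputSpec",
    "RunSpec",
    "load_runspec",
    "save_runspec",
    "generate_fixtures",
    "run_pipeline",
    "write_program_csv",
    "write_program_text",
    "write_trajectory_csv",
    "write_comparison_csv",
    "read_dispense_log",
    "write_profile_csv",
    "read_profile_csv",
]

log = logging.getLogger("gradpump")

_FLOAT_FMT = "%.10g"  # fixed format => byte-identical reruns


class ProfileSpec(BaseModel):
    """Serializable description of a target profile and its grid."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    shape: str
    c_start: float = 0.0
    c_final: float
    duration_min: float = Field(gt=0)
    breakpoints: tuple[tuple[float, float], ...] | None = None
    n_intervals: int = Field(ge=1)

    def to_profile(self) -> TargetProfile:
        return make_profile(
            self.shape, self.c_start, self.c_final, self.duration_min, self.breakpoints
        )

    def discretized(self, config: ExperimentConfig) -> DiscretizedProfile:
        mandatory = [t for t, _ in config.sampling if t <= self.duration_min]
        return discretize(self.to_profile(), self.n_intervals, mandatory)


class OutputSpec(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    program: bool = True
    program_text: bool = False
    trajectories: bool = True
    ode_check: bool = False
    comparison: bool = False
    plots: bool = False


class RunSpec(BaseModel):
    """Everything needed to reproduce one run."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str = "run"
    profile: ProfileSpec
    experiment: ExperimentConfig
    outputs: OutputSpec = OutputSpec()
    outdir: str = "runs"


def load_runspec(path: str | Path) -> RunSpec:
    """Parse and validate a YAML/JSON run spec file."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ConfigError(f"{path}: empty run spec")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise ConfigError(f"{path}: not valid YAML/JSON: {err}") from err
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: run spec must be a mapping")
    try:
        spec = RunSpec(**data)
    except ValidationError as err:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"{path}: {details}") from err
    log.info("loaded run spec %s from %s", spec.name, path)
    return spec


def save_runspec(spec: RunSpec, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(spec.model_dump(), sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# bundled fixtures: the two worked flask configurations plus three demos

_TP_SAMPLING_MINUTES = (1, 2, 4, 6, 8, 10, 15, 20, 25, 30, 35, 40, 45, 50)


def paper_tp_spec() -> RunSpec:
    """Time-Point worked configuration: 0→0.4 M linear over 50 min, 4 M stock,
    50 mL flask, 1 mL samples at 14 scheduled minutes, 34 pump phases."""
    return RunSpec(
        name="paper_tp",
        profile=ProfileSpec(
            shape="linear", c_start=0.0, c_final=0.4, duration_min=50.0, n_intervals=34
        ),
        experiment=ExperimentConfig(
            mode="TP",
            c_max=4.0,
            v0=50.0,
            sampling=tuple((float(t), 1.0) for t in _TP_SAMPLING_MINUTES),
        ),
        outputs=OutputSpec(comparison=True),
    )


def paper_ts_spec() -> RunSpec:
    """Time-Series worked configuration: same ramp, Pump 2 at 0.1 mL/min,
    40 uniform pump phases."""
    return RunSpec(
        name="paper_ts",
        profile=ProfileSpec(
            shape="linear", c_start=0.0, c_final=0.4, duration_min=50.0, n_intervals=40
        ),
        experiment=ExperimentConfig(mode="TS", c_max=4.0, v0=50.0, pump2_rate=0.1),
        outputs=OutputSpec(comparison=True),
    )


def _fixture_specs() -> list[RunSpec]:
    return [
        paper_tp_spec(),
        paper_ts_spec(),
        # fast ramp used for single-cell imaging: 0→0.4 M in 10 min
        RunSpec(
            name="ramp_0p4M_10min",
            profile=ProfileSpec(
                shape="linear", c_start=0.0, c_final=0.4, duration_min=10.0, n_intervals=20
            ),
            experiment=ExperimentConfig(mode="TS", c_max=4.0, v0=50.0, pump2_rate=0.1),
        ),
        # slow shallow ramp for suspension-cell sampling: 0→0.1 M in 60 min
        RunSpec(
            name="ramp_0p1M_60min",
            profile=ProfileSpec(
                shape="linear", c_start=0.0, c_final=0.1, duration_min=60.0, n_intervals=30
            ),
            experiment=ExperimentConfig(
                mode="TP",
                c_max=4.0,
                v0=50.0,
                sampling=tuple((float(t), 1.0) for t in (10, 20, 30, 40, 50, 60)),
            ),
        ),
        # decreasing gradient demo: dilution with 0 M media
        RunSpec(
            name="decreasing_demo",
            profile=ProfileSpec(
                shape="linear", c_start=0.4, c_final=0.2, duration_min=20.0, n_intervals=10
            ),
            experiment=ExperimentConfig(mode="TP", c_max=4.0, v0=50.0),
        ),
    ]


def generate_fixtures(output_dir: str | Path) -> list[Path]:
    """Write the bundled, immediately runnable config files; returns paths."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for spec in _fixture_specs():
        paths.append(save_runspec(spec, outdir / f"{spec.name}.yaml"))
    log.info("wrote %d fixture configs to %s", len(paths), outdir)
    return paths


# ---------------------------------------------------------------------------
# writers / readers


def write_program_csv(program: PumpProgram, path: str | Path) -> Path:
    """Instrument schedule: phase_index, dt_min, dispense_uL, rate_uL_per_min.

    Dispensed volumes are written in µL and are exact integers whenever the
    dispense resolution is 0.001 mL (the 1 µL instrument quantum).
    """
    path = Path(path)
    dispense_ul = program.dv * 1000.0
    as_int = np.allclose(dispense_ul, np.round(dispense_ul), atol=1e-6)
    frame = pd.DataFrame(
        {
            "phase_index": np.arange(1, program.n_phases + 1),
            "dt_min": program.dt,
            "dispense_uL": np.round(dispense_ul).astype(np.int64)
            if as_int
            else dispense_ul,
            "rate_uL_per_min": program.rates,
        }
    )
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_program_text(program: PumpProgram, path: str | Path) -> Path:
    """Generic pump-program dialect: one 'PHASE i RAT <µL/min> VOL <mL>' line
    per phase.  A neutral text form for manual entry — not a validated
    firmware format for any particular instrument."""
    path = Path(path)
    lines = [
        "# gradpump pump program (generic dialect, not firmware-validated)",
        "# RAT in uL/min, VOL in mL, DUR in min",
        f"# variant={program.variant} stock_M={program.stocks.max():g}",
    ]
    for i, (dt, dv, k) in enumerate(program.entries, start=1):
        lines.append(f"PHASE {i} RAT {k:.3f} VOL {dv:.3f} DUR {dt:.4f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_trajectory_csv(result: SimulationResult, path: str | Path) -> Path:
    path = Path(path)
    result.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_comparison_csv(
    reports, long_path: str | Path, summary_path: str | Path
) -> tuple[Path, Path]:
    """Per-time errors (variant, time_min, error_percent) and scalar summary."""
    rows = []
    summary = []
    for variant, rep in reports.items():
        for t, e in zip(rep.times, rep.per_time_error):
            rows.append({"variant": variant, "time_min": t, "error_percent": e})
        summary.append(
            {
                "variant": variant,
                "max_abs_percent": rep.max_abs_percent,
                "rms_percent": rep.rms_percent,
            }
        )
    long_path, summary_path = Path(long_path), Path(summary_path)
    pd.DataFrame(rows).to_csv(long_path, index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(summary).to_csv(summary_path, index=False, float_format=_FLOAT_FMT)
    return long_path, summary_path


def read_dispense_log(path: str | Path) -> list[tuple[float, float]]:
    """Read a cumulative dispense log CSV (time_min, cumulative_mL)."""
    frame = pd.read_csv(path)
    required = {"time_min", "cumulative_mL"}
    if not required.issubset(frame.columns):
        raise ConfigError(f"{path}: dispense log needs columns {sorted(required)}")
    return list(zip(frame["time_min"].astype(float), frame["cumulative_mL"].astype(float)))


def write_profile_csv(profile: DiscretizedProfile, path: str | Path) -> Path:
    """Export discretized targets as (time_min, concentration_M)."""
    path = Path(path)
    pd.DataFrame(
        {"time_min": profile.times, "concentration_M": profile.targets}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_profile_csv(path: str | Path) -> list[tuple[float, float]]:
    """Read (time_min, concentration_M) breakpoints for piecewise profiles."""
    frame = pd.read_csv(path)
    required = {"time_min", "concentration_M"}
    if not required.issubset(frame.columns):
        raise ConfigError(f"{path}: profile CSV needs columns {sorted(required)}")
    return list(
        zip(frame["time_min"].astype(float), frame["concentration_M"].astype(float))
    )


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(spec: RunSpec, outdir: str | Path | None = None) -> dict[str, Path]:
    """discretize → build → simulate → metrics → writers.  Deterministic.

    Returns a mapping of artifact name to written path; writes only what the
    spec's outputs request.
    """
    outdir = Path(outdir if outdir is not None else spec.outdir) / spec.name
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    disc = spec.profile.discretized(spec.experiment)
    log.info(
        "%s: %d phases over %.4g min", spec.name, disc.n_intervals, disc.duration
    )
    program = build_program(spec.experiment, disc)
    log.info(
        "%s: total dispense %.3f mL, final flask volume %.3f mL",
        spec.name,
        program.total_dispensed,
        program.flask_volumes[-1],
    )
    if spec.outputs.program:
        artifacts["program_csv"] = write_program_csv(program, outdir / "program.csv")
    if spec.outputs.program_text:
        artifacts["program_txt"] = write_program_text(program, outdir / "program.txt")

    if spec.outputs.trajectories or spec.outputs.ode_check or spec.outputs.plots:
        result = simulate_discrete(program, spec.experiment)
        report = percent_error(result)
        log.info(
            "%s: final %.4f M, max |error| %.3f%% of final target",
            spec.name,
            result.final_concentration,
            report.max_abs_percent,
        )
        if spec.outputs.trajectories:
            artifacts["trajectory_csv"] = write_trajectory_csv(
                result, outdir / "trajectory.csv"
            )
        if spec.outputs.ode_check:
            ode = simulate_ode(program, spec.experiment, substeps=100)
            artifacts["trajectory_ode_csv"] = write_trajectory_csv(
                ode, outdir / "trajectory_ode.csv"
            )

    reports = None
    if spec.outputs.comparison or spec.outputs.plots:
        reports = compare_variants(spec.experiment, disc)
        if spec.outputs.comparison:
            long_p, sum_p = write_comparison_csv(
                reports, outdir / "comparison.csv", outdir / "comparison_summary.csv"
            )
            artifacts["comparison_csv"] = long_p
            artifacts["comparison_summary_csv"] = sum_p

    if spec.outputs.plots:
        from .plotting import plot_comparison, plot_trajectory

        artifacts["trajectory_png"] = plot_trajectory(
            result, outdir / "trajectory.png"
        )
        artifacts["comparison_png"] = plot_comparison(
            reports, outdir / "comparison.png"
        )
    return artifacts
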