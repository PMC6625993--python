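"""Forward simulation of the stirred flask under a pump program.

Two simulators are provided:

* :func:`simulate_discrete` — the same per-phase recurrence the planner
  inverts, applied forward with the *true* withdrawals.  This is the
  reference pathway for all quantitative accuracy claims: a fully corrected
  planner round-trips through it exactly (up to dispense quantization), while
  blind planners reveal their error here.
* :func:`simulate_ode` — an independent continuous well-mixed-reactor (CSTR)
  oracle: volume changes at the net flow rate and stimulus mass obeys
  dM/dt = stock·q_in − m(t)·q_out, integrated with classical fixed-step RK4;
  Time-Point samples are instantaneous events (volume drops, concentration
  unchanged, as physically happens when an aliquot is removed).

The two agree exactly for closed phases starting from m=0 and to second order
when inflow and outflow balance, but the discrete recurrence books the prior
mass at the *new* volume and charges sample withdrawals as dilutions, so on
sampling-heavy schedules the physical oracle deviates; see docs/methods.md.

:func:`reconstruct_from_dispense` converts a cumulative dispensed-volume
record (e.g. a balance log of the stock beaker) into the delivered molarity
trajectory — the experimental-validation pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import FlaskDepleted, InvalidInput, InvalidMeasurement
from .profile import DiscretizedProfile, TargetProfile
from .program import (
    ExperimentConfig,
    PumpProgram,
    step_decreasing,
    step_increasing,
    _withdrawals,
)

__all__ = [
    "SimulationResult",
    "simulate_discrete",
    "simulate_ode",
    "reconstruct_from_dispense",
]


@dataclass(frozen=True)
class SimulationResult:
    """Realized trajectories at the program breakpoints.

    ``theory`` is the planned target series on the same grid (NaN-free when
    the program knows its profile).  ``source`` tags the pathway that produced
    the numbers: ``discrete``, ``ode`` or ``reconstruction``.
    """

    times: np.ndarray
    concentrations: np.ndarray
    volumes: np.ndarray
    theory: np.ndarray | None
    source: str
    variant: str = ""

    def __post_init__(self):
        n = len(self.times)
        if len(self.concentrations) != n or len(self.volumes) != n:
            raise InvalidInput("trajectory series must share one length")
        if self.theory is not None and len(self.theory) != n:
            raise InvalidInput("theory series must match the trajectory grid")

    @property
    def final_concentration(self) -> float:
        return float(self.concentrations[-1])

    def to_frame(self):
        """Trajectory as a DataFrame (time_min, concentration_M, volume_mL,
        theory_M, error_percent normalized to the final theory value)."""
        import pandas as pd

        theory = (
            self.theory if self.theory is not None else np.full_like(self.times, np.nan)
        )
        denom = theory[-1] if self.theory is not None and theory[-1] != 0 else np.nan
        return pd.DataFrame(
            {
                "time_min": self.times,
                "concentration_M": self.concentrations,
                "volume_mL": self.volumes,
                "theory_M": theory,
                "error_percent": 100.0 * (self.concentrations - theory) / denom,
            }
        )


def _true_du(program: PumpProgram, config: ExperimentConfig) -> np.ndarray:
    """Pump 2 withdrawal per phase under the true physics of the setup."""
    if program.variant == "setup1_equal_rate":
        return program.dv.copy()  # slaved to Pump 1
    if config.mode == "TS":
        return config.pump2_rate * program.dt
    return np.zeros_like(program.dv)


def simulate_discrete(
    program: PumpProgram, config: ExperimentConfig | None = None
) -> SimulationResult:
    """Run the discrete mass-balance recurrence forward under true physics.

    Whatever the planner assumed, each phase here sees the real withdrawals
    (Pump 2 draw-off and scheduled samples).  Dilution phases (stock 0 M) use
    the decreasing-form recurrence, which is the same bookkeeping the planner
    inverted.
    """
    config = config or program.config
    du = _true_du(program, config)
    dw = program.dw
    m = float(program.planned.targets[0])
    v = config.v0
    n = program.n_phases
    conc = np.zeros(n + 1)
    vol = np.zeros(n + 1)
    conc[0], vol[0] = m, v
    for i in range(n):
        delta = du[i] + dw[i]
        if v + program.dv[i] - delta <= 0:
            raise FlaskDepleted(f"flask depleted at phase {i + 1}")
        if program.stocks[i] > 0:
            m = step_increasing(m, program.dv[i], v, delta, program.stocks[i])
        else:
            m = step_decreasing(m, program.dv[i], v, delta)
        v = v + program.dv[i] - delta
        assert m >= 0, "mass balance cannot produce negative concentration"
        assert m <= config.c_max, "flask cannot exceed the stock concentration"
        conc[i + 1], vol[i + 1] = m, v
    return SimulationResult(
        times=program.times.copy(),
        concentrations=conc,
        volumes=vol,
        theory=program.planned.targets.copy(),
        source="discrete",
        variant=program.variant,
    )


def simulate_ode(
    program: PumpProgram,
    config: ExperimentConfig | None = None,
    substeps: int = 100,
) -> SimulationResult:
    """Integrate the continuous well-mixed flask as an independent oracle.

    Within phase *i*, inflow runs at ``dv_i/dt_i`` and Pump 2 outflow at
    ``du_i/dt_i`` (both constant); state (V, M) obeys dV/dt = q_in − q_out and
    dM/dt = stock·q_in − (M/V)·q_out, integrated with ``substeps`` classical
    RK4 steps (the system is smooth between events, so a fixed step suffices).
    Sample withdrawals are instantaneous events at the phase end: V drops by
    dw with concentration unchanged.
    """
    if substeps < 1:
        raise InvalidInput("substeps must be >= 1")
    config = config or program.config
    du = _true_du(program, config)
    dw = program.dw
    dt = program.dt
    v = config.v0
    mass = float(program.planned.targets[0]) * v
    n = program.n_phases
    conc = np.zeros(n + 1)
    vol = np.zeros(n + 1)
    conc[0], vol[0] = mass / v, v

    for i in range(n):
        q_in = program.dv[i] / dt[i]
        q_out = du[i] / dt[i]
        stock = program.stocks[i]
        h = dt[i] / substeps
        v0_phase = v

        def mdot(tau: float, m_state: float) -> float:
            v_tau = v0_phase + (q_in - q_out) * tau
            return stock * q_in - (m_state / v_tau) * q_out

        tau = 0.0
        for _ in range(substeps):
            k1 = mdot(tau, mass)
            k2 = mdot(tau + 0.5 * h, mass + 0.5 * h * k1)
            k3 = mdot(tau + 0.5 * h, mass + 0.5 * h * k2)
            k4 = mdot(tau + h, mass + h * k3)
            mass += (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            tau += h
        v = v0_phase + (q_in - q_out) * dt[i]
        if dw[i] > 0:  # instantaneous aliquot: proportional mass leaves
            if v <= dw[i]:
                raise FlaskDepleted(f"flask depleted by sample at phase {i + 1}")
            mass -= (mass / v) * dw[i]
            v -= dw[i]
        if v <= 0:
            raise FlaskDepleted(f"flask depleted at phase {i + 1}")
        conc[i + 1], vol[i + 1] = mass / v, v

    return SimulationResult(
        times=program.times.copy(),
        concentrations=conc,
        volumes=vol,
        theory=program.planned.targets.copy(),
        source="ode",
        variant=program.variant,
    )


def reconstruct_from_dispense(
    cumulative_dispense: Sequence[tuple[float, float]],
    config: ExperimentConfig,
    profile: TargetProfile | DiscretizedProfile | None = None,
    m0: float = 0.0,
    stock: float | None = None,
) -> SimulationResult:
    """Delivered molarity from a cumulative dispensed-volume record.

    Differences the cumulative series into per-phase ``dv`` on the recorded
    grid, then runs the discrete recurrence with the config's true
    withdrawals.  This converts a balance log of the stock beaker (or a
    recorded pump schedule) into the concentration the cells actually saw.

    ``profile`` (optional) supplies the theory series for error analysis and
    the starting concentration; ``stock`` defaults to the config's ``c_max``
    (pass 0 for a dilution run).
    """
    pairs = [(float(t), float(c)) for t, c in cumulative_dispense]
    if pairs and pairs[0][0] > 0:
        pairs.insert(0, (0.0, 0.0))
    times = np.array([p[0] for p in pairs])
    cum = np.array([p[1] for p in pairs])
    if times.size == 0:
        theory0 = None
        start = m0
        if profile is not None:
            start = float(
                profile.evaluate(0.0)
                if isinstance(profile, TargetProfile)
                else profile.targets[0]
            )
            theory0 = np.array([start])
        return SimulationResult(
            times=np.array([0.0]),
            concentrations=np.array([start]),
            volumes=np.array([config.v0]),
            theory=theory0,
            source="reconstruction",
        )
    if np.any(np.diff(times) <= 0):
        raise InvalidMeasurement("measurement times must be strictly increasing")
    if np.any(np.diff(cum) < 0):
        raise InvalidMeasurement("cumulative dispensed volume cannot decrease")

    dv = np.diff(cum)
    stock_c = config.c_max if stock is None else float(stock)
    if profile is not None:
        if isinstance(profile, TargetProfile):
            theory = np.asarray(profile.evaluate(times), dtype=float)
        else:
            theory = np.interp(times, profile.times, profile.targets)
        start = float(theory[0])
        planned = DiscretizedProfile(times, theory)
    else:
        theory = None
        start = m0
        planned = DiscretizedProfile(times, np.full_like(times, start))

    du, dw = _withdrawals(config, times)
    program = PumpProgram(
        times=times,
        dv=dv,
        rates=config.rate_unit_factor * dv / np.diff(times),
        stocks=np.full_like(dv, stock_c),
        du=du,
        dw=dw,
        flask_volumes=np.concatenate([[config.v0], config.v0 + np.cumsum(dv - du - dw)]),
        planned=planned,
        variant=config.variant,
        config=config,
    )
    result = simulate_discrete(program, config)
    return SimulationResult(
        times=result.times,
        concentrations=result.concentrations,
        volumes=result.volumes,
        theory=theory,
        source="reconstruction",
        variant=config.variant,
    )
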