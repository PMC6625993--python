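"""Pump-program computation: per-phase dispense volumes and rates.

The mixing flask starts at volume ``V0`` with stimulus concentration ``m0``.
During phase *i* (duration ``dt_i``) Pump 1 adds ``dv_i`` mL of stock —
concentrated stimulus at ``C_max`` for increasing phases, plain 0 M media for
decreasing phases — while ``du_i`` mL leaves through Pump 2 (Time-Series
draw-off) and ``dw_i`` mL leaves as manual samples (Time-Point aliquots).

The discrete recurrence that defines the delivered concentration is, for
increasing phases (removals charged at the phase-average concentration
``m̄ = (m_i + m_{i-1})/2``)::

    m_i = m_{i-1} + (C_max·dv_i − m̄·(du_i + dw_i)) / (V_{i-1} + dv_i − (du_i + dw_i))

and for decreasing phases (dilution by 0 M media)::

    m_i = m_{i-1}·V_{i-1} / (V_{i-1} + dv_i − (du_i + dw_i))

Both are closed-form invertible for ``dv_i`` given the target ``m_i``, which is
what :func:`solve_dispense_increasing` / :func:`solve_dispense_decreasing` do.
:func:`build_program` walks the discretized profile, solves each phase under
the chosen correction variant, quantizes ``dv_i`` to the instrument resolution
(default 1 µL), carries the quantized realization forward, and recomputes the
pump rate ``k_i = 1000·dv_i/dt_i`` (µL/min) from the rounded volume so rate
and volume stay consistent on the instrument.

Correction variants (what the planner knows about withdrawals):

``full_correction``
    Exact inversion: volume loss and the stimulus mass carried out.
``volume_only``
    Tracks the volume loss but ignores the mass carried out (drops the
    ``m̄·Δ`` term).
``uncorrected``
    Blind to withdrawals entirely; its internal volume grows by ``dv`` only.
``setup1_equal_rate``
    Time-Series setup with Pump 2 slaved to Pump 1 (``du_i = dv_i``, beaker
    volume pinned at V0).  The planner knows the volume is constant but
    ignores the stimulus mass the slaved draw-off carries away, which is what
    makes this setup inaccurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import (
    DirectionViolation,
    FlaskDepleted,
    InfeasibleTarget,
    InvalidInput,
)
from .profile import DiscretizedProfile

__all__ = [
    "ExperimentConfig",
    "PumpProgram",
    "solve_dispense_increasing",
    "solve_dispense_decreasing",
    "step_increasing",
    "step_decreasing",
    "build_program",
    "build_variant_program",
    "VARIANTS",
]

VARIANTS = ("full_correction", "volume_only", "uncorrected", "setup1_equal_rate")

# negative dv smaller than this (mL) is treated as numerical zero
_DV_EPS = 1e-12


class ExperimentConfig(BaseModel):
    """Physical setup of a run: flask, stock, pumps and withdrawals.

    ``mode`` is ``TP`` (stirred flask, manual samples ``sampling`` of
    (minute, mL) pairs, no Pump 2) or ``TS`` (Pump 2 draws continuously at
    ``pump2_rate`` mL/min to a flow chamber, no manual samples).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    mode: Literal["TP", "TS"]
    c_max: float = Field(gt=0, description="stock stimulus concentration (M)")
    v0: float = Field(gt=0, description="initial flask volume (mL)")
    pump2_rate: float = Field(default=0.0, ge=0, description="Pump 2 draw-off (mL/min)")
    sampling: tuple[tuple[float, float], ...] = Field(
        default=(), description="(time_min, withdrawal_mL) pairs, TP only"
    )
    variant: Literal[
        "full_correction", "volume_only", "uncorrected", "setup1_equal_rate"
    ] = "full_correction"
    dispense_resolution: float = Field(
        default=0.001, ge=0, description="dispense quantum (mL); 0 disables rounding"
    )
    rate_unit_factor: float = Field(
        default=1000.0, gt=0, description="rate unit scale (µL per mL)"
    )

    @model_validator(mode="after")
    def _check_mode(self):
        if self.mode == "TP" and self.pump2_rate != 0:
            raise ValueError("TP mode has no Pump 2: pump2_rate must be 0")
        if self.mode == "TS" and self.sampling:
            raise ValueError("TS mode takes no manual samples: sampling must be empty")
        times = [t for t, _ in self.sampling]
        if any(np.diff(times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if any(t <= 0 for t in times):
            raise ValueError("sampling times must be > 0")
        if any(w <= 0 for _, w in self.sampling):
            raise ValueError("sampling withdrawal volumes must be > 0")
        if self.variant == "setup1_equal_rate" and self.mode != "TS":
            raise ValueError("setup1_equal_rate is a TS-only variant")
        return self


@dataclass(frozen=True)
class PumpProgram:
    """Instrument-facing schedule plus the bookkeeping behind it.

    ``dv`` are the quantized dispense volumes (mL), ``rates`` the pump rates
    (µL/min) recomputed from the quantized volumes, ``stocks`` the per-phase
    stock concentration (c_max for increasing phases, 0.0 for dilution
    phases).  ``du``/``dw`` are the *true* withdrawals each phase will see and
    ``flask_volumes`` the resulting true volume trajectory — independent of
    what the planning variant assumed, so blind variants can be judged
    against reality.
    """

    times: np.ndarray            # breakpoints t_0..t_N (min)
    dv: np.ndarray               # dispensed volume per phase (mL)
    rates: np.ndarray            # pump rate per phase (µL/min)
    stocks: np.ndarray           # stock concentration per phase (M)
    du: np.ndarray               # Pump 2 withdrawal per phase (mL)
    dw: np.ndarray               # sampling withdrawal per phase (mL)
    flask_volumes: np.ndarray    # true V_0..V_N (mL)
    planned: DiscretizedProfile  # the targets the program was built for
    variant: str
    config: ExperimentConfig
    mixed_direction: bool = field(default=False)

    @property
    def dt(self) -> np.ndarray:
        """Phase durations (min)."""
        return np.diff(self.times)

    @property
    def n_phases(self) -> int:
        return len(self.dv)

    @property
    def entries(self) -> list[tuple[float, float, float]]:
        """(dt_min, dv_mL, rate_µL/min) triples, the instrument's view."""
        return [
            (float(dt), float(dv), float(k))
            for dt, dv, k in zip(self.dt, self.dv, self.rates)
        ]

    @property
    def total_dispensed(self) -> float:
        """Total stock volume pushed by Pump 1 (mL)."""
        return float(np.sum(self.dv))

    def cumulative_dispense(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, cumulative mL) series as a balance would record it."""
        return self.times.copy(), np.concatenate([[0.0], np.cumsum(self.dv)])


def solve_dispense_increasing(
    m_prev: float, m_target: float, v_prev: float, removal: float, c_max: float
) -> float:
    """Dispense volume (mL) of ``c_max`` stock that lifts ``m_prev`` to
    ``m_target`` in one phase, given ``removal`` mL leaving the flask.

    Closed-form inversion of the increasing-phase recurrence: with
    ``D = m_target − m_prev`` and ``m̄ = (m_target + m_prev)/2``,

        dv = (D·(v_prev − removal) + m̄·removal) / (c_max − D)
    """
    if m_target >= c_max:
        raise InfeasibleTarget(
            f"target {m_target} M not reachable with {c_max} M stock"
        )
    if m_target < m_prev - _DV_EPS:
        raise DirectionViolation(
            f"target {m_target} M below current {m_prev} M in increasing mode"
        )
    if removal < 0 or v_prev <= removal:
        raise InvalidInput("need v_prev > removal >= 0")
    d = m_target - m_prev
    m_bar = 0.5 * (m_target + m_prev)
    dv = (d * (v_prev - removal) + m_bar * removal) / (c_max - d)
    return max(dv, 0.0)


def solve_dispense_decreasing(
    m_prev: float, m_target: float, v_prev: float, removal: float
) -> float:
    """Dispense volume (mL) of 0 M media that dilutes ``m_prev`` to
    ``m_target``:  dv = v_prev·(m_prev/m_target − 1) + removal.
    """
    if m_target <= 0:
        raise InfeasibleTarget("finite dilution cannot reach 0 M")
    if m_target > m_prev + _DV_EPS:
        raise DirectionViolation(
            f"target {m_target} M above current {m_prev} M in decreasing mode"
        )
    if removal < 0 or v_prev <= 0:
        raise InvalidInput("need v_prev > 0 and removal >= 0")
    dv = v_prev * (m_prev / m_target - 1.0) + removal
    return max(dv, 0.0)


def step_increasing(
    m_prev: float, dv: float, v_prev: float, removal: float, stock: float
) -> float:
    """Forward increasing-phase recurrence solved for ``m_i``.

    ``m_i`` appears on both sides through m̄; the equation is linear in it:
    m_i = (m_prev·(V_new − removal/2) + stock·dv) / (V_new + removal/2)
    with V_new = v_prev + dv − removal.
    """
    v_new = v_prev + dv - removal
    return (m_prev * (v_new - 0.5 * removal) + stock * dv) / (v_new + 0.5 * removal)


def step_decreasing(m_prev: float, dv: float, v_prev: float, removal: float) -> float:
    """Forward decreasing-phase (dilution) recurrence."""
    return m_prev * v_prev / (v_prev + dv - removal)


def _withdrawals(
    config: ExperimentConfig, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """True per-phase withdrawals (du from Pump 2, dw from sampling).

    Each sample is charged to the phase whose window (t_{i-1}, t_i] contains
    its minute; TP sampling minutes are required to be breakpoints upstream.
    """
    dt = np.diff(times)
    du = config.pump2_rate * dt if config.mode == "TS" else np.zeros_like(dt)
    dw = np.zeros_like(dt)
    tol = times[-1] * 1e-9
    for t_s, w in config.sampling:
        if t_s > times[-1] + tol:
            continue  # sample after the treatment window: not this program's concern
        i = int(np.searchsorted(times, t_s - tol)) - 1
        i = min(max(i, 0), len(dt) - 1)
        dw[i] += w
    return du, dw


def _quantize(dv: float, resolution: float) -> float:
    """Round to the instrument quantum, half-to-even; resolution 0 disables."""
    if resolution <= 0:
        return dv
    return float(np.round(dv / resolution)) * resolution


def build_variant_program(
    config: ExperimentConfig,
    profile: DiscretizedProfile,
    variant: str,
) -> PumpProgram:
    """Build the pump program a planner with the given knowledge would write.

    The planner walks the phases keeping its own belief about the flask state
    (exact for ``full_correction``; deliberately wrong for the uncorrected
    variants), solves each ``dv_i``, quantizes it, and carries the quantized
    realization *of its own model* forward so rounding errors do not
    accumulate.  True withdrawals and the true volume trajectory are recorded
    alongside for simulation.
    """
    if variant not in VARIANTS:
        raise InvalidInput(f"unknown variant {variant!r}")
    if variant == "setup1_equal_rate" and config.mode != "TS":
        raise InvalidInput("setup1_equal_rate is a TS-only variant")

    times = profile.times
    targets = profile.targets
    dt = profile.intervals
    n = profile.n_intervals
    du_true, dw_true = _withdrawals(config, times)

    # TP sampling minutes must sit on the grid so withdrawals align with phases
    if config.sampling:
        tol = times[-1] * 1e-9
        for t_s, _ in config.sampling:
            if t_s <= times[-1] + tol and np.min(np.abs(times - t_s)) > tol:
                raise InvalidInput(
                    f"sampling time {t_s} min is not a program breakpoint"
                )
    if np.any(targets >= config.c_max):
        raise InfeasibleTarget("profile targets must stay below the stock c_max")

    dv = np.zeros(n)
    stocks = np.zeros(n)
    v_true = np.zeros(n + 1)
    v_true[0] = config.v0
    m_plan = float(targets[0])  # planner's belief about current concentration
    v_blind = config.v0         # 'uncorrected' planner's volume belief
    c = config.c_max

    for i in range(n):
        m_t = float(targets[i + 1])
        d = m_t - m_plan
        delta_true = du_true[i] + dw_true[i]
        increasing = d >= 0
        try:
            if variant == "full_correction":
                dv_i = (
                    solve_dispense_increasing(m_plan, m_t, v_true[i], delta_true, c)
                    if increasing
                    else solve_dispense_decreasing(m_plan, m_t, v_true[i], delta_true)
                )
            elif variant == "volume_only":
                # volume loss tracked, stimulus-mass loss ignored (m̄·Δ term dropped)
                if increasing:
                    if v_true[i] <= delta_true:
                        raise FlaskDepleted(f"phase {i + 1}: removal exceeds volume")
                    dv_i = d * (v_true[i] - delta_true) / (c - d)
                else:
                    dv_i = solve_dispense_decreasing(m_plan, m_t, v_true[i], delta_true)
            elif variant == "uncorrected":
                dv_i = (
                    d * v_blind / (c - d)
                    if increasing
                    else solve_dispense_decreasing(m_plan, m_t, v_blind, 0.0)
                )
            else:  # setup1_equal_rate: du=dv keeps V at v0; mass outflow ignored
                dv_i = (
                    d * config.v0 / (c - d)
                    if increasing
                    else solve_dispense_decreasing(m_plan, m_t, config.v0, 0.0)
                )
        except (InfeasibleTarget, DirectionViolation) as err:
            raise type(err)(f"phase {i + 1}: {err}") from err

        dv_i = _quantize(max(dv_i, 0.0), config.dispense_resolution)
        dv[i] = dv_i
        stocks[i] = c if increasing else 0.0

        # carry the quantized phase forward through the planner's own model
        if variant == "full_correction":
            m_plan = (
                step_increasing(m_plan, dv_i, v_true[i], delta_true, c)
                if increasing
                else step_decreasing(m_plan, dv_i, v_true[i], delta_true)
            )
        elif variant == "volume_only":
            v_new = v_true[i] + dv_i - delta_true
            m_plan = (
                m_plan + c * dv_i / v_new
                if increasing
                else step_decreasing(m_plan, dv_i, v_true[i], delta_true)
            )
        elif variant == "uncorrected":
            m_plan = (
                step_increasing(m_plan, dv_i, v_blind, 0.0, c)
                if increasing
                else step_decreasing(m_plan, dv_i, v_blind, 0.0)
            )
            v_blind += dv_i
        else:  # setup1_equal_rate
            m_plan = (
                step_increasing(m_plan, dv_i, config.v0, 0.0, c)
                if increasing
                else step_decreasing(m_plan, dv_i, config.v0, 0.0)
            )

        if variant == "setup1_equal_rate":
            du_true[i] = dv_i  # Pump 2 slaved to Pump 1
        v_true[i + 1] = v_true[i] + dv_i - (du_true[i] + dw_true[i])
        if v_true[i + 1] <= 0:
            raise FlaskDepleted(
                f"flask volume {v_true[i + 1]:.3f} mL at phase {i + 1}"
            )

    rates = config.rate_unit_factor * dv / dt
    nonzero = stocks[np.abs(np.diff(targets)) > 0]
    mixed = bool(nonzero.size) and bool((nonzero == 0).any() and (nonzero > 0).any())
    return PumpProgram(
        times=times.copy(),
        dv=dv,
        rates=rates,
        stocks=stocks,
        du=du_true,
        dw=dw_true,
        flask_volumes=v_true,
        planned=profile,
        variant=variant,
        config=config,
        mixed_direction=mixed,
    )


def build_program(config: ExperimentConfig, profile: DiscretizedProfile) -> PumpProgram:
    """Build the program for the variant named in the config."""
    return build_variant_program(config, profile, config.variant)
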