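"""Target concentration profiles and their discretization.

A :class:`TargetProfile` is the continuous concentration trajectory ``m(t)``
(in M, over minutes) that an experiment wants the flask to follow: a step, a
linear or quadratic ramp, or an arbitrary piecewise-linear curve.  Programmable
syringe pumps execute a finite number of constant-rate phases, so a profile is
discretized into breakpoints ``t_0 < t_1 < ... < t_N`` with per-breakpoint
targets ``m_i = m(t_i)``; every phase then ramps the flask linearly from
``m_{i-1}`` to ``m_i``.

For Time-Point experiments the sampling minutes must be breakpoints (a
withdrawal is booked against the phase that ends at it), so :func:`discretize`
accepts mandatory times and merges the remaining grid around them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InfeasibleDiscretization, InvalidInput

__all__ = ["TargetProfile", "DiscretizedProfile", "make_profile", "discretize"]

SHAPES = ("step", "linear", "quadratic", "piecewise")

# relative tolerance used when deciding two breakpoint times coincide
_TIME_RTOL = 1e-9


@dataclass(frozen=True)
class TargetProfile:
    """Continuous desired concentration trajectory m(t) on [0, duration].

    Parameters
    ----------
    shape
        One of ``step``, ``linear``, ``quadratic``, ``piecewise``.
    c_start, c_final
        Concentrations (M) at t=0 and t=duration.
    duration
        Treatment window length (min), > 0.
    breakpoints
        For ``piecewise`` only: ordered (time_min, concentration_M) pairs
        starting at t=0 and ending at t=duration.
    """

    shape: str
    c_start: float
    c_final: float
    duration: float
    breakpoints: tuple[tuple[float, float], ...] | None = field(default=None)

    @property
    def direction(self) -> str:
        """``increasing`` or ``decreasing`` (constant counts as increasing)."""
        return "decreasing" if self.c_final < self.c_start else "increasing"

    def evaluate(self, t):
        """Evaluate m(t); accepts scalars or arrays, returns like input."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < -self.duration * _TIME_RTOL) or np.any(
            t_arr > self.duration * (1 + _TIME_RTOL)
        ):
            raise InvalidInput(
                f"evaluation time outside [0, {self.duration}] min"
            )
        if self.shape == "step":
            out = np.where(t_arr > 0, self.c_final, self.c_start)
        elif self.shape == "linear":
            out = self.c_start + (self.c_final - self.c_start) * t_arr / self.duration
        elif self.shape == "quadratic":
            out = self.c_start + (self.c_final - self.c_start) * (t_arr / self.duration) ** 2
        else:  # piecewise
            times = np.array([p[0] for p in self.breakpoints])
            concs = np.array([p[1] for p in self.breakpoints])
            out = np.interp(t_arr, times, concs)
        return float(out) if np.isscalar(t) else out

    __call__ = evaluate


@dataclass(frozen=True)
class DiscretizedProfile:
    """A profile sampled at program breakpoints.

    ``times`` has N+1 entries starting at 0; ``targets`` are the profile values
    at those times.  ``intervals`` (dt_i, length N) are the phase durations.
    """

    times: np.ndarray
    targets: np.ndarray
    source: TargetProfile | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "targets", np.asarray(self.targets, dtype=float))
        if self.times.shape != self.targets.shape or self.times.ndim != 1:
            raise InvalidInput("times and targets must be 1-D and equal length")
        if self.times[0] != 0:
            raise InvalidInput("discretized profile must start at t=0")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidInput("breakpoint times must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return len(self.times) - 1

    @property
    def intervals(self) -> np.ndarray:
        """Phase durations dt_i (min)."""
        return np.diff(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1])


def make_profile(
    shape: str,
    c_start: float,
    c_final: float,
    duration: float,
    breakpoints: Sequence[tuple[float, float]] | None = None,
) -> TargetProfile:
    """Construct and validate a :class:`TargetProfile`.

    ``step`` means m(t) = c_final for all t > 0 (a bolus at t=0); ``quadratic``
    is m(t) = c_start + (c_final − c_start)·(t/duration)².  Piecewise profiles
    must be monotone (one stock per run: concentrated stimulus for increasing,
    plain media for decreasing).
    """
    if shape not in SHAPES:
        raise InvalidInput(f"unknown profile shape {shape!r}; choose from {SHAPES}")
    if duration <= 0:
        raise InvalidInput("duration must be > 0")
    if c_start < 0 or c_final < 0:
        raise InvalidInput("concentrations must be >= 0")
    if shape == "piecewise":
        if not breakpoints:
            raise InvalidInput("piecewise profile requires breakpoints")
        bp = tuple((float(t), float(c)) for t, c in breakpoints)
        t = np.array([p[0] for p in bp])
        c = np.array([p[1] for p in bp])
        if np.any(c < 0):
            raise InvalidInput("breakpoint concentrations must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise InvalidInput("breakpoint times must be strictly increasing")
        if t[0] != 0 or abs(t[-1] - duration) > duration * _TIME_RTOL:
            raise InvalidInput("breakpoints must start at t=0 and end at t=duration")
        if abs(c[0] - c_start) > 1e-12 or abs(c[-1] - c_final) > 1e-12:
            raise InvalidInput("breakpoint endpoints must match c_start/c_final")
        dc = np.diff(c)
        if not (np.all(dc >= 0) or np.all(dc <= 0)):
            raise InvalidInput(
                "piecewise profile must be monotone (single stock per run)"
            )
    else:
        if breakpoints:
            raise InvalidInput(f"{shape} profile takes no breakpoints")
        bp = None
    return TargetProfile(shape, float(c_start), float(c_final), float(duration), bp)


def _merge_grid(candidates: np.ndarray, mandatory: np.ndarray, n_intervals: int, duration: float) -> np.ndarray:
    """Reduce a breakpoint candidate set to exactly n_intervals+1 points.

    Greedy rule: repeatedly drop the interior non-mandatory breakpoint whose
    nearer neighbour is closest (ties resolved toward earlier times), which
    keeps the grid as even as the mandatory times allow.  Deterministic.
    """
    pts = list(candidates)
    tol = duration * _TIME_RTOL

    def is_mandatory(t: float) -> bool:
        return bool(mandatory.size) and np.min(np.abs(mandatory - t)) <= tol

    while len(pts) - 1 > n_intervals:
        best_idx, best_gap = None, np.inf
        for j in range(1, len(pts) - 1):
            if is_mandatory(pts[j]):
                continue
            gap = min(pts[j] - pts[j - 1], pts[j + 1] - pts[j])
            if gap < best_gap - tol:
                best_idx, best_gap = j, gap
        if best_idx is None:
            raise InfeasibleDiscretization(
                f"cannot reach {n_intervals} intervals: all remaining "
                "breakpoints are mandatory"
            )
        del pts[best_idx]
    return np.array(pts)


def discretize(
    profile: TargetProfile,
    n_intervals: int,
    mandatory_times: Sequence[float] | None = None,
) -> DiscretizedProfile:
    """Sample a profile onto a program grid of exactly ``n_intervals`` phases.

    The grid is the union of ``mandatory_times`` (e.g. sampling minutes, which
    must fall in (0, duration]) and a uniform grid, merged down to
    ``n_intervals`` by dropping the most crowded non-mandatory breakpoints.
    Step profiles are a single bolus phase by construction and reject mandatory
    times.
    """
    if n_intervals < 1:
        raise InvalidInput("n_intervals must be >= 1")
    duration = profile.duration
    mandatory = np.array(sorted(set(float(t) for t in (mandatory_times or []))))
    if mandatory.size:
        if np.any(mandatory <= 0) or np.any(mandatory > duration * (1 + _TIME_RTOL)):
            raise InvalidInput("mandatory times must lie in (0, duration]")

    if profile.shape == "step":
        if mandatory.size:
            raise InvalidInput(
                "step profiles are delivered as a single bolus and cannot "
                "carry mandatory breakpoints"
            )
        times = np.array([0.0, duration])
        return DiscretizedProfile(times, profile.evaluate(times), profile)

    # minimum intervals forced by the mandatory set
    forced = mandatory.size + (0 if (mandatory.size and abs(mandatory[-1] - duration) <= duration * _TIME_RTOL) else 1)
    if n_intervals < forced:
        raise InfeasibleDiscretization(
            f"{n_intervals} intervals cannot contain {mandatory.size} mandatory times"
        )

    uniform = np.linspace(0.0, duration, n_intervals + 1)
    pts = np.concatenate([uniform, mandatory])
    pts = np.sort(pts)
    # dedupe near-coincident points (mandatory minute hitting the uniform grid)
    keep = np.concatenate([[True], np.diff(pts) > duration * _TIME_RTOL])
    pts = pts[keep]
    # a mandatory time may have absorbed its uniform neighbour: snap exact values
    for t in mandatory:
        j = int(np.argmin(np.abs(pts - t)))
        pts[j] = t
    times = _merge_grid(pts, mandatory, n_intervals, duration)
    times[0], times[-1] = 0.0, duration
    return DiscretizedProfile(times, profile.evaluate(times), profile)
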