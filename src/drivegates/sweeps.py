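"""Two-parameter phase-diagram sweeps and one-parameter threshold finders.

A grid sweep runs one independent trajectory per cell, overriding two named
parameters of a base configuration, and records the outcome and time to
fixation — the numerical content of an outcome heatmap.  The threshold
finder bisects a single parameter against an outcome predicate, with a
coarse monotonicity pre-scan.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Callable
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import DegeneratePopulationError, DriveParams, InductionSettings
from .simulate import Outcome, SimulationConfig, Trajectory, run

__all__ = [
    "AxisSpec",
    "OutcomeGrid",
    "ThresholdResult",
    "NoSignChangeError",
    "grid_sweep",
    "find_threshold",
    "DEGENERATE_LABEL",
]

#: Cell label for runs that collapse (all-lethal); distinct from the three
#: fixation outcomes because the frequency model cannot represent extinction.
DEGENERATE_LABEL = "DEGENERATE"

_PARAM_FIELDS = {f.name for f in dataclasses.fields(DriveParams)}
_INDUCTION_FIELDS = {"alpha", "start_generation"}
_CONFIG_FIELDS = {"initial_q_D"}
SWEEPABLE = _PARAM_FIELDS | _INDUCTION_FIELDS | _CONFIG_FIELDS


class NoSignChangeError(ValueError):
    """The outcome predicate does not differ between the bracket ends."""


@dataclass(frozen=True)
class AxisSpec:
    """One sweep axis: a parameter name and an inclusive linear grid."""

    name: str
    lower: float
    upper: float
    count: int = 101

    def __post_init__(self) -> None:
        if self.name not in SWEEPABLE:
            raise ValueError(f"{self.name!r} is not a sweepable parameter; choose from {sorted(SWEEPABLE)}")
        if self.count < 2:
            raise ValueError(f"count must be >= 2, got {self.count!r}")
        if not (self.lower < self.upper):
            raise ValueError(f"need lower < upper, got [{self.lower!r}, {self.upper!r}]")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.count)


def with_override(config: SimulationConfig, name: str, value: float) -> SimulationConfig:
    """Return a copy of `config` with one named parameter replaced."""
    if name in _PARAM_FIELDS:
        return dataclasses.replace(config, params=dataclasses.replace(config.params, **{name: value}))
    if name in _INDUCTION_FIELDS:
        if name == "start_generation":
            value = int(value)
        return dataclasses.replace(
            config, induction=dataclasses.replace(config.induction, **{name: value})
        )
    if name in _CONFIG_FIELDS:
        return dataclasses.replace(config, **{name: value})
    raise ValueError(f"{name!r} is not a sweepable parameter")


@dataclass(frozen=True)
class OutcomeGrid:
    """Outcome and fixation-time matrices over a 2-D parameter grid.

    ``outcome[i, j]`` corresponds to ``y_axis.values[i]`` (rows) and
    ``x_axis.values[j]`` (columns).  ``time`` holds NaN where no fixation
    occurred; ``pre_induction_loss`` marks wild-type fixations completed
    before the signal ever switched on.
    """

    x_axis: AxisSpec
    y_axis: AxisSpec
    outcome: np.ndarray
    time: np.ndarray
    pre_induction_loss: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per grid cell."""
        records = []
        for i, yv in enumerate(self.y_axis.values):
            for j, xv in enumerate(self.x_axis.values):
                t = self.time[i, j]
                records.append(
                    {
                        "x_param": self.x_axis.name,
                        "x_value": xv,
                        "y_param": self.y_axis.name,
                        "y_value": yv,
                        "outcome": self.outcome[i, j],
                        "fixation_generation": int(t) if np.isfinite(t) else pd.NA,
                        "pre_induction_loss": int(self.pre_induction_loss[i, j]),
                    }
                )
        return pd.DataFrame.from_records(records)


def _pre_induction_loss(traj: Trajectory) -> bool:
    return (
        traj.outcome is Outcome.WT_FIXATION
        and traj.induction_applied_from is not None
        and traj.fixation_generation is not None
        and traj.fixation_generation <= traj.induction_applied_from
    )


def grid_sweep(x: AxisSpec, y: AxisSpec, base_config: SimulationConfig) -> OutcomeGrid:
    """Run one trajectory per cell of the (x, y) parameter grid.

    Cells are mutually independent; a degenerate-population collapse in one
    cell is recorded under :data:`DEGENERATE_LABEL` and never aborts the
    sweep.
    """
    if x.name == y.name:
        raise ValueError("sweep axes must name distinct parameters")
    outcome = np.empty((y.count, x.count), dtype=object)
    time = np.full((y.count, x.count), np.nan)
    pil = np.zeros((y.count, x.count), dtype=bool)
    for i, yv in enumerate(y.values):
        cfg_row = with_override(base_config, y.name, float(yv))
        for j, xv in enumerate(x.values):
            cfg = with_override(cfg_row, x.name, float(xv))
            try:
                traj = run(cfg)
            except DegeneratePopulationError:
                outcome[i, j] = DEGENERATE_LABEL
                continue
            outcome[i, j] = traj.outcome.value
            if traj.fixation_generation is not None:
                time[i, j] = traj.fixation_generation
            pil[i, j] = _pre_induction_loss(traj)
    return OutcomeGrid(x_axis=x, y_axis=y, outcome=outcome, time=time, pre_induction_loss=pil)


@dataclass(frozen=True)
class ThresholdResult:
    """Bisection output: the midpoint estimate and its final bracket."""

    value: float
    bracket: tuple[float, float]
    predicate_at_lower: bool


def find_threshold(
    parameter_name: str,
    bracket: tuple[float, float],
    base_config: SimulationConfig,
    predicate: Callable[[Trajectory], bool],
    tolerance: float = 1e-4,
    prescan_points: int = 11,
) -> ThresholdResult:
    """Bisect `parameter_name` to the critical value where `predicate` flips.

    The predicate maps a trajectory to a boolean (e.g. "ends in drive
    fixation").  It must differ between the two bracket ends; a coarse
    pre-scan checks that the flip happens exactly once on the bracket and
    emits a warning when outcome reversals are detected (the bisection then
    converges to one of the crossings, not necessarily the first).

    Returns the midpoint of the final bracket, so the critical value is
    within ``tolerance / 2`` of the reported value under monotonicity.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError(f"bracket must satisfy low < high, got {bracket!r}")

    def eval_at(v: float) -> bool:
        return bool(predicate(run(with_override(base_config, parameter_name, v))))

    p_lo = eval_at(lo)
    p_hi = eval_at(hi)
    if p_lo == p_hi:
        raise NoSignChangeError(
            f"predicate is {p_lo} at both ends of [{lo}, {hi}] for {parameter_name!r}"
        )

    scan = np.linspace(lo, hi, prescan_points)
    flags = [eval_at(float(v)) for v in scan]
    flips = sum(1 for a, b in zip(flags, flags[1:]) if a != b)
    if flips > 1:
        warnings.warn(
            f"outcome predicate is non-monotone in {parameter_name!r} on [{lo}, {hi}] "
            f"({flips} reversals in a {prescan_points}-point pre-scan)",
            stacklevel=2,
        )

    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if eval_at(mid) == p_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(value=0.5 * (lo + hi), bracket=(lo, hi), predicate_at_lower=p_lo)
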