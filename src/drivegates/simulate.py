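"""Multi-generation trajectory runs with induction scheduling.

A run iterates the selected variant's one-generation update from an initial
drive frequency until either allele exceeds the fixation threshold or a
generation cap is reached.  The external signal, when enabled, switches on
at a configured generation: the transition producing generation
``start_generation + 1`` is the first induced one, and the signal stays on
for every later transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .models import (
    AlleleState,
    DegeneratePopulationError,
    DriveParams,
    InductionSettings,
    ModelVariant,
    effective_params,
    step,
)

__all__ = [
    "Outcome",
    "SimulationConfig",
    "Trajectory",
    "run",
    "classify_outcome",
    "time_to_fixation",
]


class Outcome(str, Enum):
    """Terminal classification of a trajectory."""

    GD_FIXATION = "GD_FIXATION"
    WT_FIXATION = "WT_FIXATION"
    NO_FIXATION = "NO_FIXATION"


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one trajectory.

    Defaults follow the study conditions: drive introduced at 0.1% allele
    frequency, fixation declared when any allele strictly exceeds 0.99999,
    and a 1,000-generation cap.
    """

    params: DriveParams
    variant: ModelVariant = ModelVariant.STANDARD
    induction: InductionSettings = field(default_factory=InductionSettings)
    initial_q_D: float = 0.001
    max_generations: int = 1000
    fixation_threshold: float = 0.99999

    def __post_init__(self) -> None:
        if not (0.0 < self.initial_q_D < 1.0):
            raise ValueError(f"initial_q_D must lie in (0, 1), got {self.initial_q_D!r}")
        if not (0.5 < self.fixation_threshold < 1.0):
            raise ValueError(
                f"fixation_threshold must lie in (0.5, 1), got {self.fixation_threshold!r}"
            )
        if self.max_generations < 1:
            raise ValueError(f"max_generations must be >= 1, got {self.max_generations!r}")


@dataclass(frozen=True)
class Trajectory:
    """Per-generation allele states plus the terminal classification."""

    states: tuple[AlleleState, ...]
    outcome: Outcome
    fixation_generation: int | None
    induction_applied_from: int | None

    @property
    def final_q_D(self) -> float:
        return self.states[-1].q_D

    def frequencies(self) -> list[float]:
        return [s.q_D for s in self.states]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per generation.

        ``induced`` flags generations exposed to the external signal
        (``generation >= induction_applied_from``); the first induced
        transition is the one leaving the first flagged generation.
        """
        start = self.induction_applied_from
        rows = {
            "generation": [s.generation for s in self.states],
            "q_D": [s.q_D for s in self.states],
            "q_W": [s.q_W for s in self.states],
            "induced": [
                int(start is not None and s.generation >= start) for s in self.states
            ],
        }
        return pd.DataFrame(rows)


def classify_outcome(final_q_D: float, fixation_threshold: float) -> Outcome:
    """Map a final drive frequency to a terminal outcome label.

    Strict inequalities on both sides; anything in between (at the
    generation cap) is NO_FIXATION.
    """
    if final_q_D > fixation_threshold:
        return Outcome.GD_FIXATION
    if (1.0 - final_q_D) > fixation_threshold:
        return Outcome.WT_FIXATION
    return Outcome.NO_FIXATION


def run(config: SimulationConfig) -> Trajectory:
    """Run one deterministic trajectory.

    The transition producing generation ``g + 1`` uses induced parameters
    iff induction is enabled and ``g >= start_generation``.  The fixation
    check is applied after every update and also at generation 0, so a
    starting frequency beyond the threshold terminates immediately.

    Raises
    ------
    DegeneratePopulationError
        Re-raised with the generation at which mean fitness collapsed.
    """
    q = config.initial_q_D
    states = [AlleleState(q_D=q, generation=0)]
    threshold = config.fixation_threshold

    fixation_generation: int | None = None
    if q > threshold or (1.0 - q) > threshold:
        fixation_generation = 0
    else:
        for g in range(config.max_generations):
            eff = effective_params(config.params, config.induction, g, config.variant)
            try:
                q = step(q, config.params, config.variant, eff)
            except DegeneratePopulationError as err:
                raise DegeneratePopulationError(str(err), generation=g + 1) from err
            states.append(AlleleState(q_D=q, generation=g + 1))
            if q > threshold or (1.0 - q) > threshold:
                fixation_generation = g + 1
                break

    outcome = classify_outcome(q, threshold)
    induced_from = config.induction.start_generation if config.induction.enabled else None
    return Trajectory(
        states=tuple(states),
        outcome=outcome,
        fixation_generation=fixation_generation if outcome is not Outcome.NO_FIXATION else None,
        induction_applied_from=induced_from,
    )


def time_to_fixation(trajectory: Trajectory) -> int | None:
    """First generation whose frequency exceeds the threshold; None if never."""
    return trajectory.fixation_generation
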