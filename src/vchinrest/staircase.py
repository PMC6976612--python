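"""1-up 3-down transformed staircase over target--flanker spacing.

The crowding task adapts the center-to-center spacing between the
target and its flankers: any wrong response makes the task easier
(spacing up, one step), three consecutive correct responses make it
harder (spacing down, one step).  A 1-up n-down rule converges where
P(correct)^n = 1/2, i.e. at P(correct) = 0.5**(1/n); for n = 3 that is
0.7937, the familiar 79.4% point.

Steps are multiplicative (constant in log-spacing, factor 1.2 by
default) because critical spacing spans a multiplicative range; the
threshold is the geometric mean of the last few reversal spacings
(6 by default), consistent with log-spaced steps.  An arithmetic-mean
estimator is selectable.  Spacing is clamped, not terminated, at the
configured bounds: 1 degree (the flanker diameter, preventing overlap)
below, the eccentricity (preventing flankers crossing fixation) above.

``update`` is a pure function of (state, correct): replaying a logged
response sequence reproduces the history bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

#: Flanker/target circle diameter in degrees; also the lower spacing bound.
STIMULUS_DIAMETER_DEG = 1.0


class EstimationError(RuntimeError):
    """Threshold could not be estimated; carries the partial state."""

    def __init__(self, message: str, state: "StaircaseState | None" = None):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one 1-up 3-down track.

    ``start_spacing_deg`` defaults to 1.3 x eccentricity / 2 when built
    via :func:`init_staircase` (3.9 deg at 6 deg eccentricity, 2.6 deg
    at 4 deg).
    """

    eccentricity_deg: float
    start_spacing_deg: float
    n_trials: int = 25
    step_factor: float = 1.2
    min_spacing_deg: float = STIMULUS_DIAMETER_DEG
    max_spacing_deg: float = field(default=None)  # type: ignore[assignment]
    n_down: int = 3
    n_reversals_for_threshold: int = 6
    threshold_estimator: str = "geometric"

    def __post_init__(self) -> None:
        if self.max_spacing_deg is None:
            object.__setattr__(self, "max_spacing_deg", self.eccentricity_deg)
        if not self.eccentricity_deg > 0:
            raise ValueError(f"eccentricity_deg must be > 0, got {self.eccentricity_deg}")
        if not self.step_factor > 1:
            raise ValueError(f"step_factor must be > 1, got {self.step_factor}")
        if not (self.min_spacing_deg < self.start_spacing_deg <= self.max_spacing_deg):
            raise ValueError(
                "need min_spacing_deg < start_spacing_deg <= max_spacing_deg, got "
                f"{self.min_spacing_deg}, {self.start_spacing_deg}, {self.max_spacing_deg}"
            )
        if self.threshold_estimator not in ("geometric", "arithmetic"):
            raise ValueError(f"unknown threshold_estimator {self.threshold_estimator!r}")
        if self.n_down < 1:
            raise ValueError(f"n_down must be >= 1, got {self.n_down}")


@dataclass(frozen=True)
class StaircaseState:
    """Immutable snapshot of a running staircase.

    ``history`` holds (spacing, correct) per trial; ``reversal_spacings``
    the spacing at each trial where the step direction flipped (the
    first direction change is the first reversal).
    """

    config: StaircaseConfig
    spacing_deg: float
    consecutive_correct: int = 0
    direction: str = "none"  # none | up | down
    reversal_spacings: tuple = ()
    history: tuple = ()


def init_staircase(eccentricity_deg: float, **overrides) -> StaircaseConfig:
    """Staircase config from the eccentricity alone.

    Start spacing = 1.3 x eccentricity / 2; bounds [1 deg, eccentricity].
    Keyword overrides pass through to :class:`StaircaseConfig`.
    """
    if not eccentricity_deg > 0:
        raise ValueError(f"eccentricity_deg must be > 0, got {eccentricity_deg}")
    kwargs = dict(
        eccentricity_deg=float(eccentricity_deg),
        start_spacing_deg=1.3 * eccentricity_deg / 2.0,
    )
    kwargs.update(overrides)
    return StaircaseConfig(**kwargs)


def new_state(config: StaircaseConfig) -> StaircaseState:
    return StaircaseState(config=config, spacing_deg=config.start_spacing_deg)


def update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance one trial: 1-up on any error, 3-down on a correct triplet.

    Pure: returns a new state, never mutates.  A step that would leave
    the bounds is clamped; the 3-down counter resets on any wrong
    response and after a down-step.
    """
    cfg = state.config
    spacing = state.spacing_deg
    cc = state.consecutive_correct
    step: str | None = None

    if correct:
        cc += 1
        if cc >= cfg.n_down:
            step = "down"
            cc = 0
    else:
        step = "up"
        cc = 0

    direction = state.direction
    reversals = state.reversal_spacings
    new_spacing = spacing
    if step is not None:
        if direction not in ("none", step):
            reversals = reversals + (spacing,)
        direction = step
        factor = cfg.step_factor if step == "up" else 1.0 / cfg.step_factor
        new_spacing = min(max(spacing * factor, cfg.min_spacing_deg),
                          cfg.max_spacing_deg)

    return replace(
        state,
        spacing_deg=new_spacing,
        consecutive_correct=cc,
        direction=direction,
        reversal_spacings=reversals,
        history=state.history + ((spacing, bool(correct)),),
    )


def threshold(state: StaircaseState) -> float:
    """Crowding threshold from reversal spacings, degrees.

    Geometric (default) or arithmetic mean of the last
    ``n_reversals_for_threshold`` reversals; all reversals if fewer.
    Raises :class:`EstimationError` (carrying the state) with fewer
    than 2 reversals.
    """
    cfg = state.config
    revs = state.reversal_spacings
    if len(revs) < 2:
        raise EstimationError(
            f"need >= 2 reversals to estimate a threshold, got {len(revs)}",
            state=state,
        )
    use = revs[-cfg.n_reversals_for_threshold:]
    if cfg.threshold_estimator == "geometric":
        return float(math.exp(np.mean(np.log(use))))
    return float(np.mean(use))


def convergence_probability(n_down: int = 3) -> float:
    """Equilibrium P(correct) of a 1-up n-down rule: 0.5**(1/n).

    At equilibrium an up-step (any error) and a down-step (n straight
    corrects) are equally likely, so p**n = 1/2.  For n = 3 this is
    0.7937 -- performance converges to ~79.4% correct.
    """
    if n_down < 1:
        raise ValueError(f"n_down must be >= 1, got {n_down}")
    return 0.5 ** (1.0 / n_down)


def run_staircase(
    config: StaircaseConfig,
    respond: Callable[[float], bool],
    n_trials: int | None = None,
) -> StaircaseState:
    """Drive a staircase with a response callback ``respond(spacing) -> bool``."""
    state = new_state(config)
    for _ in range(n_trials if n_trials is not None else config.n_trials):
        state = update(state, respond(state.spacing_deg))
    return state
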