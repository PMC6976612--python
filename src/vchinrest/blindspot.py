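"""Blind-spot sweep simulation and viewing-distance estimation.

In the sweep task the participant fixates a black square with the right
eye closed while a red dot sweeps from right to left and presses a key
the moment the dot vanishes into the blind spot.  The horizontal
fixation-to-dot offset at the keypress, averaged over a handful of
sweeps, is the physical distance ``s`` feeding ``d = s / tan(alpha)``.

The simulator abstracts the sweep into the keypress offset directly:
each trial's offset is ``true_d * tan(entry_angle)`` plus Gaussian
keypress noise on the on-screen position (default SD 2 mm).  Offsets are
unsigned magnitudes; logs store pixels, estimation is done in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import DEFAULT_ALPHA_DEG, DisplayCalibration, mm_to_px, px_to_mm

#: Mean angular diameter of the human blind spot, degrees.
BLINDSPOT_DIAMETER_DEG = 4.5


@dataclass(frozen=True)
class BlindspotTrial:
    """One sweep trial: dot-center offset from fixation at the keypress."""

    disappear_offset_px: float
    sweep_direction: str = "right-to-left"

    def __post_init__(self) -> None:
        if not self.disappear_offset_px > 0:
            raise ValueError(
                f"disappear_offset_px must be > 0, got {self.disappear_offset_px}"
            )


@dataclass(frozen=True)
class BlindspotResult:
    """Distance estimate from a block of sweep trials.

    ``s_mm`` is the mean per-trial offset in mm and ``d_mm`` the derived
    viewing distance ``s_mm / tan(alpha_deg)``.
    """

    s_mm: float
    d_mm: float
    n_trials: int
    per_trial_offsets_mm: tuple
    alpha_deg: float = DEFAULT_ALPHA_DEG


def estimate_distance(
    trials: Sequence[BlindspotTrial],
    cal: DisplayCalibration,
    alpha_deg: float = DEFAULT_ALPHA_DEG,
) -> BlindspotResult:
    """Average sweep offsets (in mm) and apply d = s / tan(alpha).

    Raises ``ValueError`` on an empty trial list.  The result is
    invariant to trial order.
    """
    if len(trials) == 0:
        raise ValueError("need at least one blind-spot trial")
    if not 0 < alpha_deg < 90:
        raise ValueError(f"alpha_deg must be in (0, 90), got {alpha_deg}")
    offsets_mm = tuple(px_to_mm(t.disappear_offset_px, cal) for t in trials)
    s_mm = float(np.mean(offsets_mm))
    d_mm = s_mm / math.tan(math.radians(alpha_deg))
    return BlindspotResult(
        s_mm=s_mm,
        d_mm=d_mm,
        n_trials=len(trials),
        per_trial_offsets_mm=offsets_mm,
        alpha_deg=alpha_deg,
    )


def simulate_sweep(
    observer,
    true_d_mm: float,
    cal: DisplayCalibration,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
    noise_sd_mm: float = 2.0,
) -> list[BlindspotTrial]:
    """Simulate ``n_trials`` sweep keypresses for one observer.

    The noiseless offset is ``true_d_mm * tan(blindspot_entry_deg)``;
    Gaussian keypress noise (``noise_sd_mm``, on-screen mm) is added and
    the offset clamped positive.

    Parameters
    ----------
    observer:
        Anything with a ``blindspot_entry_deg`` attribute.
    rng:
        ``numpy`` Generator or seed; fixed seeds reproduce trials.
    """
    if not true_d_mm > 0:
        raise ValueError(f"true_d_mm must be > 0, got {true_d_mm}")
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    base_mm = true_d_mm * math.tan(math.radians(observer.blindspot_entry_deg))
    trials = []
    for _ in range(n_trials):
        offset_mm = base_mm + (rng.normal(0.0, noise_sd_mm) if noise_sd_mm > 0 else 0.0)
        offset_mm = max(offset_mm, 1e-9)
        trials.append(BlindspotTrial(disappear_offset_px=mm_to_px(offset_mm, cal)))
    return trials


def backsolve_alpha(known_d_mm: float, result: BlindspotResult) -> float:
    """Blind-spot entry angle implied by a known viewing distance.

    Validation-study arithmetic: with the true distance fixed by a
    physical chinrest, ``atan(s / d)`` recovers the participant's entry
    angle in degrees.
    """
    if not known_d_mm > 0:
        raise ValueError(f"known_d_mm must be > 0, got {known_d_mm}")
    return math.degrees(math.atan(result.s_mm / known_d_mm))


def blindspot_center(entry_deg: float,
                     diameter_deg: float = BLINDSPOT_DIAMETER_DEG) -> float:
    """Angular position of the blind-spot center from its entry point.

    The sweep detects the blind spot's near (entry) edge; the center
    lies half a diameter further out: ``entry + diameter / 2``.
    """
    if not diameter_deg > 0:
        raise ValueError(f"diameter_deg must be > 0, got {diameter_deg}")
    return entry_deg + diameter_deg / 2.0
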