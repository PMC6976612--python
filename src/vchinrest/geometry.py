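"""Display calibration and visual-angle arithmetic.

Remote psychophysics has to recover two quantities that a lab controls
physically: the display's pixel pitch and the participant's viewing
distance.  The card task gives the first as a *logical pixel density*
(LPD, pixels per millimetre): the participant scales an on-screen card
image until it matches a physical credit card, whose standardized width
is 85.60 mm, so

    LPD = card_image_width_px / 85.60

The blind-spot task gives the second: with the fixation mark and the
blind-spot entry point separated by a physical on-screen distance ``s``
(mm), and the entry point lying at a known angle ``alpha`` temporal to
fixation (13.5 degrees on average), simple trigonometry yields the
viewing distance

    d = s / tan(alpha)

Everything else in the package converts between the three unit systems
this implies -- device pixels, physical millimetres on the screen, and
degrees of visual angle at a given viewing distance.  Internally mm and
degrees are canonical; pixels appear only at I/O boundaries.

Degrees are mapped to on-screen extent with the exact tangent, not the
small-angle approximation (at 13.5 degrees the small-angle error is
already ~2%).  The screen is assumed flat and perpendicular to gaze at
fixation; no off-axis tangent-screen correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: Physical width of an ISO/IEC 7810 ID-1 card (credit card), mm.
CARD_WIDTH_MM = 85.60

#: Average angular position of the blind-spot entry point, degrees
#: temporal to fixation, used as the calibration angle.
DEFAULT_ALPHA_DEG = 13.5


@dataclass(frozen=True)
class DisplayCalibration:
    """Logical pixel density of a display, from the card task.

    Attributes
    ----------
    card_image_width_px:
        Width in pixels of the on-screen card image after the
        participant matched it to the physical card.
    lpd:
        Logical pixel density in pixels per millimetre; always equal to
        ``card_image_width_px / 85.60``.
    physical_card_width_mm:
        Width of the physical reference card (fixed, 85.60 mm).
    """

    card_image_width_px: float
    lpd: float
    physical_card_width_mm: float = field(default=CARD_WIDTH_MM)

    def __post_init__(self) -> None:
        if not self.card_image_width_px > 0:
            raise ValueError(
                f"card_image_width_px must be > 0, got {self.card_image_width_px}"
            )
        if not self.lpd > 0:
            raise ValueError(f"lpd must be > 0, got {self.lpd}")
        if self.lpd != self.card_image_width_px / self.physical_card_width_mm:
            raise ValueError(
                "inconsistent calibration: lpd must equal "
                "card_image_width_px / physical_card_width_mm"
            )

    def to_json_dict(self) -> dict:
        return {
            "card_image_width_px": self.card_image_width_px,
            "lpd_px_per_mm": self.lpd,
        }


@dataclass(frozen=True)
class ViewingGeometry:
    """Calibration angle, on-screen offset, and derived viewing distance.

    ``d_mm == s_mm / tan(alpha_deg)`` when built with :meth:`from_offset`.
    """

    alpha_deg: float
    s_mm: float
    d_mm: float

    def __post_init__(self) -> None:
        if not 0 < self.alpha_deg < 90:
            raise ValueError(f"alpha_deg must be in (0, 90), got {self.alpha_deg}")
        if not self.s_mm > 0:
            raise ValueError(f"s_mm must be > 0, got {self.s_mm}")
        if not self.d_mm > 0:
            raise ValueError(f"d_mm must be > 0, got {self.d_mm}")

    @classmethod
    def from_offset(cls, s_mm: float, alpha_deg: float = DEFAULT_ALPHA_DEG) -> "ViewingGeometry":
        return cls(alpha_deg=alpha_deg, s_mm=s_mm,
                   d_mm=viewing_distance(s_mm, alpha_deg))


def compute_lpd(card_image_width_px: float) -> DisplayCalibration:
    """Logical pixel density from the matched card-image width.

    Parameters
    ----------
    card_image_width_px:
        Width of the card image in pixels; must be positive.

    Returns
    -------
    DisplayCalibration
        With ``lpd = card_image_width_px / 85.60`` px/mm.
    """
    if not card_image_width_px > 0:
        raise ValueError(f"card_image_width_px must be > 0, got {card_image_width_px}")
    return DisplayCalibration(
        card_image_width_px=float(card_image_width_px),
        lpd=float(card_image_width_px) / CARD_WIDTH_MM,
    )


def viewing_distance(s_mm: float, alpha_deg: float = DEFAULT_ALPHA_DEG) -> float:
    """Viewing distance d = s / tan(alpha), in mm.

    ``s_mm`` is the physical on-screen distance between fixation and the
    blind-spot entry point; ``alpha_deg`` the angular position of the
    entry point (default 13.5 degrees).
    """
    if not s_mm > 0:
        raise ValueError(f"s_mm must be > 0, got {s_mm}")
    if not 0 < alpha_deg < 90:
        raise ValueError(f"alpha_deg must be in (0, 90), got {alpha_deg}")
    return s_mm / math.tan(math.radians(alpha_deg))


def px_to_mm(px: float, cal: DisplayCalibration) -> float:
    """Convert an on-screen extent from pixels to physical mm."""
    return px / cal.lpd


def mm_to_px(mm: float, cal: DisplayCalibration) -> float:
    """Convert a physical on-screen extent from mm to pixels."""
    return mm * cal.lpd


def deg_to_px(angle_deg: float, d_mm: float, cal: DisplayCalibration) -> float:
    """On-screen extent in pixels subtending ``angle_deg`` at distance ``d_mm``.

    Uses the exact tangent: extent_px = tan(angle) * d * LPD.
    """
    if not d_mm > 0:
        raise ValueError(f"d_mm must be > 0, got {d_mm}")
    if not abs(angle_deg) < 90:
        raise ValueError(f"|angle_deg| must be < 90, got {angle_deg}")
    return math.tan(math.radians(angle_deg)) * d_mm * cal.lpd


def px_to_deg(px: float, d_mm: float, cal: DisplayCalibration) -> float:
    """Visual angle in degrees subtended by ``px`` pixels at distance ``d_mm``.

    Exact inverse of :func:`deg_to_px`.
    """
    if not d_mm > 0:
        raise ValueError(f"d_mm must be > 0, got {d_mm}")
    return math.degrees(math.atan(px / (d_mm * cal.lpd)))
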