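"""Viewing geometry: physical letter size <-> logMAR, with pixel-grid quantization.

Acuity levels are expressed in logMAR, the base-10 log of the minimum angle of
resolution (MAR) in arcminutes; the MAR of an optotype is the angle subtended
by one stroke, i.e. one fifth of the letter.  Letters are rendered on a
discrete pixel grid: one noise check is an integer number of screen pixels and
a letter spans 5*checks_per_stroke checks, so only a discrete ladder of sizes
(and hence logMAR values) is achievable at a given viewing distance.  The
exact atan is used throughout; at metre-scale distances it differs from the
small-angle approximation only in the 7th decimal, but exactness costs
nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ViewingGeometry", "AcuityLevel", "size_to_logmar", "logmar_to_size"]

_ARCMIN_PER_RAD = 60.0 * 180.0 / math.pi


@dataclass(frozen=True)
class ViewingGeometry:
    """Observer-to-screen distance and the screen's pixel pitch.

    Defaults follow the stimulus convention of one 0.47 mm pixel per noise
    check at the smallest size and three checks per letter stroke.
    """

    distance_m: float
    pixel_pitch_mm: float = 0.47
    checks_per_stroke: int = 3

    def __post_init__(self) -> None:
        if self.distance_m <= 0:
            raise ValueError("distance_m must be positive")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be positive")
        if self.checks_per_stroke < 1:
            raise ValueError("checks_per_stroke must be >= 1")

    @property
    def letter_side_unit_px(self) -> int:
        """Letter side, in pixels, at the minimum one-pixel-per-check size."""
        return 5 * self.checks_per_stroke


@dataclass(frozen=True)
class AcuityLevel:
    """An achievable acuity level: the logMAR actually rendered, not requested."""

    logmar: float
    mar_arcmin: float
    letter_side_px: int
    check_size_px: int


def size_to_logmar(letter_side_px: int, geometry: ViewingGeometry) -> AcuityLevel:
    """logMAR of a letter of the given pixel side at the given geometry.

    The MAR is the angle of one stroke = letter_side_px/5 pixels.
    """
    unit = geometry.letter_side_unit_px
    if letter_side_px < unit or letter_side_px % unit != 0:
        raise ValueError(
            f"letter_side_px must be a positive multiple of 5*checks_per_stroke "
            f"= {unit} (one check = an integer number of screen pixels); "
            f"got {letter_side_px}"
        )
    stroke_mm = (letter_side_px / 5.0) * geometry.pixel_pitch_mm
    angle_rad = math.atan2(stroke_mm, 1000.0 * geometry.distance_m)
    mar_arcmin = angle_rad * _ARCMIN_PER_RAD
    return AcuityLevel(
        logmar=math.log10(mar_arcmin),
        mar_arcmin=mar_arcmin,
        letter_side_px=letter_side_px,
        check_size_px=letter_side_px // unit,
    )


def logmar_to_size(target_logmar: float, geometry: ViewingGeometry) -> AcuityLevel:
    """Nearest achievable acuity level for a requested logMAR.

    Candidate sizes are integer check pixel counts; the one minimizing
    |achieved - target| in logMAR wins, with exact ties broken toward the
    larger letter (conservative: avoids floor effects in adaptive tracks).
    Targets below the one-pixel-per-check floor raise, reporting the floor.
    """
    unit = geometry.letter_side_unit_px
    floor = size_to_logmar(unit, geometry)
    if target_logmar < floor.logmar - 1e-12:
        raise ValueError(
            f"target logMAR {target_logmar:.4f} is below the 1-pixel-check floor "
            f"{floor.logmar:.4f} for distance {geometry.distance_m} m"
        )
    # invert: stroke angle tan = checks_per_stroke*check_px*pitch / distance
    mar_rad = (10.0 ** target_logmar) / _ARCMIN_PER_RAD
    stroke_mm = math.tan(mar_rad) * 1000.0 * geometry.distance_m
    check_px_real = stroke_mm / (geometry.pixel_pitch_mm * geometry.checks_per_stroke)
    lo = max(1, math.floor(check_px_real))
    candidates = [size_to_logmar(unit * k, geometry) for k in (lo, lo + 1)]
    d0 = abs(candidates[0].logmar - target_logmar)
    d1 = abs(candidates[1].logmar - target_logmar)
    if abs(d0 - d1) <= 1e-12:
        return candidates[1]  # tie: larger letter
    return candidates[0] if d0 < d1 else candidates[1]
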