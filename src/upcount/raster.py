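"""Laser raster-scan geometry.

A flyback raster ablates left-to-right along each line, closes a mechanical
shutter, returns without firing, steps down by one line spacing and repeats.
This module encodes that schedule and converts acquisition time to stage
position and pixel indices.  Coordinates: origin at the top-left corner of
the raster, x along the scan lines, y down, all lengths in micrometres.
Pixel (0, 0) covers the half-open square ``[0, pixel) x [0, pixel)``; the
map pixel size is the pulse pitch along x and the line spacing along y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "RasterPlan",
    "InvalidConfigError",
    "OutOfScheduleError",
    "WashoutDiagnostic",
    "pulse_pitch",
    "overlap_fractions",
    "time_to_position",
    "time_to_pixel",
    "pixel_time_window",
    "check_washout",
]


class InvalidConfigError(ValueError):
    """Raised when a raster plan violates its physical invariants."""


class OutOfScheduleError(ValueError):
    """Raised when a query time lies beyond the end of the scan schedule."""


@dataclass(frozen=True)
class RasterPlan:
    """Geometry and timing of a flyback laser raster.

    Parameters
    ----------
    spot_diameter
        Laser spot diameter in μm.
    scan_speed
        Stage speed along a line in μm/s.
    repetition_rate
        Laser repetition rate in Hz.
    line_spacing
        Distance between adjacent lines in μm; spacing below the spot
        diameter gives overlapping lines.
    area_width, area_height
        Extent of the rastered rectangle in μm.
    origin_x, origin_y
        Top-left corner of the raster in μm.
    scan_mode
        Only ``"flyback"`` is supported: every line is ablated in the same
        direction with a non-acquiring return.
    shutter_blanking
        Whether the shutter blocks the beam during the return (the return
        is non-acquiring either way).
    washout_time_ms
        Ablation-cell washout time in ms, or ``None`` if unknown.
    flyback_return_s
        Time for the non-acquiring return per line in s.  Not a physical
        model — only the ordering of events matters.
    """

    spot_diameter: float
    scan_speed: float
    repetition_rate: float
    line_spacing: float
    area_width: float
    area_height: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    scan_mode: str = "flyback"
    shutter_blanking: bool = True
    washout_time_ms: float | None = None
    flyback_return_s: float = 0.5

    def __post_init__(self) -> None:
        for name in ("spot_diameter", "scan_speed", "repetition_rate",
                     "line_spacing", "area_width", "area_height"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if self.scan_mode != "flyback":
            raise InvalidConfigError(f"unsupported scan_mode {self.scan_mode!r}")
        if self.flyback_return_s < 0:
            raise InvalidConfigError("flyback_return_s must be non-negative")

    # -- derived schedule quantities -------------------------------------

    @property
    def n_lines(self) -> int:
        """Number of scan lines needed to cover the raster height."""
        return max(1, math.ceil(round(self.area_height / self.line_spacing, 9)))

    @property
    def line_duration_s(self) -> float:
        """Acquiring time per line in s."""
        return self.area_width / self.scan_speed

    @property
    def line_period_s(self) -> float:
        """Line duration plus the non-acquiring flyback return, in s."""
        return self.line_duration_s + self.flyback_return_s

    @property
    def total_duration_s(self) -> float:
        """End of the schedule: the last line has no return."""
        return self.n_lines * self.line_duration_s + (self.n_lines - 1) * self.flyback_return_s

    @property
    def total_acquiring_s(self) -> float:
        return self.n_lines * self.line_duration_s

    @property
    def n_pixels_x(self) -> int:
        return max(1, math.ceil(round(self.area_width / pulse_pitch(self), 9)))

    @property
    def n_pixels_y(self) -> int:
        return self.n_lines


def pulse_pitch(plan: RasterPlan) -> float:
    """Distance in μm the stage travels between consecutive laser pulses.

    150 μm/s at 10 Hz gives the 15 μm pixel pitch used for imaging.
    """
    if plan.repetition_rate <= 0:
        raise InvalidConfigError("repetition_rate must be positive")
    return plan.scan_speed / plan.repetition_rate


def overlap_fractions(plan: RasterPlan) -> tuple[float, float]:
    """Fractional spot overlap (along_line, between_lines), clamped to [0, 1].

    A 30 μm spot with 15 μm line spacing overlaps adjacent lines by 50%;
    the same spot at a 15 μm pulse pitch overlaps consecutive pulses by 50%.
    """
    if plan.spot_diameter <= 0:
        raise InvalidConfigError("spot_diameter must be positive")
    along = 1.0 - pulse_pitch(plan) / plan.spot_diameter
    between = 1.0 - plan.line_spacing / plan.spot_diameter
    clamp = lambda v: min(1.0, max(0.0, v))
    return clamp(along), clamp(between)


def time_to_position(t: float, plan: RasterPlan) -> tuple[float, float, bool]:
    """Map acquisition time (s from schedule start) to stage position.

    Returns ``(x_um, y_um, acquiring)``.  During the flyback return the
    laser is blanked: ``acquiring`` is False and the reported position is
    the end of the just-finished line.
    """
    if t < 0:
        raise OutOfScheduleError(f"t={t} s is before the schedule start")
    if t > plan.total_duration_s + 1e-12:
        raise OutOfScheduleError(
            f"t={t} s is beyond the schedule end ({plan.total_duration_s} s)")
    period = plan.line_period_s
    line = min(int(t / period), plan.n_lines - 1)
    t_in = t - line * period
    y = plan.origin_y + line * plan.line_spacing
    if t_in <= plan.line_duration_s:
        return plan.origin_x + plan.scan_speed * t_in, y, True
    return plan.origin_x + plan.area_width, y, False


def time_to_pixel(t: float, plan: RasterPlan) -> tuple[int, int, bool]:
    """Pixel indices ``(ix, iy, acquiring)`` for an acquisition time.

    Pixels are pulse_pitch wide along x and line_spacing tall along y;
    ``ix`` is clipped to the raster width so the end-of-line instant maps
    to the last pixel.
    """
    x, _, acquiring = time_to_position(t, plan)
    period = plan.line_period_s
    iy = min(int(t / period), plan.n_lines - 1)
    ix = int((x - plan.origin_x) / pulse_pitch(plan))
    ix = min(max(ix, 0), plan.n_pixels_x - 1)
    return ix, iy, acquiring


def pixel_time_window(ix: int, iy: int, plan: RasterPlan) -> tuple[float, float]:
    """Half-open acquiring-time window [t0, t1) during which pixel (ix, iy)
    is under the beam."""
    if not (0 <= ix < plan.n_pixels_x and 0 <= iy < plan.n_pixels_y):
        raise OutOfScheduleError(f"pixel ({ix}, {iy}) outside the raster")
    pitch = pulse_pitch(plan)
    t0 = iy * plan.line_period_s + ix * pitch / plan.scan_speed
    t1 = iy * plan.line_period_s + min((ix + 1) * pitch, plan.area_width) / plan.scan_speed
    return t0, t1


@dataclass(frozen=True)
class WashoutDiagnostic:
    passed: bool
    inter_pulse_ms: float
    washout_ms: float | None
    message: str


def check_washout(plan: RasterPlan) -> WashoutDiagnostic:
    """Check that the inter-pulse interval exceeds the ablation-cell washout.

    Failing this check smears particles into following pixels (an imaging
    artefact); the total number of detected particles is unaffected, so
    counting-based transport efficiency remains valid.
    """
    inter_ms = 1000.0 / plan.repetition_rate
    if plan.washout_time_ms is None:
        return WashoutDiagnostic(True, inter_ms, None,
                                 "washout time unset; check skipped")
    if inter_ms >= plan.washout_time_ms:
        return WashoutDiagnostic(True, inter_ms, plan.washout_time_ms,
                                 f"inter-pulse {inter_ms:.0f} ms >= washout "
                                 f"{plan.washout_time_ms:.0f} ms")
    return WashoutDiagnostic(False, inter_ms, plan.washout_time_ms,
                             f"inter-pulse {inter_ms:.0f} ms < washout "
                             f"{plan.washout_time_ms:.0f} ms: expect pixel "
                             "spillover (counting unaffected)")


def plan_from_dict(cfg: dict) -> RasterPlan:
    """Build a RasterPlan from a flat key-value mapping (YAML/JSON config)."""
    known = {f for f in RasterPlan.__dataclass_fields__}
    unknown = set(cfg) - known
    if unknown:
        raise InvalidConfigError(f"unknown raster config keys: {sorted(unknown)}")
    return RasterPlan(**cfg)
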