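"""Virtual sound-image kinematics and the virtual-impact model.

A panning stimulus sweeps a virtual sound image across the listener.  How
far, and over what effective time, depends on the listening device:

* **ears-free** (open-ear) headphone with a speaker array: the image moves
  the full speaker separation D = 2 m in the 1-s sweep — about 2 m/s;
* **closed-type** headphone: the image is only audible between the auricles
  (inter-auricular distance L = 0.20 m) for an assumed effective 0.5 s —
  about 0.4 m/s;
* **bone-conduction** headphone: the stimulus couples directly to the inner
  ears, so the travel distance is the inner-ear separation of about 0.12 m
  over the same 0.5 s — about 0.24 m/s.

Sound itself is massless; the *virtual impact* assigns a nominal mass to the
moving image, ``impact = effective_mass x virtual_speed`` (kg·m/s), as a
heuristic ranking of how strongly each device's stimulus could perturb
stance.  With the default 100 kg effective mass the devices rank
ears-free (200) > closed (40) > bone (24).

For bone conduction the tissue path (~3 cm at ~1,500 m/s, the speed of sound
in water) is crossed in 0.02 ms — an equivalent rate of 50 kHz, far above
the audible range, which is why the array-to-auricle leg is negligible for
that device.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "DeviceGeometry",
    "VirtualImpactResult",
    "DEVICES",
    "default_geometries",
    "virtual_speed",
    "virtual_impact",
    "conduction_travel",
    "impact_table",
]

DEVICES = ("ears_free", "closed", "bone")


@dataclass(frozen=True)
class DeviceGeometry:
    """Geometry and timing of the virtual sound-image path for one device.

    ``medium_speed`` and ``tissue_path_length`` parameterize the
    bone-conduction tissue leg (defaults: 1,500 m/s, 0.03 m); they are inert
    for the other devices but validated for all.
    """

    device: str
    travel_distance: float  # m
    scan_time: float  # s
    medium_speed: float = 1500.0  # m/s
    tissue_path_length: float = 0.03  # m

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise ValidationError(f"unknown device {self.device!r}; expected {DEVICES}")
        for name in ("travel_distance", "scan_time", "medium_speed", "tissue_path_length"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass(frozen=True)
class VirtualImpactResult:
    """Virtual momentum assigned to a moving sound image."""

    device: str
    virtual_speed: float  # m/s
    unit_mass: float  # kg
    effective_mass: float  # kg
    impact: float  # kg m/s

    def __post_init__(self) -> None:
        if abs(self.impact - self.effective_mass * self.virtual_speed) > 1e-9 * max(
            1.0, abs(self.impact)
        ):
            raise ValidationError("impact must equal effective_mass * virtual_speed")


def default_geometries() -> dict[str, DeviceGeometry]:
    """Device geometries for the reference setup: array speakers 1 m left and
    1 m right of the midline (D = 2 m) scanned in 1 s; inter-auricular
    distance L = 0.20 m; inner-ear separation 0.12 m; effective scan time
    0.5 s for the closed and bone devices."""
    return {
        "ears_free": DeviceGeometry("ears_free", travel_distance=2.0, scan_time=1.0),
        "closed": DeviceGeometry("closed", travel_distance=0.20, scan_time=0.5),
        "bone": DeviceGeometry("bone", travel_distance=0.12, scan_time=0.5),
    }


def virtual_speed(geometry: DeviceGeometry) -> float:
    """Virtual sound-image travel speed, ``travel_distance / scan_time`` (m/s)."""
    return geometry.travel_distance / geometry.scan_time


def virtual_impact(speed: float, effective_mass: float = 100.0) -> float:
    """Virtual impact (momentum) of the moving image, kg·m/s.

    A unit mass of 1 kg scaled by 100 (a nominal body mass) is the default
    effective mass.
    """
    if speed < 0:
        raise ValidationError("speed must be nonnegative")
    if effective_mass <= 0:
        raise ValidationError("effective_mass must be positive")
    return effective_mass * speed


def impact_result(
    geometry: DeviceGeometry, effective_mass: float = 100.0, unit_mass: float = 1.0
) -> VirtualImpactResult:
    speed = virtual_speed(geometry)
    return VirtualImpactResult(
        device=geometry.device,
        virtual_speed=speed,
        unit_mass=unit_mass,
        effective_mass=effective_mass,
        impact=virtual_impact(speed, effective_mass),
    )


def conduction_travel(geometry: DeviceGeometry) -> tuple[float, float]:
    """Tissue-path travel time (s) and its equivalent frequency (Hz).

    ``time = tissue_path_length / medium_speed``; the equivalent frequency is
    its reciprocal (0.03 m at 1,500 m/s -> 2e-5 s, i.e. 50 kHz).
    """
    time = geometry.tissue_path_length / geometry.medium_speed
    return time, 1.0 / time


def impact_table(effective_mass: float = 100.0) -> pd.DataFrame:
    """Speed and impact per device with the default geometries."""
    rows = []
    for device, geom in default_geometries().items():
        res = impact_result(geom, effective_mass=effective_mass)
        rows.append(
            {
                "device": device,
                "travel_distance_m": geom.travel_distance,
                "scan_time_s": geom.scan_time,
                "virtual_speed_m_per_s": res.virtual_speed,
                "effective_mass_kg": res.effective_mass,
                "impact_kg_m_per_s": res.impact,
            }
        )
    return pd.DataFrame(rows)
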