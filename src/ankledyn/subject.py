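"""Subject-specific anthropometry and muscle parameters.

A :class:`SubjectModel` bundles everything both moment estimators need about
one person: the four body segments of the sagittal sit-to-stand linkage
(foot, shank, thigh, HAT = head-arms-trunk) with their inertial parameters,
the four ankle muscles (tibialis anterior, extensor digitorum longus, medial
gastrocnemius, soleus) with their Hill constants and 3-D via-point paths,
the knee-frame origin expressed in the ankle frame at quiet standing, and
the per-muscle MVC normalisation constants for sEMG.

The shipped reference subject (73 kg, 1.70 m, 10-kg waist load) lives in
``data/subject1.yaml``; other subjects are produced by geometric scaling:
lengths with stature, forces and masses with body mass, inertias with
mass x length^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import InvalidModelError, InvalidParameterError

__all__ = [
    "PathPoint",
    "MuscleParameters",
    "SegmentParameters",
    "SubjectModel",
    "MUSCLE_NAMES",
    "SEGMENT_NAMES",
    "GRAVITY",
    "build_reference_subject",
    "scale_subject",
    "load_subject",
    "save_subject",
]

GRAVITY = 9.81  # m/s^2

MUSCLE_NAMES = ("tib_ant", "ext_dig", "med_gas", "soleus")
SEGMENT_NAMES = ("foot", "shank", "thigh", "HAT")

_REFERENCE_MASS = 73.0  # kg
_REFERENCE_HEIGHT = 1.70  # m


@dataclass(frozen=True)
class PathPoint:
    """One waypoint of a muscle-tendon polyline.

    coords are millimetres in either the ankle or the knee joint frame
    (X anterior, Y proximal, Z lateral); ``segment`` names the body segment
    the point rides on, which decides how it moves with the joints.
    """

    coords: tuple[float, float, float]
    frame: str  # "ankle" | "knee"
    segment: str  # "foot" | "shank" | "thigh"

    def __post_init__(self) -> None:
        if self.frame not in ("ankle", "knee"):
            raise InvalidModelError(f"unknown frame {self.frame!r}")
        if self.segment not in ("foot", "shank", "thigh"):
            raise InvalidModelError(f"unknown segment {self.segment!r}")
        if self.frame == "knee" and self.segment not in ("thigh", "shank"):
            raise InvalidModelError(
                "knee-frame points must ride on the thigh or shank"
            )
        if not all(math.isfinite(c) for c in self.coords):
            raise InvalidModelError("non-finite path coordinates")


@dataclass(frozen=True)
class MuscleParameters:
    """Hill constants and geometric path of one muscle-tendon unit.

    peak_force: F_m0 [N]; optimal_fiber_length: l_m0 [mm]; tendon_length:
    tendon slack length l_t [mm]; pennation_at_optimum: theta_0 [rad];
    path: ordered waypoints from origin to insertion.
    """

    name: str
    peak_force: float
    optimal_fiber_length: float
    tendon_length: float
    pennation_at_optimum: float
    path: tuple[PathPoint, ...]

    def __post_init__(self) -> None:
        if self.peak_force <= 0:
            raise InvalidParameterError(f"{self.name}: peak_force must be > 0")
        if self.optimal_fiber_length <= 0:
            raise InvalidParameterError(
                f"{self.name}: optimal_fiber_length must be > 0"
            )
        if self.tendon_length < 0:
            raise InvalidParameterError(f"{self.name}: tendon_length must be >= 0")
        if not 0 <= self.pennation_at_optimum < math.pi / 2:
            raise InvalidParameterError(
                f"{self.name}: pennation must be in [0, pi/2)"
            )
        if len(self.path) < 2:
            raise InvalidModelError(f"{self.name}: path needs >= 2 points")
        frames = [p.frame for p in self.path]
        # all knee-frame points must precede all ankle-frame points
        if "knee" in frames:
            switch = frames.index("ankle") if "ankle" in frames else len(frames)
            if any(f == "knee" for f in frames[switch:]):
                raise InvalidModelError(
                    f"{self.name}: knee-frame points must all precede "
                    "ankle-frame points"
                )


@dataclass(frozen=True)
class SegmentParameters:
    """Inertial parameters of one body segment.

    length [m]; mass [kg]; com_factor: COM position as a fraction of segment
    length from the distal joint (k_i); inertia: about the COM [kg m^2].
    """

    name: str
    length: float
    mass: float
    com_factor: float
    inertia: float

    def __post_init__(self) -> None:
        if self.length <= 0 or self.mass <= 0:
            raise InvalidParameterError(f"{self.name}: length and mass must be > 0")
        if not 0 < self.com_factor < 1:
            raise InvalidParameterError(f"{self.name}: com_factor must be in (0,1)")
        if self.inertia < 0:
            raise InvalidParameterError(f"{self.name}: inertia must be >= 0")


@dataclass(frozen=True)
class SubjectModel:
    """Everything subject-specific that the two estimators consume."""

    body_mass: float  # kg, excluding the carried load
    height: float  # m
    load_mass: float  # kg, worn at the waist
    segments: Mapping[str, SegmentParameters]
    muscles: Mapping[str, MuscleParameters]
    knee_origin_in_ankle_frame: tuple[float, float, float]  # mm, standing
    rms_mvc: Mapping[str, float]  # mV per muscle

    def __post_init__(self) -> None:
        for name in SEGMENT_NAMES:
            if name not in self.segments:
                raise InvalidModelError(f"missing segment {name!r}")
        for name in MUSCLE_NAMES:
            if name not in self.muscles:
                raise InvalidModelError(f"missing muscle {name!r}")
            if self.rms_mvc.get(name, 0.0) <= 0:
                raise InvalidModelError(f"rms_mvc for {name!r} must be > 0")

    @property
    def total_weight(self) -> float:
        """G: gravity on body plus carried load [N]."""
        return (self.body_mass + self.load_mass) * GRAVITY

    def hat_mass(self) -> float:
        """HAT segment mass including the waist load [kg]."""
        return self.segments["HAT"].mass + self.load_mass


def _build_from_config(cfg: dict) -> SubjectModel:
    body_mass = float(cfg["subject"]["mass_kg"])
    height = float(cfg["subject"]["height_m"])
    load = float(cfg["subject"].get("load_kg", 0.0))

    segments = {}
    for name, row in cfg["segments"].items():
        segments[name] = SegmentParameters(
            name=name,
            length=height * float(row["length_pct_height"]) / 100.0,
            mass=body_mass * float(row["mass_pct_body"]) / 100.0,
            com_factor=float(row["com_factor"]),
            inertia=float(row["inertia_kg_m2"]),
        )
    mass_frac = sum(float(r["mass_pct_body"]) for r in cfg["segments"].values())
    if abs(mass_frac - 100.0) > 1.0:
        raise InvalidModelError(
            f"segment mass percentages sum to {mass_frac}, expected ~100"
        )

    muscles = {}
    for name, row in cfg["muscles"].items():
        path = tuple(
            PathPoint(
                coords=tuple(float(c) for c in pt["xyz_mm"]),
                frame=pt["frame"],
                segment=pt["segment"],
            )
            for pt in row["path"]
        )
        muscles[name] = MuscleParameters(
            name=name,
            peak_force=float(row["peak_force_N"]),
            optimal_fiber_length=float(row["l_m0_mm"]),
            tendon_length=float(row["l_t_mm"]),
            pennation_at_optimum=float(row["theta0_rad"]),
            path=path,
        )

    return SubjectModel(
        body_mass=body_mass,
        height=height,
        load_mass=load,
        segments=segments,
        muscles=muscles,
        knee_origin_in_ankle_frame=tuple(
            float(c) for c in cfg["knee_origin_in_ankle_frame_mm"]
        ),
        rms_mvc={k: float(v) for k, v in cfg["emg"]["rms_mvc_mV"].items()},
    )


def load_subject(path: str | Path) -> SubjectModel:
    """Load a subject configuration from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _build_from_config(cfg)


def save_subject(subject: SubjectModel, path: str | Path) -> None:
    """Write a subject back to the YAML configuration format."""
    cfg = {
        "subject": {
            "mass_kg": subject.body_mass,
            "height_m": subject.height,
            "load_kg": subject.load_mass,
        },
        "knee_origin_in_ankle_frame_mm": list(subject.knee_origin_in_ankle_frame),
        "segments": {
            name: {
                "length_pct_height": 100.0 * seg.length / subject.height,
                "mass_pct_body": 100.0 * seg.mass / subject.body_mass,
                "com_factor": seg.com_factor,
                "inertia_kg_m2": seg.inertia,
            }
            for name, seg in subject.segments.items()
        },
        "muscles": {
            name: {
                "peak_force_N": m.peak_force,
                "l_m0_mm": m.optimal_fiber_length,
                "l_t_mm": m.tendon_length,
                "theta0_rad": m.pennation_at_optimum,
                "path": [
                    {
                        "xyz_mm": list(p.coords),
                        "frame": p.frame,
                        "segment": p.segment,
                    }
                    for p in m.path
                ],
            }
            for name, m in subject.muscles.items()
        },
        "emg": {"rms_mvc_mV": dict(subject.rms_mvc)},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def build_reference_subject() -> SubjectModel:
    """Return the shipped reference subject (73 kg, 1.70 m, 10-kg load)."""
    ref = resources.files("ankledyn.data").joinpath("subject1.yaml")
    cfg = yaml.safe_load(ref.read_text())
    return _build_from_config(cfg)


def scale_subject(
    reference: SubjectModel, body_mass: float, height: float
) -> SubjectModel:
    """Geometrically scale a subject to a new body mass and stature.

    Lengths (segment lengths, fiber and tendon lengths, path coordinates,
    knee-frame offset) scale with the height ratio; peak forces and segment
    masses with the mass ratio; inertias with mass x height^2.  Pennation
    angles, COM factors and MVC constants are scale-invariant.
    """
    if body_mass <= 0 or height <= 0:
        raise InvalidParameterError("body_mass and height must be > 0")
    s_len = height / reference.height
    s_mass = body_mass / reference.body_mass
    s_inertia = s_mass * s_len**2

    segments = {
        name: replace(
            seg,
            length=seg.length * s_len,
            mass=seg.mass * s_mass,
            inertia=seg.inertia * s_inertia,
        )
        for name, seg in reference.segments.items()
    }
    muscles = {
        name: replace(
            m,
            peak_force=m.peak_force * s_mass,
            optimal_fiber_length=m.optimal_fiber_length * s_len,
            tendon_length=m.tendon_length * s_len,
            path=tuple(
                replace(p, coords=tuple(c * s_len for c in p.coords))
                for p in m.path
            ),
        )
        for name, m in reference.muscles.items()
    }
    return SubjectModel(
        body_mass=body_mass,
        height=height,
        load_mass=reference.load_mass,
        segments=segments,
        muscles=muscles,
        knee_origin_in_ankle_frame=tuple(
            c * s_len for c in reference.knee_origin_in_ankle_frame
        ),
        rms_mvc=dict(reference.rms_mvc),
    )
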