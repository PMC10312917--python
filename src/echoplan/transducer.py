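"""Focused-ultrasound transducer geometry.

The source is a spherical-bowl single element with a central circular
opening (for a coaxial imaging probe).  Defaults correspond to a 250 kHz
bowl with 110 mm outer diameter, 44 mm inner opening and 110 mm focal
distance (radius of curvature), driven in the low-MPa linear regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["TransducerGeometry"]


@dataclass
class TransducerGeometry:
    f0: float = 250e3  # Hz
    outer_diameter: float = 110.0  # mm
    inner_diameter: float = 44.0  # mm
    focal_distance: float = 110.0  # mm (radius of curvature; geometric focus)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm, bowl apex
    propagation: tuple[float, float, float] = (0.0, 0.0, -1.0)  # unit vector

    def __post_init__(self):
        if self.inner_diameter >= self.outer_diameter:
            raise ValueError("inner diameter must be smaller than outer diameter")
        if self.inner_diameter < 0:
            raise ValueError("inner diameter must be non-negative")
        if self.focal_distance <= 0:
            raise ValueError("focal distance must be positive")
        if self.outer_diameter > 2 * self.focal_distance:
            raise ValueError("aperture cannot exceed the bowl diameter of curvature")
        p = np.asarray(self.propagation, dtype=float)
        n = np.linalg.norm(p)
        if not np.isfinite(n) or n == 0:
            raise ValueError("propagation direction must be a non-zero vector")
        self.propagation = tuple(p / n)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def focus(self) -> np.ndarray:
        """Geometric focus (mm): focal_distance along propagation from the apex."""
        return np.asarray(self.origin) + self.focal_distance * np.asarray(self.propagation)

    @property
    def outer_half_angle(self) -> float:
        """Half-opening angle of the bowl rim, radians."""
        return float(np.arcsin(self.outer_diameter / (2 * self.focal_distance)))

    @property
    def inner_half_angle(self) -> float:
        """Half-angle of the central opening, radians (0 for a full cap)."""
        return float(np.arcsin(self.inner_diameter / (2 * self.focal_distance)))

    def to_yaml(self, path) -> None:
        d = {
            "f0": self.f0,
            "outer_diameter": self.outer_diameter,
            "inner_diameter": self.inner_diameter,
            "focal_distance": self.focal_distance,
            "origin": list(self.origin),
            "propagation": list(self.propagation),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "TransducerGeometry":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("origin", "propagation"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
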