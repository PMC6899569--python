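"""Tibia-like elliptical-annulus stacks with per-slice analytic geometry.

Each slice is an elliptical annulus whose outer/inner semi-axes, centroid and
rotation vary smoothly (linearly between end values, or per-slice arrays)
along the axis. The analytic cross-sectional area and principal second
moments of each slice are returned alongside the rasterised stack, so
geometry code can be validated against closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..volumes import VolumeImage

__all__ = ["TibiaPhantomSpec", "generate_tibia_stack"]


def _per_slice(value, n: int) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape == (2,):
        return np.linspace(arr[0], arr[1], n)
    if arr.shape == (n,):
        return arr
    raise ValueError(f"expected scalar, (start, end) pair or length-{n} array")


@dataclass
class TibiaPhantomSpec:
    """Elliptical-annulus stack parameters (µm, degrees).

    Every ellipse parameter may be a scalar, a ``(start, end)`` pair
    (linear taper along the axis) or a per-slice array.
    """

    n_slices: int = 60
    pixel_size_um: float = 1.0
    image_size: int = 256
    outer_a_um: object = 100.0
    outer_b_um: object = 100.0
    inner_a_um: object = 60.0
    inner_b_um: object = 60.0
    center_y_um: object = None   # defaults to image centre
    center_x_um: object = None
    rotation_deg: object = 0.0
    bone_intensity: int = 200
    background_intensity: int = 20

    def resolved(self) -> dict[str, np.ndarray]:
        n = self.n_slices
        c_default = (self.image_size - 1) / 2.0 * self.pixel_size_um
        return {
            "outer_a": _per_slice(self.outer_a_um, n),
            "outer_b": _per_slice(self.outer_b_um, n),
            "inner_a": _per_slice(self.inner_a_um, n),
            "inner_b": _per_slice(self.inner_b_um, n),
            "cy": _per_slice(self.center_y_um if self.center_y_um is not None
                             else c_default, n),
            "cx": _per_slice(self.center_x_um if self.center_x_um is not None
                             else c_default, n),
            "rot": np.deg2rad(_per_slice(self.rotation_deg, n)),
        }


def _ellipse_inside(yy, xx, cy, cx, a, b, theta) -> np.ndarray:
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _analytic_row(a_o, b_o, a_i, b_i) -> dict[str, float]:
    # elliptical annulus about its centroid; principal moments are those of
    # the outer ellipse minus the inner (same centre and orientation)
    csa = np.pi * (a_o * b_o - a_i * b_i)
    i1 = np.pi / 4.0 * (a_o * b_o ** 3 - a_i * b_i ** 3)  # about major axis
    i2 = np.pi / 4.0 * (a_o ** 3 * b_o - a_i ** 3 * b_i)  # about minor axis
    i_min, i_max = min(i1, i2), max(i1, i2)
    return {"csa_um2": csa, "i_min_um4": i_min, "i_max_um4": i_max,
            "j_um4": i_min + i_max,
            "ellipticity": float(np.sqrt(i_max / i_min))}


def generate_tibia_stack(spec: TibiaPhantomSpec) -> tuple[VolumeImage, pd.DataFrame]:
    """Rasterise the stack and tabulate per-slice analytic section properties."""
    p = spec.resolved()
    if np.any(p["inner_a"] >= p["outer_a"]) or np.any(p["inner_b"] >= p["outer_b"]):
        raise ValueError("inner ellipse must be strictly inside the outer ellipse")
    ps = spec.pixel_size_um
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n]
    yy = yy * ps
    xx = xx * ps
    stack = np.full((spec.n_slices, n, n), spec.background_intensity, dtype=np.uint8)
    rows = []
    for k in range(spec.n_slices):
        outer = _ellipse_inside(yy, xx, p["cy"][k], p["cx"][k],
                                p["outer_a"][k], p["outer_b"][k], p["rot"][k])
        inner = _ellipse_inside(yy, xx, p["cy"][k], p["cx"][k],
                                p["inner_a"][k], p["inner_b"][k], p["rot"][k])
        stack[k][outer & ~inner] = spec.bone_intensity
        row = _analytic_row(p["outer_a"][k], p["outer_b"][k],
                            p["inner_a"][k], p["inner_b"][k])
        row["slice_index"] = k
        row["rotation_deg"] = float(np.rad2deg(p["rot"][k]))
        rows.append(row)
    return VolumeImage(stack, ps), pd.DataFrame(rows)
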