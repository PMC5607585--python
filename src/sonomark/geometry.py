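"""Scan grids, regions and closed-form marker/target geometry.

The imaging grid of the study is a 200 mm field of view sampled at
1.56 x 1.56 mm in plane with 5 mm slices.  Markers are modelled as
cylinders (or spheres for ball-configured anchors) and targeted regions
as discs, annuli or ellipsoids in millimetre coordinates centred on the
sonication axis.

Two voxel-counting semantics coexist on purpose:

* ``voxel_centers_in_region`` counts voxel *centres* falling inside a
  region (this is what makes the 9 -> 12 mm edge annulus hold exactly
  28 voxels on the study grid), and
* ``disc_voxel_budget`` is the area quotient ``floor(area / dx^2)``
  (which is what makes the 12 mm targeted disc a 46-voxel budget).

The two printed reference counts are only consistent under these two
different conventions, so both are exposed.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidSpecError, OutOfBoundsError

__all__ = [
    "ScanGrid",
    "MarkerSpec",
    "RegionSpec",
    "marker_model_volume",
    "ellipsoid_volume",
    "voxel_centers_in_region",
    "disc_voxel_budget",
    "diameter_change_from_volume_ratio",
    "load_marker_catalogue",
    "marker_from_catalogue",
]

#: In-plane pixel pitch of the thermometry EPI protocol (mm).
DEFAULT_PIXEL_MM = 1.56
#: Slice thickness of the thermometry EPI protocol (mm).
DEFAULT_SLICE_MM = 5.0
#: Field of view (mm).
DEFAULT_FOV_MM = 200.0

# Cohort-mean apparent-size factors of the marker artifact on thermal maps
# (apparent width 4.2x the physical width, apparent length 2x).
DEFAULT_WIDTH_FACTOR = 4.2
DEFAULT_LENGTH_FACTOR = 2.0


@dataclass(frozen=True)
class ScanGrid:
    """Regular 2D imaging grid in millimetre coordinates.

    ``center_convention`` fixes where the continuous origin (the
    sonication centre) sits relative to the voxel lattice:

    * ``"voxel_corner"`` — the origin is a corner shared by four voxels,
      so voxel centres lie at half-integer multiples of the pitch.  This
      is the convention under which the edge annulus holds 28 voxels.
    * ``"voxel_center"`` — the origin coincides with a voxel centre.
    """

    fov_mm: float = DEFAULT_FOV_MM
    in_plane_voxel_mm: float = DEFAULT_PIXEL_MM
    slice_thickness_mm: float = DEFAULT_SLICE_MM
    n_rows: int = 128
    n_cols: int = 128
    orientation: str = "coronal"
    center_convention: str = "voxel_corner"

    def __post_init__(self) -> None:
        if self.in_plane_voxel_mm <= 0 or self.slice_thickness_mm <= 0:
            raise InvalidSpecError("voxel dimensions must be strictly positive")
        if self.orientation not in ("coronal", "sagittal"):
            raise InvalidSpecError(f"unknown orientation {self.orientation!r}")
        if self.center_convention not in ("voxel_corner", "voxel_center"):
            raise InvalidSpecError(
                f"unknown center convention {self.center_convention!r}"
            )
        if abs(self.fov_mm - self.n_cols * self.in_plane_voxel_mm) > self.in_plane_voxel_mm:
            raise InvalidSpecError(
                "fov_mm must equal n_cols * in_plane_voxel_mm within one voxel"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return self.in_plane_voxel_mm**2 * self.slice_thickness_mm

    def _axis_coords(self, n: int) -> np.ndarray:
        dx = self.in_plane_voxel_mm
        if self.center_convention == "voxel_corner":
            return (np.arange(n) - n / 2 + 0.5) * dx
        return (np.arange(n) - (n - 1) / 2) * dx

    def col_coords_mm(self) -> np.ndarray:
        """x coordinates of voxel centres along columns, origin at FOV centre."""
        return self._axis_coords(self.n_cols)

    def row_coords_mm(self) -> np.ndarray:
        """y coordinates of voxel centres along rows, origin at FOV centre."""
        return self._axis_coords(self.n_rows)


@dataclass(frozen=True)
class MarkerSpec:
    """Physical description of one biopsy marker plus its artifact size.

    ``width_mm``/``length_mm`` are the physical dimensions used by the
    cylinder/sphere volume model; the apparent factors scale them to the
    size of the susceptibility signal void seen on thermal maps.
    """

    name: str
    material: str = "gold"
    shape: str = "cylinder"
    width_mm: float = 1.0
    length_mm: float = 10.0
    orientation: str = "parallel_B0"
    apparent_width_factor: float = DEFAULT_WIDTH_FACTOR
    apparent_length_factor: float = DEFAULT_LENGTH_FACTOR

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.length_mm <= 0:
            raise InvalidSpecError("marker dimensions must be positive")
        if self.shape not in ("cylinder", "sphere"):
            raise InvalidSpecError(f"unknown marker shape {self.shape!r}")
        if self.material not in ("gold", "gold_iron", "brass", "carbon_coated"):
            raise InvalidSpecError(f"unknown marker material {self.material!r}")
        if self.orientation not in ("parallel_B0", "orthogonal_B0"):
            raise InvalidSpecError(f"unknown orientation {self.orientation!r}")
        if self.shape == "sphere":
            if not math.isclose(self.width_mm, self.length_mm, rel_tol=1e-9):
                raise InvalidSpecError("sphere requires width_mm == length_mm")
            if not 0.28 <= self.width_mm <= 2.5:
                raise InvalidSpecError("sphere diameter outside supported range")
        else:
            if not 0.28 <= self.width_mm <= 2.0:
                raise InvalidSpecError("cylinder width outside [0.28, 2] mm")
            if not 3.0 <= self.length_mm <= 30.0:
                raise InvalidSpecError("cylinder length outside [3, 30] mm")
        if self.apparent_width_factor < 1 or self.apparent_length_factor < 1:
            raise InvalidSpecError("apparent-size factors must be >= 1")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "material": self.material,
            "shape": self.shape,
            "width_mm": self.width_mm,
            "length_mm": self.length_mm,
            "orientation": self.orientation,
            "apparent_width_factor": self.apparent_width_factor,
            "apparent_length_factor": self.apparent_length_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "MarkerSpec":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class RegionSpec:
    """Disc, annulus or ellipsoid region in mm, centred on ``center``."""

    kind: str
    outer_diameter_mm: float = 0.0
    inner_diameter_mm: float = 0.0
    axes_mm: tuple[float, float, float] | None = None
    center: tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("disc", "annulus", "ellipsoid"):
            raise InvalidSpecError(f"unknown region kind {self.kind!r}")
        if self.inner_diameter_mm < 0 or self.outer_diameter_mm < 0:
            raise InvalidSpecError("region diameters must be non-negative")
        if self.kind == "annulus" and self.inner_diameter_mm >= self.outer_diameter_mm:
            # equal bounds are allowed to express an empty annulus
            if self.inner_diameter_mm > self.outer_diameter_mm:
                raise InvalidSpecError("annulus requires inner < outer diameter")
        if self.kind == "ellipsoid":
            if self.axes_mm is None or len(self.axes_mm) != 3:
                raise InvalidSpecError("ellipsoid requires three axes")
            if any(a < 0 for a in self.axes_mm):
                raise InvalidSpecError("ellipsoid axes must be non-negative")

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "center": list(self.center)}
        if self.kind == "ellipsoid":
            d["axes_mm"] = list(self.axes_mm)
        else:
            d["outer_diameter_mm"] = self.outer_diameter_mm
            if self.kind == "annulus":
                d["inner_diameter_mm"] = self.inner_diameter_mm
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSpec":
        d = dict(d)
        if "center" in d:
            d["center"] = tuple(d["center"])
        if "axes_mm" in d and d["axes_mm"] is not None:
            d["axes_mm"] = tuple(d["axes_mm"])
        return cls(**d)


def marker_model_volume(spec: MarkerSpec) -> float:
    """Model volume of a marker in mm³.

    Cylinder: ``pi (w/2)^2 L``; sphere: ``(pi/6) w^3``.  Full precision
    is returned; round to two decimals for display.
    """
    if spec.width_mm <= 0 or spec.length_mm <= 0:
        raise InvalidSpecError("marker dimensions must be positive")
    if spec.shape == "sphere":
        return math.pi / 6.0 * spec.width_mm**3
    return math.pi * (spec.width_mm / 2.0) ** 2 * spec.length_mm


def ellipsoid_volume(axes_mm: Iterable[float]) -> float:
    """Volume of an ellipsoid given its three *diameters* (mm), in ml."""
    a, b, c = axes_mm
    if a < 0 or b < 0 or c < 0:
        raise InvalidSpecError("ellipsoid axes must be non-negative")
    return math.pi / 6.0 * a * b * c / 1000.0


def voxel_centers_in_region(grid: ScanGrid, region: RegionSpec) -> set[tuple[int, int]]:
    """Voxel (row, col) indices whose centre falls inside a disc/annulus.

    Membership uses a strict inner bound and an inclusive outer bound,
    ``inner/2 < r <= outer/2``, which reproduces the 28-voxel edge
    annulus (9 -> 12 mm) on the study grid with the voxel-corner
    convention.
    """
    if region.kind not in ("disc", "annulus"):
        raise InvalidSpecError("voxel_centers_in_region supports disc/annulus only")
    cx, cy = region.center[0], region.center[1]
    outer_r = region.outer_diameter_mm / 2.0
    half_fov = grid.fov_mm / 2.0
    if abs(cx) + outer_r > half_fov + 1e-9 or abs(cy) + outer_r > half_fov + 1e-9:
        raise OutOfBoundsError("region extends beyond the field of view")
    xs = grid.col_coords_mm() - cx
    ys = grid.row_coords_mm() - cy
    r = np.hypot(xs[None, :], ys[:, None])
    inside = r <= outer_r + 1e-12
    if region.kind == "annulus":
        inside &= r > region.inner_diameter_mm / 2.0 + 1e-12
    rows, cols = np.nonzero(inside)
    return set(zip(rows.tolist(), cols.tolist()))


def disc_voxel_budget(grid: ScanGrid, diameter_mm: float) -> int:
    """Area-quotient voxel budget of a disc: ``floor(pi (d/2)^2 / dx^2)``.

    This quotient — not centre counting — is the convention under which
    the 12 mm targeted region holds 46 voxels at 1.56 mm pitch.
    """
    if diameter_mm < 0:
        raise InvalidSpecError("diameter must be non-negative")
    area = math.pi * (diameter_mm / 2.0) ** 2
    return int(math.floor(area / grid.in_plane_voxel_mm**2))


def diameter_change_from_volume_ratio(ratio: float) -> float:
    """Percent diameter change implied by a volume ratio, assuming
    isotropic scaling: ``(ratio^(1/3) - 1) * 100``."""
    if ratio <= 0:
        raise InvalidSpecError("volume ratio must be positive")
    return (ratio ** (1.0 / 3.0) - 1.0) * 100.0


def load_marker_catalogue() -> pd.DataFrame:
    """Packaged marker catalogue (name, material, shape, dimensions,
    orientation, apparent-size factors) as a DataFrame."""
    with importlib.resources.files("sonomark.data").joinpath("markers.csv").open() as fh:
        return pd.read_csv(fh)


def marker_from_catalogue(name: str) -> MarkerSpec:
    """Look one marker up by name in the packaged catalogue."""
    cat = load_marker_catalogue()
    row = cat[cat["name"] == name]
    if row.empty:
        raise InvalidSpecError(f"marker {name!r} not in catalogue")
    r = row.iloc[0]
    return MarkerSpec(
        name=r["name"],
        material=r["material"],
        shape=r["shape"],
        width_mm=float(r["width_mm"]),
        length_mm=float(r["length_mm"]),
        orientation=r["orientation"],
        apparent_width_factor=float(r["apparent_width_factor"]),
        apparent_length_factor=float(r["apparent_length_factor"]),
    )
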