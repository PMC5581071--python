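"""Digital mouse phantom geometry.

Organs are ellipsoids on a regular mm grid.  Overlap between organs is an
error by design — ground truth must stay unambiguous — and every labelled
voxel belongs to exactly one organ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .kinetics import OneTissueParams
from .reference import UPTAKE_PIDG_MEAN

__all__ = [
    "OrganSpec",
    "Phantom",
    "TumorCaliper",
    "build_phantom",
    "core_mask",
    "default_mouse_organs",
    "tumor_caliper_volume",
    "DEFAULT_GRID_SHAPE",
]

#: Default simulation grid (voxels) at 1 mm isotropic: a 44×44×84 mm box
#: comfortably holding a ~20 g mouse with ≥5 mm clearance to every border.
DEFAULT_GRID_SHAPE = (44, 44, 84)


@dataclass(frozen=True)
class OrganSpec:
    """An ellipsoidal organ with either a static or a kinetic ground truth.

    Exactly one of ``uptake`` (static %ID/g at the uptake window) or
    ``kinetic`` (one-tissue-compartment parameters, optionally mixed with a
    vascular ``blood_fraction``) must be given.  A pure blood pool is
    ``kinetic=OneTissueParams(0, 0), blood_fraction=1``.
    """

    name: str
    center: tuple[float, float, float]  # mm
    semi_axes: tuple[float, float, float]  # mm
    uptake: float | None = None  # %ID/g
    kinetic: OneTissueParams | None = None
    blood_fraction: float = 0.0
    density: float = 1.0  # g/ml

    def __post_init__(self) -> None:
        if len(self.center) != 3 or len(self.semi_axes) != 3:
            raise ValueError("center and semi_axes must be length-3")
        if min(self.semi_axes) <= 0:
            raise ValueError(f"semi-axes of {self.name!r} must be positive")
        if (self.uptake is None) == (self.kinetic is None) and self.blood_fraction == 0:
            raise ValueError(
                f"organ {self.name!r}: give exactly one of uptake or kinetic"
            )
        if self.uptake is not None and self.uptake < 0:
            raise ValueError(f"uptake of {self.name!r} must be >= 0")
        if not 0.0 <= self.blood_fraction <= 1.0:
            raise ValueError("blood_fraction must lie in [0, 1]")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def is_kinetic(self) -> bool:
        return self.kinetic is not None or self.blood_fraction > 0


@dataclass(frozen=True)
class TumorCaliper:
    """Caliper measurement of a subcutaneous tumor (mm)."""

    length: float
    width: float

    def __post_init__(self) -> None:
        if not self.length >= self.width > 0:
            raise ValueError(
                f"need length >= width > 0, got L={self.length}, W={self.width}"
            )


def tumor_caliper_volume(c: TumorCaliper) -> float:
    """Ellipsoid caliper volume V = L·W²/2 in mm³."""
    return c.length * c.width**2 / 2.0


@dataclass(frozen=True)
class Phantom:
    """Voxelised organ set: integer label volume plus per-organ masks."""

    labels: np.ndarray  # int16, 0 = background, i+1 = organs[i]
    masks: dict[str, np.ndarray] = field(repr=False)
    organs: tuple[OrganSpec, ...]
    voxel_size: float  # mm, isotropic

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        return self.masks[name]


def _ellipsoid_mask(shape, voxel_size: float, organ: OrganSpec) -> np.ndarray:
    # voxel centers at (index + 0.5) * voxel_size
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * voxel_size for n in shape], indexing="ij"
    )
    r2 = sum(
        ((c - c0) / a) ** 2
        for c, c0, a in zip(coords, organ.center, organ.semi_axes)
    )
    return r2 <= 1.0


def build_phantom(
    organs: list[OrganSpec],
    shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
    voxel_size: float = 1.0,
) -> Phantom:
    """Voxelise organs onto the grid; organs must be pairwise disjoint.

    Raises
    ------
    ValueError
        If an organ's bounding box leaves the grid, or two organs claim
        the same voxel.
    """
    extent = tuple(n * voxel_size for n in shape)
    labels = np.zeros(shape, dtype=np.int16)
    masks: dict[str, np.ndarray] = {}
    for i, organ in enumerate(organs):
        if organ.name in masks:
            raise ValueError(f"duplicate organ name {organ.name!r}")
        for c0, a, lim in zip(organ.center, organ.semi_axes, extent):
            if c0 - a < 0 or c0 + a > lim:
                raise ValueError(
                    f"organ {organ.name!r} extends outside the {extent} mm grid"
                )
        m = _ellipsoid_mask(shape, voxel_size, organ)
        clash = m & (labels != 0)
        if clash.any():
            other = organs[int(labels[clash][0]) - 1].name
            raise ValueError(
                f"organs {other!r} and {organ.name!r} overlap on the grid"
            )
        labels[m] = i + 1
        masks[organ.name] = m
    return Phantom(labels=labels, masks=masks, organs=tuple(organs), voxel_size=voxel_size)


def core_mask(mask: np.ndarray, margin_mm: float, voxel_size: float = 1.0) -> np.ndarray:
    """Erode a mask by ``margin_mm``, keeping voxels deeper than the margin.

    Emulates ROI placement over the most intense part of an organ, which
    keeps the region mean away from resolution-blurred edges.  Falls back
    to the full mask if erosion would empty it.
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    if margin_mm == 0:
        return mask.copy()
    depth = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    core = depth > margin_mm
    return core if core.any() else mask.copy()


def default_mouse_organs(
    uptake: dict[str, float] | None = None,
    kinetic: dict[str, OneTissueParams] | None = None,
    blood_fraction: dict[str, float] | None = None,
) -> list[OrganSpec]:
    """The canonical six-organ mouse layout on the default grid.

    Brain, heart, liver and one kidney along the body axis, the tumor on
    the right shoulder and a thigh muscle region; all ellipsoids are
    pairwise disjoint with ≥5 mm clearance from the grid border.  Uptake
    defaults to the reference γ-counter levels; ``kinetic`` entries switch
    the named organs to model-driven time courses.
    """
    uptake = dict(UPTAKE_PIDG_MEAN if uptake is None else uptake)
    kinetic = kinetic or {}
    blood_fraction = blood_fraction or {}
    geometry = {
        "brain": ((22.0, 22.0, 70.0), (5.0, 5.0, 5.0)),
        "heart": ((22.0, 22.0, 52.0), (4.5, 4.5, 4.5)),
        "liver": ((22.0, 22.0, 38.0), (7.0, 7.0, 6.0)),
        "kidney": ((12.0, 22.0, 30.0), (3.0, 3.0, 4.0)),
        "tumor": ((34.0, 22.0, 60.0), (3.6, 3.6, 3.6)),
        "muscle": ((32.0, 22.0, 16.0), (4.0, 4.0, 7.0)),
    }
    organs = []
    for name, (center, axes) in geometry.items():
        if name in kinetic or name in blood_fraction:
            organs.append(
                OrganSpec(
                    name,
                    center,
                    axes,
                    kinetic=kinetic.get(name),
                    blood_fraction=blood_fraction.get(name, 0.0),
                )
            )
        else:
            organs.append(OrganSpec(name, center, axes, uptake=uptake[name]))
    return organs
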