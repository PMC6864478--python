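"""ETDRS-style circular quadrant grid and per-consultation feature assembly.

The retinal vasculature is analysed over five sectors of a circular grid
centred on the image: a central disk (1 mm diameter by convention) and the
surrounding annulus split by the two diagonals into superior, inferior,
temporal and nasal sectors.  Which lateral sector is "nasal" (toward the
nose) depends on the eye: for a right eye (OD) the left image sector is
temporal, for a left eye (OS) the assignment is mirrored.

Vessel density inside a sector is normalised by the sector's own pixel
count so values are comparable across sectors of different size; the global
figure uses the whole image as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ParameterError, ValidationError

#: canonical ordering of image acquisitions within one consultation
IMAGE_KEYS = ("scp3", "dcp3", "scp6", "dcp6")

#: canonical ordering of grid sectors
SECTORS = ("central", "temporal", "nasal", "superior", "inferior")

_LATERALITIES = ("OD", "OS")


@dataclass(frozen=True)
class QuadrantGrid:
    """Five disjoint sector masks partitioning the inscribed disk."""

    masks: Mapping[str, np.ndarray]
    center: tuple[float, float]
    central_radius_px: float
    outer_radius_px: float
    laterality: str

    def sector(self, name: str) -> np.ndarray:
        return self.masks[name]

    @property
    def disk(self) -> np.ndarray:
        out = np.zeros_like(self.masks["central"])
        for m in self.masks.values():
            out |= m
        return out


@dataclass(frozen=True)
class QuadrantDensities:
    """Per-sector and global vessel densities (percent)."""

    central: float
    temporal: float
    nasal: float
    superior: float
    inferior: float
    global_: float

    def as_dict(self) -> dict[str, float]:
        return {
            "central": self.central,
            "temporal": self.temporal,
            "nasal": self.nasal,
            "superior": self.superior,
            "inferior": self.inferior,
            "global": self.global_,
        }

    def sector_values(self) -> tuple[float, ...]:
        return (self.central, self.temporal, self.nasal, self.superior, self.inferior)


@dataclass(frozen=True)
class FeatureLayout:
    """Ordered names of the per-consultation feature vector.

    Default layout is 21 features: the FAZ area measured on the 3 mm SCP
    image followed by the five sector densities of each of the four
    acquisitions.  Optionally the four global densities are appended
    (25 features).  The layout travels with any trained model so a saved
    model can refuse mismatched feature tables.
    """

    include_global: bool = False

    @property
    def names(self) -> tuple[str, ...]:
        names = ["faz_area_mm2"]
        for key in IMAGE_KEYS:
            names.extend(f"vd_{key}_{sector}" for sector in SECTORS)
        if self.include_global:
            names.extend(f"vd_{key}_global" for key in IMAGE_KEYS)
        return tuple(names)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class FeatureVector:
    """One consultation's ordered feature values plus its layout."""

    values: tuple[float, ...]
    layout: FeatureLayout = field(default_factory=FeatureLayout)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.layout):
            raise ValidationError(
                f"feature vector has {len(self.values)} values, "
                f"layout expects {len(self.layout)}"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.layout.names, self.values))


def build_grid(
    dims: tuple[int, int],
    fov_mm: float,
    laterality: str,
    central_diameter_mm: float = 1.0,
) -> QuadrantGrid:
    """Build the five-sector grid for an image of ``dims`` = (H, W).

    The grid is centred on the geometric image centre; the outer radius is
    half the image width (the inscribed circle) and the central disk
    diameter is ``central_diameter_mm`` converted to pixels through the
    field of view.  Annulus pixels are assigned by comparing |dx| and |dy|
    around the centre; ties on the exact diagonals go to the vertical
    (superior/inferior) sectors, a rule symmetric under horizontal mirror
    and 180-degree rotation so the grid equivariances hold exactly.
    """
    h, w = int(dims[0]), int(dims[1])
    if h < 2 or w < 2:
        raise ParameterError(f"image dims {dims} too small for a grid")
    if fov_mm <= 0:
        raise ParameterError(f"fov_mm must be positive, got {fov_mm}")
    if laterality not in _LATERALITIES:
        raise ParameterError(f"laterality must be one of {_LATERALITIES}")
    central_radius = 0.5 * central_diameter_mm * w / fov_mm
    if central_radius <= 0 or 2 * central_radius > min(h, w) / 2:
        raise ParameterError(
            f"central diameter {central_diameter_mm} mm does not fit dims {dims} "
            f"at fov {fov_mm} mm"
        )
    outer_radius = w / 2.0
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    dist = np.hypot(dy, dx)

    disk = dist <= outer_radius
    central = dist <= central_radius
    annulus = disk & ~central

    vertical = np.abs(dy) >= np.abs(dx)  # ties -> vertical sectors
    superior = annulus & vertical & (dy < 0)
    inferior = annulus & vertical & (dy >= 0)
    left = annulus & ~vertical & (dx < 0)
    right = annulus & ~vertical & (dx > 0)

    if laterality == "OD":
        temporal, nasal = left, right
    else:
        temporal, nasal = right, left

    masks = {
        "central": central,
        "temporal": temporal,
        "nasal": nasal,
        "superior": superior,
        "inferior": inferior,
    }
    return QuadrantGrid(
        masks=masks,
        center=(cy, cx),
        central_radius_px=central_radius,
        outer_radius_px=outer_radius,
        laterality=laterality,
    )


def quadrant_densities(skeleton: np.ndarray, grid: QuadrantGrid) -> QuadrantDensities:
    """Sector densities of a binary skeleton under ``grid``.

    Sector value = 100 * |skeleton ∩ sector| / |sector|; the global value
    is the plain whole-image density 100 * p / (H * W).
    """
    skel = np.asarray(skeleton).astype(bool)
    if skel.shape != grid.masks["central"].shape:
        raise ValidationError(
            f"skeleton shape {skel.shape} does not match grid "
            f"{grid.masks['central'].shape}"
        )
    values = {}
    for name in SECTORS:
        sector = grid.masks[name]
        n = int(sector.sum())
        values[name] = 100.0 * int((skel & sector).sum()) / n if n else 0.0
    h, w = skel.shape
    global_ = 100.0 * int(skel.sum()) / (h * w)
    return QuadrantDensities(
        central=values["central"],
        temporal=values["temporal"],
        nasal=values["nasal"],
        superior=values["superior"],
        inferior=values["inferior"],
        global_=global_,
    )


def assemble_features(
    faz_area_mm2: float,
    densities: Mapping[str, QuadrantDensities],
    layout: FeatureLayout | None = None,
) -> FeatureVector:
    """Concatenate the FAZ area and sector densities in layout order.

    ``densities`` is keyed by the acquisition keys ``scp3/dcp3/scp6/dcp6``;
    the FAZ area is the one measured on the 3 mm SCP image (the deep-plexus
    FAZ is similar and less precisely imaged, so it is not used).
    """
    layout = layout or FeatureLayout()
    missing = [k for k in IMAGE_KEYS if k not in densities]
    if missing:
        raise ValidationError(f"missing densities for acquisitions: {missing}")
    values: list[float] = [float(faz_area_mm2)]
    for key in IMAGE_KEYS:
        values.extend(densities[key].sector_values())
    if layout.include_global:
        values.extend(densities[key].global_ for key in IMAGE_KEYS)
    return FeatureVector(values=tuple(values), layout=layout)
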