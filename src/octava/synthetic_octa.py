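"""Synthetic en-face OCTA angiograms with known ground truth.

Clinical OCTA datasets are private, so every downstream stage is exercised
on rendered phantoms that reproduce the properties the pipeline must cope
with: a branching capillary network of controllable per-sector density, a
central foveal avascular zone (FAZ) bounded by a perifoveal capillary
arcade, vessels with a gradual (Gaussian) intensity fall-off, a smooth
background gradient, and multiplicative speckle.

Ground truth travels with each sample: the exact centerline mask, the FAZ
disk, and the measured per-sector centerline densities.  Cohorts of
consultations additionally carry a known linear link from the true feature
vector to a decimal visual acuity, so regression recovery is testable.

Generation is closed-loop: walkers are seeded on the image border, biased
toward an aim point in the currently most deficient sector, branch with a
fixed probability, are deflected off the avascular disk, and keep being
spawned until every sector reaches its target centerline density (so the
recorded densities track the targets instead of hoping a fixed walker
count lands near them).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as _line

from .errors import ParameterError
from .quadrant_features import (
    IMAGE_KEYS,
    SECTORS,
    FeatureLayout,
    build_grid,
    quadrant_densities,
)

_VESSEL_SIGMA_AT_320 = 1.5  # px, Gaussian half-profile of a capillary
_VESSEL_PEAK = 185.0  # gray levels above background at the centerline
_BACKGROUND_BASE = 28.0
_BRANCH_PROB = 0.035  # per step
_MAX_WALKERS = 20_000


def _normalize_targets(target_density) -> dict[str, float]:
    if isinstance(target_density, Mapping):
        unknown = set(target_density) - set(SECTORS)
        if unknown:
            raise ParameterError(f"unknown sector names {sorted(unknown)}")
        return {s: float(target_density.get(s, 0.0)) for s in SECTORS}
    return {s: float(target_density) for s in SECTORS}


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of one rendered angiogram.

    target_density is the per-sector centerline density in percent (scalar
    applies to all five sectors); noise_sigma is the speckle standard
    deviation as a fraction of the local intensity; background_drift is the
    peak amplitude (gray levels) of a smooth additive gradient.
    """

    fov_mm: float = 3.0
    size_px: int = 320
    faz_radius_mm: float = 0.35
    target_density: object = 5.0
    noise_sigma: float = 0.10
    background_drift: float = 30.0
    seed: int = 0
    laterality: str = "OD"
    plexus: str = "SCP"

    def validate(self) -> None:
        if self.fov_mm not in (3, 6, 3.0, 6.0):
            raise ParameterError(f"fov_mm must be 3 or 6, got {self.fov_mm}")
        if self.size_px < 64:
            raise ParameterError(f"size_px must be >= 64, got {self.size_px}")
        if not 0 <= self.faz_radius_mm < self.fov_mm / 2:
            raise ParameterError(
                f"faz_radius_mm {self.faz_radius_mm} outside [0, fov/2)"
            )
        targets = _normalize_targets(self.target_density)
        for s, v in targets.items():
            if not 0 <= v <= 100:
                raise ParameterError(f"target density for {s} outside [0, 100]: {v}")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.laterality not in ("OD", "OS"):
            raise ParameterError(f"laterality must be OD or OS, got {self.laterality}")
        if self.plexus not in ("SCP", "DCP"):
            raise ParameterError(f"plexus must be SCP or DCP, got {self.plexus}")

    @property
    def targets(self) -> dict[str, float]:
        return _normalize_targets(self.target_density)


@dataclass(frozen=True)
class SyntheticSample:
    """Rendered angiogram plus its generating ground truth."""

    image: np.ndarray  # uint8, size_px x size_px
    true_faz_mask: np.ndarray  # bool
    true_centerlines: np.ndarray  # bool
    true_quadrant_density: dict[str, float]  # per sector + "global", percent
    params: SyntheticParams


@dataclass(frozen=True)
class SyntheticConsultation:
    """Four acquisitions of one eye at one visit plus its true features."""

    sample_id: str
    images: dict[str, SyntheticSample]  # keyed by scp3/dcp3/scp6/dcp6
    laterality: str
    va_true: float
    features_true: tuple[float, ...]


@dataclass(frozen=True)
class SyntheticCohort:
    samples: tuple[SyntheticConsultation, ...]
    weights: tuple[float, ...]
    intercept: float
    noise_sigma_va: float
    seed: int
    layout: FeatureLayout = field(default_factory=FeatureLayout)

    @property
    def va_true(self) -> tuple[float, ...]:
        return tuple(s.va_true for s in self.samples)


def _sector_of(grid_masks: dict[str, np.ndarray]) -> np.ndarray:
    """Label image: sector index (0..4 in SECTORS order) or -1 outside."""
    label = np.full(grid_masks["central"].shape, -1, dtype=np.int8)
    for i, s in enumerate(SECTORS):
        label[grid_masks[s]] = i
    return label


def _draw_arc(centerline: np.ndarray, center: tuple[float, float],
              radius: float, frac: float, start: float) -> None:
    """Mark an arc (fraction ``frac`` of a circle, from angle ``start``)."""
    if radius <= 0 or frac <= 0:
        return
    n = max(8, int(math.ceil(2 * math.pi * radius * frac * 2)))
    angles = start + np.linspace(0.0, 2 * math.pi * frac, n)
    rr = np.round(center[0] + radius * np.sin(angles)).astype(int)
    cc = np.round(center[1] + radius * np.cos(angles)).astype(int)
    h, w = centerline.shape
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    centerline[rr[ok], cc[ok]] = True


def generate_vessel_image(params: SyntheticParams) -> SyntheticSample:
    """Render one angiogram; deterministic for a given seed.

    Centerline pixels never fall inside the avascular disk: walkers are
    deflected at its rim (plus one vessel half-width, so the rendered
    vessel body also stays outside) and the perifoveal arcade is drawn just
    outside the rim, as in real anatomy where the FAZ is bounded by a
    continuous capillary ring.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.size_px
    grid = build_grid((n, n), params.fov_mm, params.laterality)
    sector_label = _sector_of(dict(grid.masks))
    sector_sizes = np.array([int(grid.masks[s].sum()) for s in SECTORS], dtype=float)
    targets = params.targets
    target_px = np.array(
        [targets[s] / 100.0 * sector_sizes[i] for i, s in enumerate(SECTORS)]
    )

    sigma_v = _VESSEL_SIGMA_AT_320 * n / 320.0
    halfwidth = 2.0 * sigma_v
    cy, cx = grid.center
    r_faz = params.faz_radius_mm / params.fov_mm * n
    yy, xx = np.mgrid[0:n, 0:n]
    dist_c = np.hypot(yy - cy, xx - cx)
    faz_mask = dist_c <= r_faz if r_faz > 0 else np.zeros((n, n), dtype=bool)
    r_forbid = r_faz + halfwidth if r_faz > 0 else 0.0

    centerline = np.zeros((n, n), dtype=bool)
    counts = [0.0] * len(SECTORS)

    # perifoveal arcade: always a complete ring when an avascular zone
    # exists (the FAZ is bounded by a continuous capillary arcade, and a
    # gapped ring would let contour refinement flood out of the zone);
    # its pixels count toward the central budget, so the central sector
    # has an anatomical density floor of ring/|central| percent
    central_idx = SECTORS.index("central")
    if r_faz > 0 and any(target_px):
        ring_r = r_faz + halfwidth
        _draw_arc(centerline, (cy, cx), ring_r, 1.0, rng.uniform(0, 2 * math.pi))
        for i, s in enumerate(SECTORS):
            counts[i] = float((centerline & grid.masks[s]).sum())

    def spawn_order() -> int | None:
        d = [target_px[i] - counts[i] for i in range(len(SECTORS))]
        if d[central_idx] > 0:  # feeders to the centre help outer sectors too
            return central_idx
        best = max(range(len(d)), key=lambda i: d[i])
        return best if d[best] > 0 else None

    max_segments = n  # more than enough to cross the frame

    def walk(py: float, px: float, vy: float, vx: float,
             aim_y: float, aim_x: float, target_sector: int, depth: int) -> None:
        """Mark a capillary path as straight thin segments between waypoints.

        Bresenham segments are minimal 8-connected paths, so the marked
        set is thin by construction and its pixel count is an honest
        centerline length.  Direction updates per segment blend momentum,
        a pull toward the aim point, and jitter.
        """
        vn = math.hypot(vy, vx) or 1e-9
        vy, vx = vy / vn, vx / vn
        for _seg in range(max_segments):
            dy, dx = aim_y - py, aim_x - px
            norm = math.hypot(dy, dx)
            if norm > 1e-9:
                jy, jx = rng.normal(), rng.normal()
                vy = 0.72 * vy + 0.22 * dy / norm + 0.30 * jy
                vx = 0.72 * vx + 0.22 * dx / norm + 0.30 * jx
                vn = math.hypot(vy, vx) or 1e-9
                vy, vx = vy / vn, vx / vn
            seg_len = float(rng.uniform(6.0, 14.0))
            ey, ex = py + vy * seg_len, px + vx * seg_len
            escaped = not (0 <= ey < n and 0 <= ex < n)
            ey = min(max(ey, 0.0), n - 1.0)
            ex = min(max(ex, 0.0), n - 1.0)
            rr, cc = _line(int(round(py)), int(round(px)),
                           int(round(ey)), int(round(ex)))
            for r, c in zip(rr.tolist()[1:], cc.tolist()[1:]):
                if r_forbid > 0 and math.hypot(r - cy, c - cx) <= r_forbid:
                    return  # capillary terminates at the arcade
                lab = sector_label[r, c]
                if not centerline[r, c]:
                    centerline[r, c] = True
                    if lab >= 0:
                        counts[lab] += 1
                # stop once the sector under the tip has met its budget —
                # whether it is the walker's own target or one it merely
                # crosses (prevents wandering tips from over-filling
                # already-complete sectors)
                if lab >= 0 and counts[lab] >= target_px[lab]:
                    return
            py, px = ey, ex
            if escaped:
                return
            if depth < 3 and rng.random() < 8 * _BRANCH_PROB:
                ang = rng.uniform(0.5, 1.2) * (1.0 if rng.random() < 0.5 else -1.0)
                ca, sa = math.cos(ang), math.sin(ang)
                walk(py, px, ca * vy - sa * vx, sa * vy + ca * vx,
                     aim_y, aim_x, target_sector, depth + 1)
                if counts[target_sector] >= target_px[target_sector]:
                    return

    # per-sector pools of pixels a walker may aim at
    aim_pools: list[np.ndarray] = []
    for s in SECTORS:
        allowed = grid.masks[s] & ~faz_mask
        if r_forbid > 0:
            allowed &= dist_c > r_forbid
        aim_pools.append(np.flatnonzero(allowed))

    spawned = 0
    stall = 0
    while spawned < _MAX_WALKERS:
        target_sector = spawn_order()
        if target_sector is None:
            break
        idx = aim_pools[target_sector]
        if idx.size == 0:
            # unreachable (e.g. the FAZ covers the sector): give up on it
            target_px[target_sector] = counts[target_sector]
            continue
        pick = int(idx[rng.integers(idx.size)])
        aim_y, aim_x = float(pick // n), float(pick % n)
        # seed on the border where the centre-to-aim ray (plus jitter)
        # exits the frame, so walkers enter from the side of their sector
        ang = math.atan2(aim_y - cy, aim_x - cx) + rng.normal(0, 0.35)
        sy, sx = math.sin(ang), math.cos(ang)
        ty = ((0.0 - cy) / sy if sy < 0 else (n - 1.0 - cy) / sy) \
            if abs(sy) > 1e-9 else math.inf
        tx = ((0.0 - cx) / sx if sx < 0 else (n - 1.0 - cx) / sx) \
            if abs(sx) > 1e-9 else math.inf
        t = min(ty, tx)
        ey = min(max(cy + t * sy, 0.0), n - 1.0)
        ex = min(max(cx + t * sx, 0.0), n - 1.0)
        before = counts[target_sector]
        walk(ey, ex, aim_y - ey, aim_x - ex, aim_y, aim_x, target_sector, 0)
        spawned += 1
        stall = stall + 1 if counts[target_sector] <= before else 0
        if stall > 200:
            break  # no progress; record what was achieved

    # render: Gaussian radial profile around the centerlines
    if centerline.any():
        d_vessel = ndimage.distance_transform_edt(~centerline)
        vessel = _VESSEL_PEAK * np.exp(-0.5 * (d_vessel / sigma_v) ** 2)
    else:
        vessel = np.zeros((n, n))

    theta = rng.uniform(0, 2 * math.pi)
    ramp = (xx * math.cos(theta) + yy * math.sin(theta)) / n
    ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-9)
    clean = _BACKGROUND_BASE + params.background_drift * ramp + vessel

    if params.noise_sigma > 0:
        # multiplicative speckle with a grain size of about one pixel
        # (spatially correlated, as the imaging point-spread function
        # imposes); rescaled after smoothing so the per-pixel standard
        # deviation equals noise_sigma
        k = 1.0 / params.noise_sigma**2
        field = rng.gamma(shape=k, scale=1.0 / k, size=(n, n))
        field = ndimage.gaussian_filter(field, sigma=1.5, mode="reflect")
        sd = field.std()
        if sd > 0:
            field = 1.0 + (field - field.mean()) * (params.noise_sigma / sd)
        clean = clean * np.clip(field, 0.0, None)
    image = np.clip(np.round(clean), 0, 255).astype(np.uint8)

    qd = quadrant_densities(centerline, grid)
    truth = qd.as_dict()
    return SyntheticSample(
        image=image,
        true_faz_mask=faz_mask,
        true_centerlines=centerline,
        true_quadrant_density=truth,
        params=params,
    )


# -- cohorts ---------------------------------------------------------------

#: generative VA link used by default: logMAR-scale VA worsens with FAZ
#: enlargement and improves with vessel density, superficial plexus
#: weighted a little more than the deep one.
DEFAULT_INTERCEPT = 1.75
DEFAULT_VA_WEIGHTS: tuple[float, ...] = (0.5,) + tuple(
    -0.015 if key.startswith("scp") else -0.010
    for key in IMAGE_KEYS
    for _sector in SECTORS
)


def _true_features(images: dict[str, SyntheticSample],
                   layout: FeatureLayout) -> tuple[float, ...]:
    scp3 = images["scp3"]
    h, w = scp3.true_faz_mask.shape
    area = scp3.true_faz_mask.sum() * scp3.params.fov_mm**2 / (h * w)
    values = [float(area)]
    for key in IMAGE_KEYS:
        truth = images[key].true_quadrant_density
        values.extend(truth[s] for s in SECTORS)
    if layout.include_global:
        values.extend(images[key].true_quadrant_density["global"]
                      for key in IMAGE_KEYS)
    return tuple(values)


def generate_cohort(
    n: int,
    weights: Sequence[float] = DEFAULT_VA_WEIGHTS,
    noise_sigma_va: float = 0.05,
    seed: int = 0,
    intercept: float = DEFAULT_INTERCEPT,
    size_px: int = 160,
    layout: FeatureLayout | None = None,
) -> SyntheticCohort:
    """Simulate ``n`` consultations with a linear feature-to-VA link.

    Structural parameters per consultation: FAZ radius uniform on
    [0.2, 0.5] mm (shared by all four acquisitions of the eye), per-sector
    density targets uniform on [3, 8]% for SCP and [2, 6]% for DCP slabs
    (the deep plexus images are noisier and read sparser).  The logMAR-
    scale VA is ``intercept + weights . features + N(0, noise_sigma_va)``,
    floored at 0 so the decimal VA stays in (0, 1].
    """
    if n < 1:
        raise ParameterError(f"cohort size must be >= 1, got {n}")
    layout = layout or FeatureLayout()
    weights = tuple(float(v) for v in weights)
    if len(weights) != len(layout):
        raise ParameterError(
            f"weights length {len(weights)} != feature layout length {len(layout)}"
        )
    rng = np.random.default_rng(seed)
    consultations = []
    for i in range(n):
        laterality = "OD" if rng.random() < 0.5 else "OS"
        faz_r = rng.uniform(0.2, 0.5)
        images: dict[str, SyntheticSample] = {}
        for key in IMAGE_KEYS:
            plexus = "SCP" if key.startswith("scp") else "DCP"
            fov = 3.0 if key.endswith("3") else 6.0
            lo, hi = (3.0, 8.0) if plexus == "SCP" else (2.0, 6.0)
            targets = {s: float(rng.uniform(lo, hi)) for s in SECTORS}
            noise = 0.10 if plexus == "SCP" else 0.14
            p = SyntheticParams(
                fov_mm=fov,
                size_px=size_px,
                faz_radius_mm=faz_r,
                target_density=targets,
                noise_sigma=noise,
                background_drift=float(rng.uniform(15, 40)),
                seed=int(rng.integers(2**31)),
                laterality=laterality,
                plexus=plexus,
            )
            images[key] = generate_vessel_image(p)
        feats = _true_features(images, layout)
        log_va = intercept + float(np.dot(weights, feats))
        log_va += float(rng.normal(0.0, noise_sigma_va)) if noise_sigma_va > 0 else 0.0
        log_va = max(log_va, 0.0)
        va = 10.0 ** (-log_va)
        consultations.append(
            SyntheticConsultation(
                sample_id=f"synth{i:04d}",
                images=images,
                laterality=laterality,
                va_true=float(min(max(va, 1e-6), 1.0)),
                features_true=feats,
            )
        )
    return SyntheticCohort(
        samples=tuple(consultations),
        weights=weights,
        intercept=intercept,
        noise_sigma_va=noise_sigma_va,
        seed=seed,
        layout=layout,
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Save images as 8-bit PNGs plus a manifest CSV; returns manifest path.

    Manifest columns: sample_id, path_scp3, path_dcp3, path_scp6,
    path_dcp6, laterality, va_decimal — the structure the readers expect.
    """
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for cons in cohort.samples:
        paths = {}
        for key in IMAGE_KEYS:
            fname = f"{cons.sample_id}_{key}.png"
            Image.fromarray(cons.images[key].image, mode="L").save(directory / fname)
            paths[key] = fname
        rows.append(
            {
                "sample_id": cons.sample_id,
                **{f"path_{k}": paths[k] for k in IMAGE_KEYS},
                "laterality": cons.laterality,
                "va_decimal": f"{cons.va_true:.17g}",
            }
        )
    import csv

    manifest = directory / "manifest.csv"
    fieldnames = ["sample_id"] + [f"path_{k}" for k in IMAGE_KEYS] + [
        "laterality",
        "va_decimal",
    ]
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        writer.writerows(rows)
    return manifest
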