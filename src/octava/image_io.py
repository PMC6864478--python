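"""Readers and writers: images, consultation manifests, feature tables, models.

A dataset is organised as one manifest row per ophthalmic consultation,
pointing at the four en-face acquisitions of the pathological eye
(3 mm and 6 mm field of view, superficial and deep plexus) together with
the manually measured decimal visual acuity.  All readers raise typed
errors on malformed input; nothing partially parsed is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ImageReadError, ValidationError
from .quadrant_features import IMAGE_KEYS, FeatureLayout, FeatureVector

_MANIFEST_COLUMNS = (
    ["sample_id"] + [f"path_{k}" for k in IMAGE_KEYS] + ["laterality", "va_decimal"]
)


@dataclass(frozen=True)
class AngioImage:
    """One grayscale en-face OCTA scan plus acquisition metadata."""

    pixels: np.ndarray  # uint8, H x W
    fov_mm: float
    plexus: str
    laterality: str
    source_path: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise FormatError(f"image must be 2-D and non-empty: {self.source_path}")
        if self.fov_mm not in (3, 6, 3.0, 6.0):
            raise ValidationError(f"fov_mm must be 3 or 6, got {self.fov_mm}")


@dataclass(frozen=True)
class ConsultationRecord:
    """The four acquisitions of one consultation plus the measured VA."""

    sample_id: str
    images: dict[str, AngioImage]  # keyed scp3/dcp3/scp6/dcp6
    va_decimal: float

    def __post_init__(self) -> None:
        if set(self.images) != set(IMAGE_KEYS):
            raise ValidationError(
                f"consultation {self.sample_id} needs images {IMAGE_KEYS}, "
                f"got {sorted(self.images)}"
            )
        lats = {img.laterality for img in self.images.values()}
        if len(lats) != 1:
            raise ValidationError(
                f"consultation {self.sample_id} mixes lateralities {sorted(lats)}"
            )
        if not 0 < self.va_decimal <= 1:
            raise ValidationError(
                f"consultation {self.sample_id}: va_decimal {self.va_decimal} "
                "outside (0, 1]"
            )

    @property
    def laterality(self) -> str:
        return next(iter(self.images.values())).laterality


@dataclass(frozen=True)
class FeatureTable:
    """Per-consultation feature rows with a fixed column layout."""

    frame: pd.DataFrame  # columns: sample_id, <layout names...>, va_decimal
    layout: FeatureLayout = field(default_factory=FeatureLayout)

    def __post_init__(self) -> None:
        expected = ["sample_id", *self.layout.names, "va_decimal"]
        if list(self.frame.columns) != expected:
            raise FormatError(
                f"feature table columns {list(self.frame.columns)} != {expected}"
            )
        if len(self.frame) and self.frame[list(self.layout.names) + ["va_decimal"]] \
                .isna().any().any():
            raise ValidationError("feature table contains missing values")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(self.layout.names)].to_numpy(dtype=float)

    @property
    def va_decimal(self) -> np.ndarray:
        return self.frame["va_decimal"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def read_image(path: str | Path, fov_mm: float, plexus: str,
               laterality: str) -> AngioImage:
    """Load a raster as 8-bit grayscale (ITU-R 601 luminance if RGB)."""
    from PIL import Image, UnidentifiedImageError

    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("L"))
    except (FileNotFoundError, UnidentifiedImageError, OSError) as exc:
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise FormatError(f"empty image: {path}")
    return AngioImage(
        pixels=arr.astype(np.uint8),
        fov_mm=fov_mm,
        plexus=plexus,
        laterality=laterality,
        source_path=str(path),
    )


def read_manifest(path: str | Path, load_images: bool = True
                  ) -> list[ConsultationRecord]:
    """Parse a manifest CSV into consultation records.

    Image paths are resolved relative to the manifest's directory.  Rows
    failing validation are reported together with their (1-based data) row
    numbers; nothing is returned if any row is invalid.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"sample_id": str},
                            float_precision="round_trip")
    except (OSError, pd.errors.ParserError) as exc:
        raise ImageReadError(f"cannot read manifest {path}: {exc}") from exc
    missing = [c for c in _MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns {missing}")
    records: list[ConsultationRecord] = []
    problems: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = row._asdict()
        try:
            va = float(row["va_decimal"])
            if not 0 < va <= 1:
                raise ValidationError(f"va_decimal {va} outside (0, 1]")
            images = {}
            for key in IMAGE_KEYS:
                fov = 3.0 if key.endswith("3") else 6.0
                plexus = "SCP" if key.startswith("scp") else "DCP"
                img_path = path.parent / str(row[f"path_{key}"])
                if load_images:
                    images[key] = read_image(img_path, fov, plexus,
                                             str(row["laterality"]))
                else:
                    images[key] = AngioImage(
                        pixels=np.zeros((1, 1), dtype=np.uint8),
                        fov_mm=fov, plexus=plexus,
                        laterality=str(row["laterality"]),
                        source_path=str(img_path),
                    )
            records.append(ConsultationRecord(
                sample_id=str(row["sample_id"]), images=images, va_decimal=va))
        except (ValidationError, FormatError, ImageReadError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError(
            f"manifest {path} has invalid rows:\n  " + "\n  ".join(problems)
        )
    return records


def features_to_table(rows: Iterable[tuple[str, FeatureVector, float]],
                      layout: FeatureLayout | None = None) -> FeatureTable:
    """Build a FeatureTable from (sample_id, FeatureVector, va) triples."""
    rows = list(rows)
    layout = layout or (rows[0][1].layout if rows else FeatureLayout())
    data = [
        {"sample_id": sid, **fv.as_dict(), "va_decimal": va}
        for sid, fv, va in rows
    ]
    frame = pd.DataFrame(data, columns=["sample_id", *layout.names, "va_decimal"])
    return FeatureTable(frame=frame, layout=layout)


def write_features(table: FeatureTable, path: str | Path) -> Path:
    """CSV round-trip at full float precision (repr-precision floats)."""
    path = Path(path)
    table.frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_features(path: str | Path, layout: FeatureLayout | None = None
                  ) -> FeatureTable:
    try:
        frame = pd.read_csv(path, dtype={"sample_id": str},
                            float_precision="round_trip")
    except (OSError, pd.errors.ParserError) as exc:
        raise ImageReadError(f"cannot read feature table {path}: {exc}") from exc
    if layout is None:
        ncols = len(frame.columns) - 2
        for candidate in (FeatureLayout(False), FeatureLayout(True)):
            if len(candidate) == ncols:
                layout = candidate
                break
        else:
            raise FormatError(
                f"feature table {path} has {ncols} feature columns; no known layout"
            )
    return FeatureTable(frame=frame, layout=layout)


def save_model(model, path: str | Path) -> Path:
    """Persist a trained VA model: joblib blob + JSON metadata sidecar."""
    import joblib

    path = Path(path)
    joblib.dump(model, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "feature_names": list(model.feature_names),
        "hyperparameters": {k: (v if isinstance(v, (int, float, str)) else str(v))
                            for k, v in model.params.items()},
        "include_global": model.layout.include_global,
        "split_seed": model.seed,
        "n_train": model.n_train,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def load_model(path: str | Path):
    """Restore a trained model; predictions are bit-identical to pre-save."""
    import joblib

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise ImageReadError(f"model sidecar {sidecar} missing")
    try:
        model = joblib.load(path)
    except (OSError, EOFError) as exc:
        raise ImageReadError(f"cannot load model {path}: {exc}") from exc
    meta = json.loads(sidecar.read_text())
    if list(model.feature_names) != list(meta["feature_names"]):
        raise ValidationError(
            f"model {path} feature layout disagrees with its sidecar"
        )
    return model
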