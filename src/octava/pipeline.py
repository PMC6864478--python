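"""End-to-end biomarker extraction: consultations -> feature table.

Glue over the segmentation, density and grid modules: for each
consultation, segment the FAZ on the 3 mm SCP slab, run the adaptive
threshold + skeleton density on all four slabs, split the skeleton over
the laterality-aware quadrant grid, and assemble the ordered feature
vector.
"""

from __future__ import annotations

from typing import Iterable

from .faz_segmentation import FazConfig, segment_faz
from .image_io import ConsultationRecord, FeatureTable, features_to_table
from .quadrant_features import (
    IMAGE_KEYS,
    FeatureLayout,
    FeatureVector,
    assemble_features,
    build_grid,
    quadrant_densities,
)
from .vessel_density import vd_proposed


def extract_features(
    record: ConsultationRecord,
    faz_cfg: FazConfig | None = None,
    layout: FeatureLayout | None = None,
) -> FeatureVector:
    """Compute the feature vector of one consultation."""
    layout = layout or FeatureLayout()
    faz = segment_faz(record.images["scp3"], faz_cfg)
    densities = {}
    for key in IMAGE_KEYS:
        img = record.images[key]
        _mask, skel, _vd = vd_proposed(img.pixels)
        grid = build_grid(img.pixels.shape, img.fov_mm, img.laterality)
        densities[key] = quadrant_densities(skel.grid, grid)
    return assemble_features(faz.area_mm2, densities, layout)


def extract_feature_table(
    records: Iterable[ConsultationRecord],
    faz_cfg: FazConfig | None = None,
    layout: FeatureLayout | None = None,
) -> FeatureTable:
    """Feature table over a list of consultations."""
    layout = layout or FeatureLayout()
    rows = [
        (rec.sample_id, extract_features(rec, faz_cfg, layout), rec.va_decimal)
        for rec in records
    ]
    return features_to_table(rows, layout)
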