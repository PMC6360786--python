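"""End-to-end convenience wrapper: raw plot cloud -> phenotype table."""

from __future__ import annotations

import pandas as pd

from .cloud import PointCloud
from .phenotypes import PADConfig, extract_phenotypes
from .preprocess import (OutlierParams, build_dtm, classify_ground,
                         normalize_heights, remove_outliers)
from .segmentation import segment_grid


def process_plot(cloud: PointCloud, n_cols: int, n_rows: int,
                 col_spacing: float = 0.50, row_spacing: float = 0.30,
                 origin: tuple[float, float] = (0.0, 0.0),
                 stage: str | None = None,
                 outlier_params: OutlierParams = OutlierParams(),
                 dtm_resolution: float = 0.05,
                 cfg: PADConfig = PADConfig(),
                 on_orphans: str = "drop") -> pd.DataFrame:
    """Run denoise -> ground -> DTM -> normalize -> segment -> extract.

    Returns the per-plant phenotype table.  Orphan vegetation points
    (e.g. surviving outliers beyond the planting grid) are dropped by
    default rather than raising.
    """
    denoised, _ = remove_outliers(cloud, outlier_params)
    labeled = classify_ground(denoised)
    dtm = build_dtm(labeled, resolution=dtm_resolution)
    normalized = normalize_heights(labeled, dtm)
    plants = segment_grid(normalized, origin, n_cols, n_rows,
                          col_spacing, row_spacing, stage,
                          on_orphans=on_orphans)
    return extract_phenotypes(plants, cfg)
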