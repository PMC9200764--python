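"""Slide-level inference: exhaustive ROI scoring, patient aggregation, heatmaps.

At test time every tissue ROI of a slide is scored (half-tile stride, no
augmentation); a patient's risk is the median over the pooled ROI risks
of all their slides; per-slide risk density maps render low risk blue and
high risk red over the tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .model import RiskModel
from .tiling import ArraySlide, enumerate_rois, normalize, tissue_mask

__all__ = ["SlideRiskTable", "RiskMap", "score_slide", "aggregate_patient", "render_risk_map"]


@dataclass
class SlideRiskTable:
    """Per-ROI risks of one slide: rows of (x, y, size, risk)."""

    slide_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"x", "y", "size", "risk"} - set(self.table.columns)
        if missing:
            raise ValueError(f"risk table missing columns {sorted(missing)}")
        if not np.all(np.isfinite(self.table["risk"])):
            raise ValueError("risks must be finite")

    @property
    def risks(self) -> np.ndarray:
        return self.table["risk"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "slide_id", self.slide_id)
        out.to_csv(path, index=False)


@dataclass
class RiskMap:
    """Risks on the tiling grid plus the rendered overlay."""

    grid: np.ndarray      # per-pixel overlap-averaged risk, NaN off-tissue-grid
    overlay: np.ndarray   # H x W x 3 RGB in [0, 1]
    colormap_name: str


def score_slide(model: RiskModel, slide, size: int | None = None,
                stride: int | None = None, min_tissue: float = 0.5,
                batch_size: int = 64) -> SlideRiskTable:
    """Score every tissue ROI of a slide with the trained model.

    The grid is exhaustive at half-tile stride by default; patches are
    normalized but never augmented, so scoring is deterministic.
    """
    if isinstance(slide, np.ndarray):
        slide = ArraySlide(slide)
    size = size or model.input_size
    if stride is None:
        stride = size // 2
    mask = tissue_mask(slide.thumbnail())
    coords = enumerate_rois(mask, size=size, stride=stride, min_tissue=min_tissue)
    if not coords:
        raise ValueError(f"slide {slide.slide_id!r}: no tissue ROIs to score")

    risks = np.empty(len(coords))
    for start in range(0, len(coords), batch_size):
        chunk = coords[start : start + batch_size]
        patches = np.stack(
            [normalize(slide.read_region(x, y, size, size)) for x, y in chunk]
        )
        risks[start : start + len(chunk)] = model.forward(
            patches.transpose(0, 3, 1, 2), train=False
        )
    table = pd.DataFrame(
        {
            "x": [c[0] for c in coords],
            "y": [c[1] for c in coords],
            "size": size,
            "risk": risks,
        }
    )
    return SlideRiskTable(slide_id=slide.slide_id, table=table)


def aggregate_patient(tables) -> float:
    """Median of the pooled ROI risks across all of one patient's slides.

    Accepts one :class:`SlideRiskTable`, one array of risks, or an
    iterable mixing either.
    """
    if isinstance(tables, SlideRiskTable):
        tables = [tables]
    elif not isinstance(tables, (list, tuple)):
        tables = [np.asarray(tables, dtype=float)]
    pooled = [
        t.risks if isinstance(t, SlideRiskTable) else np.asarray(t, dtype=float).ravel()
        for t in tables
    ]
    risks = np.concatenate(pooled) if pooled else np.array([])
    if risks.size == 0:
        raise ValueError("no ROI risks to aggregate")
    return float(np.median(risks))


def render_risk_map(table: SlideRiskTable, thumbnail: np.ndarray, alpha: float = 0.4,
                    colormap: str = "coolwarm", blur_sigma: float = 0.0,
                    value_range: tuple[float, float] | None = None) -> RiskMap:
    """Render a blue (low) to red (high) risk overlay on the slide thumbnail.

    Risks are min-max scaled per slide (or against ``value_range`` for
    absolute cross-slide scale), placed on the grid with overlapping ROI
    contributions averaged, colormapped, and alpha-blended over the
    thumbnail; pixels covered by no ROI (background) stay unshaded.  An
    all-equal table renders a uniform mid-scale map.
    """
    import matplotlib

    if len(table.table) == 0:
        raise ValueError("empty risk table")
    thumb = np.asarray(thumbnail, dtype=float)
    if thumb.ndim == 2:
        thumb = np.stack([thumb] * 3, axis=-1)
    h, w = thumb.shape[:2]

    risks = table.risks
    if value_range is not None:
        lo, hi = value_range
    else:
        lo, hi = risks.min(), risks.max()
    scaled = np.full_like(risks, 0.5) if hi == lo else np.clip((risks - lo) / (hi - lo), 0, 1)

    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for (x, y, size), r in zip(table.table[["x", "y", "size"]].to_numpy(), scaled):
        acc[int(y) : int(y) + int(size), int(x) : int(x) + int(size)] += r
        cnt[int(y) : int(y) + int(size), int(x) : int(x) + int(size)] += 1
    covered = cnt > 0
    grid = np.full((h, w), np.nan)
    grid[covered] = acc[covered] / cnt[covered]
    if blur_sigma > 0:
        filled = np.where(covered, grid, 0.0)
        grid_s = ndimage.gaussian_filter(filled, blur_sigma)
        norm = ndimage.gaussian_filter(covered.astype(float), blur_sigma)
        grid = np.where(covered, grid_s / np.maximum(norm, 1e-12), np.nan)

    cmap = matplotlib.colormaps[colormap]
    colors = cmap(np.where(covered, grid, 0.0))[..., :3]
    overlay = thumb.copy()
    overlay[covered] = (1 - alpha) * thumb[covered] + alpha * colors[covered]
    return RiskMap(grid=grid, overlay=np.clip(overlay, 0, 1), colormap_name=colormap)
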