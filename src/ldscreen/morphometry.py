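"""Per-object morphometry and per-well aggregation of the LD screen parameters.

The four well-level parameters are: mean per-object LD area (um^2), total LD
area per cell (um^2/cell), mean compactness P^2/(4 pi A) and mean form factor
4 pi A / P^2. Compactness and form factor are exact reciprocals per object
(the definitional identity C * FF = 1 is enforced by construction), so the
two carry the same shape information with opposite directionality: a circle
has FF = 1 and irregular boundaries push FF down and C up.

Perimeters use the Crofton approximation (4 directions), the least-biased
standard estimator for small digitised objects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage import measure

from .imaging import ImageSet, LabelMap

__all__ = ["ObjectFeatures", "WellSummary", "CellIntensityRatio",
           "object_features", "aggregate_well", "mito_ratio"]


@dataclass
class ObjectFeatures:
    """Morphometry of one punctum."""

    object_id: int
    parent_cell: int
    area_px: float  # px^2
    area: float  # um^2
    perimeter: float  # um (Crofton)
    compactness: float  # P^2 / (4 pi A), >= ~1, unitless
    form_factor: float  # 4 pi A / P^2 = 1 / compactness
    centroid: tuple[float, float]  # (row, col) px


@dataclass
class WellSummary:
    """The four screen parameters for one well.

    When no cells were found the parameters are NaN (undefined), never zero,
    and ``qc`` carries a flag.
    """

    well: str
    n_cells: int
    ld_area: float
    ld_total_area: float
    ld_compactness: float
    ld_form_factor: float
    qc: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "ld_area": self.ld_area,
            "ld_total_area": self.ld_total_area,
            "ld_compactness": self.ld_compactness,
            "ld_form_factor": self.ld_form_factor,
            "qc_flags": ";".join(sorted(self.qc)) if self.qc else "",
        }


@dataclass
class CellIntensityRatio:
    cell_id: int
    active_mean: float  # background-subtracted mean, a.u.
    total_mean: float
    ratio: float  # active/total; NaN when total_mean <= 0


def object_features(labels: LabelMap, pixel_size: float = 1.0) -> list[ObjectFeatures]:
    """Compute area, Crofton perimeter, compactness and form factor per object.

    ``area = pixel count * pixel_size^2``. Form factor is computed as the
    exact reciprocal of compactness so ``compactness * form_factor == 1`` to
    machine precision. Objects with a degenerate (zero) perimeter estimate
    get NaN shape factors.
    """
    out: list[ObjectFeatures] = []
    parent_of = labels.parent_of or {}
    for region in measure.regionprops(labels.labels):
        area_px = float(region.area)
        perim_px = float(region.perimeter_crofton)
        if perim_px > 0:
            compact = perim_px**2 / (4.0 * math.pi * area_px)
            ff = 1.0 / compact
        else:
            compact = ff = float("nan")
        out.append(ObjectFeatures(
            object_id=int(region.label),
            parent_cell=int(parent_of.get(region.label, 0)),
            area_px=area_px,
            area=area_px * pixel_size**2,
            perimeter=perim_px * pixel_size,
            compactness=compact,
            form_factor=ff,
            centroid=tuple(region.centroid),
        ))
    return out


def aggregate_well(
    puncta_features: Sequence[Sequence[ObjectFeatures]],
    cell_counts: Sequence[int],
    well: str = "",
    orphan_puncta: int = 0,
) -> WellSummary:
    """Pool objects across a well's fields into the four screen parameters.

    ``puncta_features`` holds one feature list per field and ``cell_counts``
    the matching per-field cell counts. Per-object means are pooled over all
    objects (not means of per-cell means), and total area is normalised per
    cell: sum of object areas / sum of cells — robust to wells where cell
    count varies across fields and to cells with zero droplets.
    """
    if len(puncta_features) != len(cell_counts):
        raise ValueError("need one cell count per field")
    if len(puncta_features) == 0:
        raise ValueError("need at least one field")
    n_cells = int(sum(cell_counts))
    objs = [o for fld in puncta_features for o in fld]
    qc: dict = {}
    if orphan_puncta:
        qc["orphan_puncta"] = orphan_puncta
    if n_cells == 0:
        qc["no_cells"] = True
        nan = float("nan")
        return WellSummary(well, 0, nan, nan, nan, nan, qc)
    if objs:
        areas = np.array([o.area for o in objs])
        ld_area = float(areas.mean())
        ld_total = float(areas.sum()) / n_cells
        comp = float(np.nanmean([o.compactness for o in objs]))
        ff = float(np.nanmean([o.form_factor for o in objs]))
    else:
        qc["no_puncta"] = True
        ld_area = comp = ff = float("nan")
        ld_total = 0.0  # a well with cells and no droplets truly has zero LD area
    return WellSummary(well, n_cells, ld_area, ld_total, comp, ff, qc)


def _background(values: np.ndarray, method: str) -> float:
    if method == "mode":
        # histogram mode refined by the modal bin's median; exact for
        # constant backgrounds, robust for large dim ones
        lo, hi = float(values.min()), float(values.max())
        if hi == lo:
            return lo
        nbins = min(max(int(hi - lo) + 1, 10), 512)
        hist, edges = np.histogram(values, bins=nbins)
        i = int(hist.argmax())
        in_bin = values[(values >= edges[i]) & (values <= edges[i + 1])]
        return float(np.median(in_bin))
    if method == "median":
        return float(np.median(values))
    if method == "none":
        return 0.0
    raise ValueError(f"unknown background method {method!r}")


def mito_ratio(
    img: ImageSet,
    cells: LabelMap,
    background: str = "mode",
    active_channel: str = "active_mito",
    total_channel: str = "total_mito",
) -> list[CellIntensityRatio]:
    """Per-cell active/total mitochondrial intensity ratio.

    For each cell mask the mean background-subtracted intensity of the
    potential-dependent stain (TMRE-like) is divided by that of the
    potential-independent stain (MitoTracker-like); the ratio indexes the
    active fraction of the mitochondrial pool. Background defaults to the
    mode of non-cell pixels per channel.
    """
    active = img.channel(active_channel)
    total = img.channel(total_channel)
    if cells.labels.shape != active.shape:
        raise ValueError("cell label map and image shapes differ")
    outside = cells.labels == 0
    if not (~outside).any():
        raise ValueError("no cells in label map; ratio undefined")
    bg_a = _background(active[outside], background) if outside.any() else 0.0
    bg_t = _background(total[outside], background) if outside.any() else 0.0
    out = []
    for region in measure.regionprops(cells.labels):
        idx = tuple(region.coords.T)
        a = float(active[idx].mean() - bg_a)
        t = float(total[idx].mean() - bg_t)
        ratio = a / t if t > 0 else float("nan")
        out.append(CellIntensityRatio(int(region.label), a, t, ratio))
    return out
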