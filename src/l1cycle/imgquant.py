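"""High-content nuclear/cytoplasmic compartment quantification.

Reproduces an Arrayscan-style "compartmental analysis": nuclei are
segmented from the nuclear-dye channel (isodata/intermeans threshold
after morphological background subtraction), each nucleus is shrunk into
a "circle" (nuclear edge offset x = −4 px) and surrounded by a "ring"
(the annulus 1 < x ≤ 8 px outside the edge), positivity limits are
calibrated on a negative control so that no control cell scores
positive, and the percentage of marker-expressing cells with nuclear
marker is computed as

    percent_nuclear = 100 · n(nuclear-positive) / n(cytoplasmic-positive)

where the cytoplasmic-positive count doubles as the total number of
expressing cells (every expressing cell has cytoplasmic signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology

from .datatypes import ImageBundle, InvalidParameterError

__all__ = [
    "CompartmentGeometry",
    "Limits",
    "QuantSummary",
    "isodata_threshold",
    "segment_nuclei",
    "build_compartments",
    "measure_cells",
    "calibrate_limits",
    "quantify",
    "CalibrationError",
]

#: minimum nucleus area: area of a disk of radius 3 px
MIN_NUCLEUS_AREA = 29


class CalibrationError(ValueError):
    """Negative-control calibration impossible (empty control)."""


@dataclass(frozen=True)
class CompartmentGeometry:
    """Circle/ring offsets (px) relative to the nuclear edge (x = 0)."""

    inner_offset: int = 4   # circle: nucleus eroded by this amount (x = -4)
    ring_inner: int = 1     # ring: annulus between these offsets outside
    ring_outer: int = 8     # the nuclear edge (1 < x <= 8)

    def __post_init__(self) -> None:
        if self.inner_offset < 0:
            raise InvalidParameterError("inner_offset must be >= 0")
        if not (0 < self.ring_inner < self.ring_outer):
            raise InvalidParameterError("need 0 < ring_inner < ring_outer")


@dataclass(frozen=True)
class Limits:
    """Positivity limits calibrated so no negative-control cell is positive."""

    circle_limit: float
    ring_limit: float

    def __post_init__(self) -> None:
        if self.circle_limit < 0 or self.ring_limit < 0:
            raise InvalidParameterError("limits must be nonnegative")


@dataclass
class QuantSummary:
    total_cells: int
    cytoplasmic_positive: int
    nuclear_positive: int
    percent_nuclear: Optional[float]


def isodata_threshold(values: np.ndarray, tol: float = 1e-6,
                      max_iter: int = 500) -> Optional[float]:
    """Iterative intermeans (isodata) threshold.

    Starting from the midrange, iterate
    ``t <- (mean(values <= t) + mean(values > t)) / 2`` to convergence.
    Returns None for a constant input (no two classes to separate).
    """
    v = np.asarray(values, float).ravel()
    if v.size == 0 or v.min() == v.max():
        return None
    t = 0.5 * (float(v.min()) + float(v.max()))
    for _ in range(max_iter):
        lo = v[v <= t]
        hi = v[v > t]
        if hi.size == 0 or lo.size == 0:
            return None
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def segment_nuclei(nuclear_channel: np.ndarray, background_radius: int = 15,
                   min_area: int = MIN_NUCLEUS_AREA) -> np.ndarray:
    """Label nuclei: background subtraction, isodata threshold, labeling.

    The background is estimated by grayscale morphological opening with
    a disk of ``background_radius`` (larger than any nucleus) and
    subtracted; the isodata threshold is applied to the residual;
    connected components below ``min_area`` pixels are discarded.
    A constant image yields zero labels.
    """
    img = np.asarray(nuclear_channel, float)
    if img.ndim != 2:
        raise InvalidParameterError("nuclear channel must be a 2-D raster")
    if (img < 0).any():
        raise InvalidParameterError("nuclear channel must be nonnegative")

    if background_radius > 0:
        background = ndi.grey_opening(
            img, footprint=morphology.disk(background_radius)
        )
        resid = np.clip(img - background, 0, None)
    else:
        resid = img

    t = isodata_threshold(resid)
    if t is None:
        return np.zeros(img.shape, dtype=np.int32)
    mask = resid > t
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return labels.astype(np.int32)
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels]


def build_compartments(labels: np.ndarray, geom: CompartmentGeometry = CompartmentGeometry()):
    """Per-nucleus circle and ring masks as label images.

    circle = nucleus eroded by ``inner_offset`` px (Euclidean);
    ring = (nucleus dilated by ``ring_outer``) minus (nucleus dilated by
    ``ring_inner``), clipped at image borders, excluding all nuclei, and
    with contested pixels assigned to the nearest nucleus (Euclidean
    pixel-center distance; ties to the lower label id).

    Returns ``(circle_labels, ring_labels, empty_circle_ids)``.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    circle = np.zeros_like(labels, dtype=np.int32)
    ring = np.zeros_like(labels, dtype=np.int32)
    if ids.size == 0:
        return circle, ring, []

    best_dist = np.full(labels.shape, np.inf)
    best_label = np.zeros(labels.shape, dtype=np.int32)
    empty_ids = []
    for lab in ids:
        mask = labels == lab
        edt_in = ndi.distance_transform_edt(mask)
        circ_mask = edt_in > geom.inner_offset
        if not circ_mask.any():
            empty_ids.append(int(lab))
        circle[circ_mask] = lab
        edt_out = ndi.distance_transform_edt(~mask)
        closer = edt_out < best_dist  # strict: ties stay with lower label
        best_dist[closer] = edt_out[closer]
        best_label[closer] = lab

    band = (labels == 0) & (best_dist > geom.ring_inner) & (best_dist <= geom.ring_outer)
    ring[band] = best_label[band]
    return circle, ring, empty_ids


def _per_label_stats(values: np.ndarray, label_img: np.ndarray,
                     ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and total intensity per label id (NaN mean for empty labels)."""
    flat_labels = label_img.ravel()
    flat_vals = values.ravel()
    maxlab = int(ids.max()) if ids.size else 0
    sums = np.bincount(flat_labels, weights=flat_vals, minlength=maxlab + 1)
    counts = np.bincount(flat_labels, minlength=maxlab + 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means[ids], sums[ids]


def measure_cells(image: ImageBundle, geom: CompartmentGeometry = CompartmentGeometry(),
                  background_radius: int = 15) -> pd.DataFrame:
    """Segment nuclei and measure marker intensity per compartment.

    Returns one row per segmented nucleus with circle/ring mean and
    total marker intensity, the centroid and an ``empty_circle`` flag.
    """
    labels = segment_nuclei(image.nuclear_channel, background_radius=background_radius)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    circle, ring, empty_ids = build_compartments(labels, geom)
    marker = np.asarray(image.marker_channel, float)

    circle_mean, circle_total = _per_label_stats(marker, circle, ids)
    ring_mean, ring_total = _per_label_stats(marker, ring, ids)
    cy, cx = np.zeros(ids.size), np.zeros(ids.size)
    if ids.size:
        coms = ndi.center_of_mass(np.ones_like(labels), labels, ids)
        cy = np.array([c[0] for c in coms])
        cx = np.array([c[1] for c in coms])
    return pd.DataFrame(
        {
            "id": ids,
            "cx": cx,
            "cy": cy,
            "circle_mean": circle_mean,
            "circle_total": circle_total,
            "ring_mean": ring_mean,
            "ring_total": ring_total,
            "empty_circle": np.isin(ids, empty_ids),
        }
    )


def calibrate_limits(negative_control: pd.DataFrame,
                     statistic: str = "mean") -> Limits:
    """Positivity limits from a negative-control per-cell table.

    The circle (ring) limit is the maximum circle (ring) intensity over
    the control cells, so that re-scoring the control at these limits
    yields zero positive cells.
    """
    if len(negative_control) == 0:
        raise CalibrationError("negative-control table is empty")
    col_c = f"circle_{statistic}"
    col_r = f"ring_{statistic}"
    circle_limit = float(np.nanmax(negative_control[col_c].to_numpy(float)))
    ring_limit = float(np.nanmax(negative_control[col_r].to_numpy(float)))
    return Limits(circle_limit=circle_limit, ring_limit=ring_limit)


def quantify(image: ImageBundle, geom: CompartmentGeometry = CompartmentGeometry(),
             limits: Limits = Limits(0.0, 0.0), background_radius: int = 15,
             statistic: str = "mean"):
    """Score nuclear/cytoplasmic marker positivity per cell.

    A cell is nuclear-positive when its circle statistic exceeds the
    circle limit, cytoplasmic-positive when its ring statistic exceeds
    the ring limit. ``percent_nuclear = 100 · nuclear / cytoplasmic``;
    with zero cytoplasmic-positive cells the percentage is undefined
    (None, with a warning).

    Returns ``(per_cell_table, QuantSummary)``.
    """
    table = measure_cells(image, geom=geom, background_radius=background_radius)
    col_c = f"circle_{statistic}"
    col_r = f"ring_{statistic}"
    circle_vals = table[col_c].to_numpy(float)
    ring_vals = table[col_r].to_numpy(float)
    with np.errstate(invalid="ignore"):
        nuclear_pos = np.nan_to_num(circle_vals, nan=-np.inf) > limits.circle_limit
        cyto_pos = np.nan_to_num(ring_vals, nan=-np.inf) > limits.ring_limit
    table["nuclear_positive"] = nuclear_pos
    table["cytoplasmic_positive"] = cyto_pos

    n_total = len(table)
    n_nuc = int(nuclear_pos.sum())
    n_cyto = int(cyto_pos.sum())
    if n_cyto > 0:
        percent = 100.0 * n_nuc / n_cyto
    else:
        warnings.warn("no cytoplasmic-positive cells; percent_nuclear undefined")
        percent = None
    return table, QuantSummary(
        total_cells=n_total, cytoplasmic_positive=n_cyto,
        nuclear_positive=n_nuc, percent_nuclear=percent,
    )
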