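"""Fluorescence-image positivity calling for single cells in nanopens.

Cells appear as dark disks on the bright brightfield channel; their
surface-marker signal is read from the paired FITC channel.  The caller:
(1) finds circles with a Hough transform, (2) drops detections failing
brightness / background-mask / edge-band filters, (3) measures disk-mean
FITC intensity and normalizes by the cohort mean (so normalized values
average to 1), and (4) splits the normalized vector into positive and
negative classes with an exact 1-D 2-means (all split points of the
sorted vector are enumerated, so the solution is the global optimum and
fully deterministic; the higher-mean class is "positive").  A fixed
scaled threshold of 0.5 is also supported for conventional microscopy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from skimage.draw import disk as disk_pixels
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from ._log import logger


@dataclass
class CellDetection:
    x: float
    y: float
    radius: float
    raw_brightfield: float = np.nan
    raw_fitc: float = np.nan
    norm_fitc: float = np.nan
    kmeans_class: str = ""
    flags: tuple[str, ...] = field(default=())


def detect_cells(
    brightfield: np.ndarray,
    radius_range: tuple[int, int],
    sensitivity: float = 0.5,
    max_cells: int | None = None,
) -> list[CellDetection]:
    """Hough-transform circle detection on the brightfield channel.

    Accumulator peaks above ``sensitivity`` (fraction of the maximum)
    become detections, non-maximum-suppressed at a minimum center
    distance equal to the smallest radius searched.  An empty image
    yields an empty list.
    """
    img = np.asarray(brightfield, dtype=float)
    if img.ndim != 2:
        raise ValueError("brightfield must be single-channel (2-D)")
    if np.ptp(img) == 0:
        return []
    norm = (img - img.min()) / np.ptp(img)
    edges = canny(norm, sigma=2.0)
    radii = np.arange(radius_range[0], radius_range[1] + 1)
    accum = hough_circle(edges, radii)
    peak_max = accum.max()
    if peak_max <= 0:
        return []
    total = max_cells if max_cells is not None else np.inf
    _, cx, cy, r = hough_circle_peaks(
        accum,
        radii,
        min_xdistance=int(radius_range[0]),
        min_ydistance=int(radius_range[0]),
        threshold=sensitivity * peak_max,
        total_num_peaks=int(min(total, edges.size)),
    )
    dets = [CellDetection(float(x), float(y), float(rr)) for x, y, rr in zip(cx, cy, r)]
    logger.info("stage=detect_cells n=%d radius_range=%s", len(dets), radius_range)
    return dets


def _disk_mean(img: np.ndarray, det: CellDetection) -> float:
    rr, cc = disk_pixels((det.y, det.x), det.radius, shape=img.shape)
    if rr.size == 0:
        return float("nan")
    return float(img[rr, cc].mean())


def apply_detection_filters(
    detections: list[CellDetection],
    brightfield: np.ndarray,
    min_brightness: float | None = None,
    background_mask: np.ndarray | None = None,
    exclusion_band: tuple[int, int] | None = None,
) -> list[CellDetection]:
    """Drop detections failing brightness, background-mask or edge filters.

    ``exclusion_band=(lo, hi)`` drops detections whose center row lies in
    [lo, hi) — e.g. the strip near the top of a nanopen where imported
    cells localize.  With no filters configured this is the identity.
    Each drop reason is recorded on the detection's flags and logged.
    """
    kept: list[CellDetection] = []
    dropped = {"low-brightness": 0, "background-mask": 0, "edge-location": 0}
    for det in detections:
        flags: list[str] = []
        if min_brightness is not None:
            if _disk_mean(brightfield, det) < min_brightness:
                flags.append("low-brightness")
        if background_mask is not None:
            rr, cc = disk_pixels((det.y, det.x), det.radius, shape=brightfield.shape)
            if rr.size and background_mask[rr, cc].any():
                flags.append("background-mask")
        if exclusion_band is not None and exclusion_band[0] <= det.y < exclusion_band[1]:
            flags.append("edge-location")
        if flags:
            for f in flags:
                dropped[f] += 1
            det.flags = tuple(flags)
        else:
            kept.append(det)
    if any(dropped.values()):
        logger.info("stage=apply_detection_filters dropped=%s kept=%d", dropped, len(kept))
    return kept


def extract_and_normalize(fitc: np.ndarray, detections: list[CellDetection]) -> list[CellDetection]:
    """Disk-mean FITC brightness, normalized by the cohort mean.

    After normalization the mean of the normalized values over the
    detections is exactly 1.
    """
    if not detections:
        return detections
    raw = np.array([_disk_mean(np.asarray(fitc, dtype=float), d) for d in detections])
    cohort_mean = raw.mean()
    if not np.isfinite(cohort_mean) or cohort_mean == 0:
        raise ValueError("cohort mean FITC brightness is zero; cannot normalize")
    for det, r, nrm in zip(detections, raw, raw / cohort_mean):
        det.raw_fitc = float(r)
        det.norm_fitc = float(nrm)
    return detections


def kmeans_positivity(values: np.ndarray, seed: int = 0) -> tuple[np.ndarray, int]:
    """Exact 1-D 2-means split of the normalized FITC vector.

    Enumerates every split point of the sorted vector and takes the
    partition minimizing within-class sum of squares; the higher-mean
    class is "positive".  Returns (classes, positive_count).  ``seed``
    is accepted for API symmetry; the solver is deterministic.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("need >=2 distinct values to partition")
    order = np.argsort(v, kind="mergesort")
    s = v[order]
    csum = np.cumsum(s)
    total = csum[-1]
    n = s.size
    k = np.arange(1, n)
    # within-class SSE = sum(x^2) - sum_left^2/k - sum_right^2/(n-k); sum(x^2) constant
    left = csum[:-1]
    score = left**2 / k + (total - left) ** 2 / (n - k)
    best = int(np.argmax(score))  # maximize between-class term
    split = best + 1
    classes_sorted = np.array(["negative"] * split + ["positive"] * (n - split), dtype=object)
    classes = np.empty(n, dtype=object)
    classes[order] = classes_sorted
    n_pos = int((classes == "positive").sum())
    return classes, n_pos


def threshold_positivity(values: np.ndarray, threshold: float = 0.5) -> tuple[np.ndarray, int]:
    """Fixed-threshold positivity on a scaled intensity vector (> threshold)."""
    v = np.asarray(values, dtype=float).ravel()
    classes = np.where(v > threshold, "positive", "negative").astype(object)
    return classes, int((v > threshold).sum())


def percent_positive(n_positive: int, n_total: int) -> float:
    """Percent positive, rounded half-up to 1 decimal (e.g. 513/1147 -> 44.7)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_positive <= n_total):
        raise ValueError(f"n_positive={n_positive} outside [0, {n_total}]")
    pct = Decimal(100 * n_positive) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def run_fov(
    brightfield: np.ndarray,
    fitc: np.ndarray,
    radius_range: tuple[int, int],
    sensitivity: float = 0.5,
    min_brightness: float | None = None,
    exclusion_band: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[list[CellDetection], float]:
    """Full single-FOV pipeline; returns (detections, percent_positive)."""
    dets = detect_cells(brightfield, radius_range, sensitivity)
    dets = apply_detection_filters(dets, brightfield, min_brightness=min_brightness, exclusion_band=exclusion_band)
    dets = extract_and_normalize(fitc, dets)
    if len(dets) < 2:
        return dets, float("nan")
    classes, n_pos = kmeans_positivity(np.array([d.norm_fitc for d in dets]), seed=seed)
    for det, cls in zip(dets, classes):
        det.kmeans_class = str(cls)
    return dets, percent_positive(n_pos, len(dets))
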