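"""Per-glomerulus 2D morphometry from segmentation masks.

Connected glomerular-tuft components are filtered to exclude
non-representative structures (profiles cut at a frame edge, merged
structures recognised by implausible area or low solidity) and the
retained profiles are measured: tuft area, podocyte number, mean nuclear
area, areal podocyte density, nuclear/tuft area ratio, and — via Otsu
thresholding of the cytoplasmic stain inside the tuft — cytoplasm area
and cytoplasm/tuft ratio.  All areas are pixel counts divided by the
square of the pixels-per-micron calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "LabeledMask",
    "ExclusionConfig",
    "ExclusionReport",
    "MorphometryRecord",
    "label_and_filter",
    "compute_morphometrics",
    "otsu_threshold",
    "nephrin_area",
    "stain_fraction",
]


@dataclass
class LabeledMask:
    """Integer-labeled mask with pixel calibration (0 = background)."""

    labels: np.ndarray
    pixels_per_micron: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        if self.pixels_per_micron <= 0:
            raise ValueError("pixels_per_micron must be positive")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class ExclusionConfig:
    """Post-processing exclusion rules for tuft components.

    ``edge_margin_px = 0`` excludes any component touching the frame
    border.  Merged structures are flagged when the component area exceeds
    ``max_area_um2`` or its solidity falls below ``min_solidity``.
    """

    edge_margin_px: int = 0
    min_area_um2: float = 50.0
    max_area_um2: float = 1200.0
    min_solidity: float = 0.85

    def __post_init__(self) -> None:
        if self.min_area_um2 >= self.max_area_um2:
            raise ValueError("min_area_um2 must be < max_area_um2")


@dataclass
class ExclusionReport:
    """Which raw components were removed and why."""

    excluded: list[tuple[int, str]] = field(default_factory=list)

    def reasons(self) -> dict[int, str]:
        return dict(self.excluded)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.excluded, columns=["component", "reason"])


@dataclass(frozen=True)
class MorphometryRecord:
    glomerulus_id: int
    tuft_area_um2: float
    podocyte_count: int
    mean_nuclear_area_um2: float   # NaN when count == 0
    area_density_per_1e4um2: float
    nuclear_tuft_ratio: float
    cytoplasm_area_um2: float
    cytoplasm_tuft_ratio: float


def label_and_filter(binary_mask, config: ExclusionConfig, ppm: float):
    """Label a binary tuft mask and drop non-representative components.

    Components are removed when they touch the frame within
    ``edge_margin_px`` (reason ``"edge"``), are implausibly large or
    insufficiently convex (reason ``"merged"``), or fall below the minimum
    area (reason ``"small"``).  Survivors are relabeled consecutively.

    Returns ``(LabeledMask, ExclusionReport)``.
    """
    binary = np.asarray(binary_mask).astype(bool)
    if ppm <= 0:
        raise ValueError("ppm must be positive")
    raw = measure.label(binary, connectivity=2)
    report = ExclusionReport()
    out = np.zeros_like(raw, dtype=np.int32)
    next_label = 1
    h, w = raw.shape
    m = config.edge_margin_px
    border = np.zeros_like(binary)
    border[: m + 1, :] = True
    border[h - m - 1 :, :] = True
    border[:, : m + 1] = True
    border[:, w - m - 1 :] = True

    for region in measure.regionprops(raw):
        area_um2 = region.area / ppm**2
        if bool(border[raw == region.label].any()):
            report.excluded.append((region.label, "edge"))
        elif area_um2 > config.max_area_um2 or region.solidity < config.min_solidity:
            report.excluded.append((region.label, "merged"))
        elif area_um2 < config.min_area_um2:
            report.excluded.append((region.label, "small"))
        else:
            out[raw == region.label] = next_label
            next_label += 1
    return LabeledMask(out, ppm), report


def compute_morphometrics(
    tuft: LabeledMask,
    nuclei: LabeledMask,
    image_nephrin: np.ndarray | None = None,
) -> list[MorphometryRecord]:
    """Measure each retained glomerulus.

    Podocyte nuclei are assigned to the tuft containing their centroid.
    When a cytoplasmic-stain image is supplied, cytoplasm area is measured
    by Otsu thresholding the intensities inside each tuft; otherwise the
    cytoplasm columns are zero.
    """
    if tuft.labels.shape != nuclei.labels.shape:
        raise ValueError("tuft and nuclei masks must be aligned")
    ppm = tuft.pixels_per_micron
    records: list[MorphometryRecord] = []

    # nucleus centroid -> tuft label, nucleus areas
    nuc_regions = measure.regionprops(nuclei.labels)
    assignments: dict[int, list[float]] = {}
    for region in nuc_regions:
        r, c = region.centroid
        owner = int(tuft.labels[int(round(r)), int(round(c))])
        if owner > 0:
            assignments.setdefault(owner, []).append(region.area / ppm**2)

    for g in range(1, tuft.n_objects + 1):
        tuft_px = int((tuft.labels == g).sum())
        tuft_area = tuft_px / ppm**2
        areas = assignments.get(g, [])
        count = len(areas)
        mean_area = float(np.mean(areas)) if count else float("nan")
        nuclear_area = float(np.sum(areas))
        if image_nephrin is not None:
            cyto_area, _ = nephrin_area(image_nephrin, tuft, g)
        else:
            cyto_area = 0.0
        records.append(
            MorphometryRecord(
                glomerulus_id=g,
                tuft_area_um2=tuft_area,
                podocyte_count=count,
                mean_nuclear_area_um2=mean_area,
                area_density_per_1e4um2=1e4 * count / tuft_area if tuft_area > 0 else 0.0,
                nuclear_tuft_ratio=min(1.0, nuclear_area / tuft_area) if tuft_area > 0 else 0.0,
                cytoplasm_area_um2=cyto_area,
                cytoplasm_tuft_ratio=min(1.0, cyto_area / tuft_area) if tuft_area > 0 else 0.0,
            )
        )
    return records


def morphometry_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    """Records as a tidy one-row-per-glomerulus table."""
    return pd.DataFrame.from_records(
        [r.__dict__ for r in records],
        columns=["glomerulus_id", "tuft_area_um2", "podocyte_count",
                 "mean_nuclear_area_um2", "area_density_per_1e4um2",
                 "nuclear_tuft_ratio", "cytoplasm_area_um2", "cytoplasm_tuft_ratio"],
    )


def otsu_threshold(values) -> tuple[float, bool]:
    """Otsu threshold of a 1D intensity sample.

    Maximizes the between-class variance ω0·ω1·(µ0 − µ1)² over a 256-bin
    histogram of the sample (exhaustively equivalent to scanning every
    candidate threshold).  Returns ``(threshold, degenerate)`` where
    ``degenerate`` marks a constant sample, for which no meaningful
    threshold exists.

    Pixels strictly above the returned threshold are "positive".
    """
    arr = np.asarray(values)
    v = arr.astype(float).ravel()
    if v.size == 0:
        raise ValueError("need at least one pixel")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return lo, True
    if np.issubdtype(arr.dtype, np.integer) and hi - lo < 4096:
        return _otsu_integer_exact(v, int(lo), int(hi))
    hist, edges = np.histogram(v, bins=256, range=(lo, hi))
    p = hist.astype(float) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = np.where(
            (w0 > 0) & (w1 > 0), (mu_t * w0 - mu) ** 2 / (w0 * w1), -np.inf
        )
    # a threshold whose boundary bin is empty splits identically to the
    # next lower one; restrict to canonical (populated-bin) candidates so
    # exact ties between equivalent thresholds cannot arise
    sigma_b[hist == 0] = -np.inf
    k = int(np.argmax(sigma_b[:-1]))  # threshold after bin k
    return float(edges[k + 1]), False


def _otsu_integer_exact(v: np.ndarray, lo: int, hi: int) -> tuple[float, bool]:
    """Otsu scan for integer gray levels in exact rational arithmetic.

    The between-class variance at threshold t is proportional to
    (S·N0 − N·S0)² / (N0·(N − N0)) with integer class count N0 and class
    sum S0, so maximizing the fraction with arbitrary-precision integers
    gives an exact argmax (ties resolved to the lowest threshold) that is
    immune to floating-point ordering noise.
    """
    levels = np.arange(lo, hi + 1)
    hist, _ = np.histogram(v, bins=np.arange(lo, hi + 2) - 0.5)
    n = int(hist.sum())
    s = int((hist * levels).sum())
    best_k, best_num, best_den = None, -1, 1
    n0, s0 = 0, 0
    for k in range(len(levels) - 1):
        n0 += int(hist[k])
        s0 += int(hist[k]) * int(levels[k])
        if hist[k] == 0 or n0 == 0 or n0 == n:
            continue
        num = (s * n0 - n * s0) ** 2
        den = n0 * (n - n0)
        if num * best_den > best_num * den:  # exact strict improvement
            best_k, best_num, best_den = k, num, den
    return float(levels[best_k]) + 0.5, False


def nephrin_area(image, tuft: LabeledMask, glomerulus_id: int) -> tuple[float, float]:
    """Cytoplasm (stain-positive) area inside one tuft, in µm².

    Otsu-thresholds the intensity histogram restricted to the tuft; the
    above-threshold pixel count divided by ppm² is the cytoplasm area.
    Returns ``(area_um2, threshold)``; a degenerate (constant-intensity)
    tuft yields area 0.
    """
    img = np.asarray(image, dtype=float)
    sel = tuft.labels == glomerulus_id
    if not sel.any():
        raise ValueError(f"glomerulus {glomerulus_id} not present in mask")
    thr, degenerate = otsu_threshold(img[sel])
    if degenerate:
        return 0.0, thr
    area = float((img[sel] > thr).sum() / tuft.pixels_per_micron**2)
    return area, thr


def stain_fraction(image, glom_mask, threshold: float) -> float:
    """Fraction of mask pixels whose intensity exceeds the threshold."""
    sel = np.asarray(glom_mask).astype(bool)
    if not sel.any():
        raise ValueError("empty mask")
    img = np.asarray(image, dtype=float)
    return float((img[sel] > threshold).mean())
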