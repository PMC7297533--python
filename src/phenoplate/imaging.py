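"""Colony quantification from flatbed-scanner plate images.

Three modes mirror the three kinds of plate acquisition used in arrayed
colony screens:

* **batch** — endpoint colony sizes from greyscale transmission scans
  (:func:`quantify_batch`),
* **redness** — phloxine B viability scores from reflective RGB scans
  (:func:`quantify_redness`),
* **timecourse** — background-subtracted intensity sums per grid position
  over an image stack, giving one growth curve per position
  (:func:`quantify_timecourse`).

Colonies are detected by adaptive local (mean) thresholding, cleaned by
morphological opening and hole filling, and assigned to the nearest node of
an evenly spaced lattice fitted to the detected object centroids.  All
geometry is reported in original-image pixel units even when segmentation is
run on a downscaled copy for speed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color as _skcolor
from skimage import filters, measure, morphology, transform
from skimage.util import img_as_float

from .exceptions import (
    CurveLengthError,
    DimensionMismatchError,
    EmptyMaskError,
    GeometryError,
    ImageModeError,
    NoBackgroundError,
)

log = logging.getLogger(__name__)

#: Greyscale transmission scan (light shines through the plate; colony
#: darkness reflects cell mass).
TRANSMISSION_GREY = "transmission-grey"
#: Reflective RGB scan (colour photograph; used for phloxine B redness).
REFLECTIVE_RGB = "reflective-rgb"

_MIN_SIDE = 64


@dataclass(frozen=True)
class PlateImage:
    """A loaded plate photograph with intensities normalised to [0, 1].

    Parameters
    ----------
    pixels
        2-D array (greyscale) or 3-D array with 3 trailing channels (RGB).
    mode
        ``"transmission-grey"`` or ``"reflective-rgb"``.
    source_path
        Where the image came from (informational).
    timestamp
        Seconds since the start of the image series, for timecourse stacks.
    """

    pixels: np.ndarray
    mode: str
    source_path: str = ""
    timestamp: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 3:
            if px.shape[2] != 3:
                raise ImageModeError(
                    f"RGB image must have exactly 3 channels, got {px.shape[2]}"
                )
        elif px.ndim != 2:
            raise ImageModeError(f"image must be 2-D or 3-D, got ndim={px.ndim}")
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise ValueError(
                f"plate image must be at least {_MIN_SIDE}x{_MIN_SIDE} px, "
                f"got {px.shape[0]}x{px.shape[1]}"
            )
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("pixel intensities must lie in [0, 1] after loading")
        if self.mode == REFLECTIVE_RGB and px.ndim != 3:
            raise ImageModeError("reflective-rgb mode requires a 3-channel image")
        if self.mode == TRANSMISSION_GREY and px.ndim != 2:
            raise ImageModeError("transmission-grey mode requires a 2-D image")
        if self.mode not in (TRANSMISSION_GREY, REFLECTIVE_RGB):
            raise ImageModeError(f"unknown image mode {self.mode!r}")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @classmethod
    def from_file(
        cls, path: str | os.PathLike, mode: str | None = None, timestamp: float | None = None
    ) -> "PlateImage":
        """Load a JPEG/PNG/TIFF image, normalising any bit depth to [0, 1]."""
        arr = iio.imread(path)
        if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
            arr = arr[..., :3]
        arr = img_as_float(arr)
        if mode is None:
            mode = REFLECTIVE_RGB if arr.ndim == 3 else TRANSMISSION_GREY
        return cls(np.asarray(arr, dtype=float), mode, source_path=str(path), timestamp=timestamp)


@dataclass(frozen=True)
class GridSpec:
    """Colony-array layout geometry: 96 = 8x12, 384 = 16x24, 1536 = 32x48.

    Row 0 is at the image top, column 0 at the image left.  Arbitrary
    formats >= 1x1 are accepted.
    """

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must be at least 1x1")

    @classmethod
    def from_format(cls, fmt: int) -> "GridSpec":
        shapes = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}
        if fmt not in shapes:
            raise ValueError(f"unknown standard format {fmt}; use 96, 384 or 1536")
        return cls(*shapes[fmt])

    @property
    def n_positions(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class ColonyRecord:
    """One detected colony's geometry, intensity and (optionally) redness.

    ``intensity`` is the background-subtracted sum of pixel intensities over
    the colony footprint, a proxy that reflects colony thickness as well as
    area.  ``circularity`` is 4*pi*A/P^2 (~1 for a disk; capped at 1.2 to
    absorb discretisation overshoot).  ``found`` is False when no object
    occupies the grid position, in which case all geometry is zero.
    """

    row: int
    col: int
    area: float = 0.0
    intensity: float = 0.0
    circularity: float = 0.0
    perimeter: float = 0.0
    centroid_x: float = float("nan")
    centroid_y: float = float("nan")
    redness: float | None = None
    found: bool = False


@dataclass
class SegmentationMask:
    """Labelled colony mask: 0 = background, k > 0 = colony at a grid position."""

    labels: np.ndarray
    position_map: dict[int, tuple[int, int]]

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        missing = set(self.position_map) - present
        if missing:
            raise ValueError(f"labels {sorted(missing)} in position_map absent from mask")

    @property
    def position_to_label(self) -> dict[tuple[int, int], int]:
        return {pos: lab for lab, pos in self.position_map.items()}


@dataclass
class TimecourseTable:
    """One growth curve per grid position: index = timepoints (hours),
    columns keyed ``"row-col"`` hold background-subtracted intensity sums."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        t = np.asarray(self.data.index, dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.data.index, dtype=float)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.data.to_csv(path, index_label="timepoint")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "TimecourseTable":
        df = pd.read_csv(path)
        df = df.set_index(df.columns[0])
        df.index.name = "timepoint"
        return cls(df.astype(float))


# ---------------------------------------------------------------------------
# segmentation internals


def _luminance(pixels: np.ndarray) -> np.ndarray:
    return _skcolor.rgb2gray(pixels) if pixels.ndim == 3 else np.asarray(pixels, float)


def _resolve_invert(grey: np.ndarray, invert) -> bool:
    """Decide whether colonies are darker than background (-> invert).

    Auto-detection assumes colonies are the minority phase: if most pixels
    fall above the global Otsu threshold, the foreground must be dark.
    """
    if invert in (True, False):
        return bool(invert)
    if float(grey.max() - grey.min()) < 1e-6:
        raise EmptyMaskError("image has no contrast; nothing to threshold")
    t = filters.threshold_otsu(grey)
    return float((grey > t).mean()) > 0.5


def _default_block(shape: tuple[int, int], grid: GridSpec) -> int:
    # ~2x the expected colony diameter, i.e. roughly one lattice pitch
    pitch = min(shape[0] / grid.n_rows, shape[1] / grid.n_cols)
    block = max(3, int(round(pitch)))
    return block if block % 2 == 1 else block + 1


def _binarise(signal: np.ndarray, block: int) -> np.ndarray:
    th = filters.threshold_local(signal, block_size=block, method="mean", offset=-0.05)
    binary = signal > th
    binary = morphology.opening(binary, morphology.disk(1))
    return ndimage.binary_fill_holes(binary)


def _refine_footprints(signal: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Trim each object to its half-maximum contour.

    Local mean thresholding admits anti-aliased edge pixels well below half
    coverage, inflating areas by a few percent; cutting each object at
    (background + object peak) / 2 puts the boundary at 50% coverage, the
    convention under which a rendered disk of radius r has area ~pi r^2.
    """
    off = signal[labels == 0]
    if off.size == 0:
        return labels
    background = float(np.median(off))
    out = labels.copy()
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        region = labels[sl] == lab
        peak = float(signal[sl][region].max())
        if peak <= background:
            continue
        keep = region & (signal[sl] > (background + peak) / 2)
        if keep.any():
            out[sl][region & ~keep] = 0
    return out


def _fit_axis(coords: np.ndarray, diameters: np.ndarray, n_positions: int, extent: float):
    """Fit origin and pitch of an evenly spaced 1-D lattice to centroids.

    Centroids are clustered along the axis (objects in one row share a
    coordinate up to a fraction of their diameter), consecutive cluster gaps
    are snapped to integer multiples of the smallest gap, and origin/pitch
    are refined by least squares on the cluster centres.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 1:
        return float(coords[0]), float(extent) / float(n_positions)
    thr = max(2.0, 0.75 * float(np.median(diameters)))
    cs = np.sort(coords)
    breaks = np.nonzero(np.diff(cs) > thr)[0]
    centers = np.array([g.mean() for g in np.split(cs, breaks + 1)])
    if centers.size == 1:
        return float(centers[0]), float(extent) / float(n_positions)
    gaps = np.diff(centers)
    mult = np.maximum(1, np.round(gaps / gaps.min())).astype(int)
    idx = np.concatenate([[0], np.cumsum(mult)]).astype(float)
    A = np.column_stack([np.ones_like(idx), idx])
    (origin, pitch), *_ = np.linalg.lstsq(A, centers, rcond=None)
    if pitch <= 0:
        raise GeometryError("fitted lattice pitch is non-positive")
    return float(origin), float(pitch)


def _segment_grey(
    grey: np.ndarray,
    grid: GridSpec,
    scale: float = 1.0,
    local_block: int | None = None,
    invert="auto",
    min_size: int | None = None,
) -> tuple[SegmentationMask, np.ndarray]:
    """Segment a greyscale image; return full-resolution mask and the
    oriented (colonies-bright) full-resolution signal image."""
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    inv = _resolve_invert(grey, invert)
    signal = 1.0 - grey if inv else grey
    if scale < 1:
        work = transform.rescale(signal, scale, anti_aliasing=True, preserve_range=True)
    else:
        work = signal
    if local_block is not None:
        if local_block < 3 or local_block % 2 == 0:
            raise ValueError("local_block must be odd and >= 3")
        block = local_block
    else:
        block = _default_block(work.shape, grid)
    if min_size is None:
        pitch_area = (work.shape[0] / grid.n_rows) * (work.shape[1] / grid.n_cols)
        min_size = max(4, int(round(0.01 * pitch_area)))
    binary = _binarise(work, block)
    lab = measure.label(binary)
    props = [p for p in measure.regionprops(lab) if p.area >= min_size]
    if not props:
        raise EmptyMaskError("no objects detected")
    cy = np.array([p.centroid[0] for p in props])
    cx = np.array([p.centroid[1] for p in props])
    diam = np.array([p.equivalent_diameter_area for p in props])
    oy, py = _fit_axis(cy, diam, grid.n_rows, work.shape[0])
    ox, px = _fit_axis(cx, diam, grid.n_cols, work.shape[1])

    assigned: dict[tuple[int, int], measure._regionprops.RegionProperties] = {}
    for p in props:
        r = int(round((p.centroid[0] - oy) / py))
        c = int(round((p.centroid[1] - ox) / px))
        if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
            continue
        if abs(p.centroid[0] - (oy + r * py)) > py / 2 or abs(p.centroid[1] - (ox + c * px)) > px / 2:
            continue
        prev = assigned.get((r, c))
        if prev is None:
            assigned[(r, c)] = p
        elif p.area > prev.area:
            log.warning("position (%d, %d): discarding smaller duplicate object", r, c)
            assigned[(r, c)] = p
        else:
            log.warning("position (%d, %d): discarding smaller duplicate object", r, c)
    if not assigned:
        raise EmptyMaskError("no detected objects map onto the grid")

    lut = np.zeros(lab.max() + 1, dtype=np.int32)
    position_map: dict[int, tuple[int, int]] = {}
    for k, (pos, p) in enumerate(sorted(assigned.items()), start=1):
        lut[p.label] = k
        position_map[k] = pos
    newlab = lut[lab]
    if scale < 1:
        newlab = transform.resize(
            newlab, signal.shape, order=0, preserve_range=True, anti_aliasing=False
        ).astype(np.int32)
    newlab = _refine_footprints(signal, newlab)
    return SegmentationMask(newlab, position_map), signal


def segment_plate(
    image: PlateImage,
    grid: GridSpec,
    scale: float = 1.0,
    local_block: int | None = None,
    invert="auto",
    min_size: int | None = None,
) -> SegmentationMask:
    """Detect colonies and assign each to the nearest fitted lattice node.

    Objects farther than half the lattice pitch from any node are discarded;
    where two objects compete for one node the larger wins.  Raises
    :class:`EmptyMaskError` on blank images and :class:`GeometryError` when
    the fitted pitch is non-positive.
    """
    mask, _ = _segment_grey(_luminance(image.pixels), grid, scale, local_block, invert, min_size)
    return mask


def estimate_background(image: PlateImage, mask: SegmentationMask) -> float:
    """Median intensity of non-colony pixels (the plate/agar background)."""
    grey = _luminance(image.pixels)
    bg = grey[mask.labels == 0]
    if bg.size == 0:
        raise NoBackgroundError("mask covers the entire image; no background pixels")
    return float(np.median(bg))


# ---------------------------------------------------------------------------
# record extraction


def _records_from_mask(
    signal: np.ndarray,
    mask: SegmentationMask,
    grid: GridSpec,
    redness_map: np.ndarray | None = None,
) -> list[ColonyRecord]:
    labels = mask.labels
    bg_pixels = signal[labels == 0]
    if bg_pixels.size == 0:
        raise NoBackgroundError("mask covers the entire image; no background pixels")
    background = float(np.median(bg_pixels))
    props = {p.label: p for p in measure.regionprops(labels)}
    n_labels = int(labels.max())
    sums = (
        ndimage.sum_labels(signal, labels, index=np.arange(1, n_labels + 1))
        if n_labels
        else np.zeros(0)
    )
    if redness_map is not None:
        # erode footprints by one pixel so colour-blended edge pixels do not
        # dilute the colony's chromaticity average
        eroded = labels * (ndimage.minimum_filter(labels, size=3) == labels)
    pos_to_label = mask.position_to_label
    records: list[ColonyRecord] = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            lab = pos_to_label.get((r, c))
            if lab is None or lab not in props:
                rec = ColonyRecord(row=r, col=c, found=False)
                if redness_map is not None:
                    rec.redness = float("nan")
                records.append(rec)
                continue
            p = props[lab]
            perimeter = float(p.perimeter)
            circularity = (
                0.0 if perimeter <= 0 else min(4.0 * np.pi * p.area / perimeter**2, 1.2)
            )
            intensity = max(float(sums[lab - 1]) - p.area * background, 0.0)
            redness = None
            if redness_map is not None:
                sel = eroded == lab
                if not sel.any():
                    sel = labels == lab
                redness = float(redness_map[sel].mean())
            records.append(
                ColonyRecord(
                    row=r,
                    col=c,
                    area=float(p.area),
                    intensity=intensity,
                    circularity=circularity,
                    perimeter=perimeter,
                    centroid_x=float(p.centroid[1]),
                    centroid_y=float(p.centroid[0]),
                    redness=redness,
                    found=True,
                )
            )
    return records


def records_to_frame(records: Sequence[ColonyRecord]) -> pd.DataFrame:
    """Tabulate colony records (one row per grid position)."""
    df = pd.DataFrame(
        {
            "row": [r.row for r in records],
            "col": [r.col for r in records],
            "area": [r.area for r in records],
            "intensity": [r.intensity for r in records],
            "circularity": [r.circularity for r in records],
            "perimeter": [r.perimeter for r in records],
            "centroid_x": [r.centroid_x for r in records],
            "centroid_y": [r.centroid_y for r in records],
            "found": [r.found for r in records],
        }
    )
    if any(r.redness is not None for r in records):
        df.insert(8, "redness", [r.redness if r.redness is not None else np.nan for r in records])
    return df


# ---------------------------------------------------------------------------
# the three quantification modes


def quantify_batch(
    images: Iterable[PlateImage],
    grid: GridSpec,
    scale: float = 1.0,
    invert="auto",
    qc_dir: str | os.PathLike | None = None,
) -> list[tuple[str, list[ColonyRecord]]]:
    """Endpoint colony-size quantification of greyscale transmission scans.

    Each image is segmented independently; one record per grid position is
    returned (``found=False`` where empty).  A QC overlay PNG is written per
    input when ``qc_dir`` is given.
    """
    images = list(images)
    if not images:
        return []
    shape0 = images[0].pixels.shape
    results = []
    for img in images:
        if img.pixels.ndim != 2:
            raise ImageModeError("batch mode requires greyscale transmission images")
        if img.pixels.shape != shape0:
            raise DimensionMismatchError(
                f"image {img.source_path!r} has shape {img.pixels.shape}, expected {shape0}"
            )
        mask, signal = _segment_grey(img.pixels, grid, scale=scale, invert=invert)
        records = _records_from_mask(signal, mask, grid)
        if qc_dir is not None:
            _write_overlay(_overlay_path(qc_dir, img), img.pixels, mask)
        results.append((img.source_path, records))
    return results


def quantify_redness(
    image: PlateImage,
    grid: GridSpec,
    scale: float = 1.0,
    qc_dir: str | os.PathLike | None = None,
) -> list[ColonyRecord]:
    """Phloxine B viability scoring of a reflective RGB scan.

    Colonies are detected on a colour-enhanced (per-channel contrast
    stretched), background-suppressed luminance image; each colony's redness
    is the mean per-pixel chromaticity R/(R+G+B) over its footprint, an
    exposure-invariant measure computed on the original pixel values.
    """
    if image.mode != REFLECTIVE_RGB or image.pixels.ndim != 3:
        raise ImageModeError("redness mode requires a reflective RGB image")
    enhanced = _stretch_channels(image.pixels)
    grey = _skcolor.rgb2gray(enhanced)
    mask, signal = _segment_grey(grey, grid, scale=scale, invert="auto")
    s = image.pixels.sum(axis=2)
    chrom = np.where(s > 1e-9, image.pixels[..., 0] / np.maximum(s, 1e-9), 1.0 / 3.0)
    records = _records_from_mask(signal, mask, grid, redness_map=chrom)
    if qc_dir is not None:
        scores = {
            (r.row, r.col): r.redness for r in records if r.found and r.redness is not None
        }
        _write_overlay(_overlay_path(qc_dir, image), image.pixels, mask, scores=scores)
    return records


def quantify_timecourse(
    image_series: Sequence[PlateImage],
    grid: GridSpec,
    scale: float = 1.0,
    invert="auto",
) -> TimecourseTable:
    """Growth curves from an image stack.

    Colony positions are determined in the **last** image only and that mask
    is applied unchanged to all earlier images; each position's value at
    each timepoint is the sum over its fixed footprint of
    (pixel - per-image background median), clipped at 0.  Positions empty in
    the final image produce no column.
    """
    series = list(image_series)
    if len(series) < 2:
        raise CurveLengthError("timecourse mode needs at least 2 images")
    shape0 = series[0].pixels.shape
    for img in series[1:]:
        if img.pixels.shape != shape0:
            raise DimensionMismatchError("all images in a series must share dimensions")
    if all(img.timestamp is not None for img in series):
        t = np.array([img.timestamp for img in series], dtype=float) / 3600.0
    else:
        t = np.arange(len(series), dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    greys = [_luminance(img.pixels) for img in series]
    inv = _resolve_invert(greys[-1], invert)
    mask, _ = _segment_grey(greys[-1], grid, scale=scale, invert=inv)
    labels = mask.labels
    order = sorted(mask.position_map.items(), key=lambda kv: kv[1])
    label_ids = np.array([lab for lab, _ in order])
    columns = [f"{r}-{c}" for _, (r, c) in order]
    areas = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels, index=label_ids)

    values = np.zeros((len(series), len(label_ids)))
    for i, grey in enumerate(greys):
        sig = 1.0 - grey if inv else grey
        background = float(np.median(sig[labels == 0]))
        sums = ndimage.sum_labels(sig, labels, index=label_ids)
        values[i] = np.maximum(sums - areas * background, 0.0)
    return TimecourseTable(pd.DataFrame(values, index=t, columns=columns))


# ---------------------------------------------------------------------------
# helpers


def _stretch_channels(pixels: np.ndarray) -> np.ndarray:
    """Rescale each colour channel to span [0, 1] over the plate."""
    out = np.empty_like(pixels)
    for ch in range(pixels.shape[2]):
        lo, hi = float(pixels[..., ch].min()), float(pixels[..., ch].max())
        out[..., ch] = (pixels[..., ch] - lo) / (hi - lo) if hi > lo else 0.0
    return out


def _overlay_path(qc_dir: str | os.PathLike, image: PlateImage) -> str:
    os.makedirs(qc_dir, exist_ok=True)
    stem = os.path.splitext(os.path.basename(image.source_path))[0] or "plate"
    return os.path.join(qc_dir, f"{stem}_qc.png")


def _write_overlay(
    path: str,
    pixels: np.ndarray,
    mask: SegmentationMask,
    scores: dict[tuple[int, int], float] | None = None,
) -> None:
    """Write a QC overlay: detected outlines (red) and optional scores."""
    from skimage.segmentation import find_boundaries

    base = pixels if pixels.ndim == 3 else np.stack([pixels] * 3, axis=-1)
    out = base.copy()
    out[find_boundaries(mask.labels, mode="outer")] = (1.0, 0.0, 0.0)
    if scores:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        centroids = {
            pos: ndimage.center_of_mass(mask.labels == lab)
            for lab, pos in mask.position_map.items()
        }
        fig, ax = plt.subplots(figsize=(out.shape[1] / 100, out.shape[0] / 100), dpi=100)
        ax.imshow(out)
        for pos, score in scores.items():
            cy, cx = centroids[pos]
            ax.text(cx, cy, f"{score:.2f}", color="blue", fontsize=5, ha="center")
        ax.set_axis_off()
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    else:
        iio.imwrite(path, (np.clip(out, 0, 1) * 255).astype(np.uint8))
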