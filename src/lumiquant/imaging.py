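"""Reading and quantifying in-vivo bioluminescence images.

An acquisition from an in-vivo imaging system (IVIS-class instrument) is a
pair of co-registered rasters covering a group of 1-5 mice: a grayscale
brightfield photograph and a luminescence raster calibrated in radiance
units (photons s^-1 cm^-2 sr^-1).  Two luminescence dialects are supported:

* **grayscale** -- a float TIFF whose pixel values *are* radiance (lossless,
  preferred);
* **pseudocolor** -- an 8-bit RGB overlay rendered through a color ramp with
  a known min/max radiance scale; inverted here on a log axis (lossy, and
  flagged as such on the loaded image).

This module isolates individual mice from a group image, removes the tail
(whose pose dominates frame-size variability), rejects slanted animals,
rescales every mouse to a common height so anatomical regions line up
across the cohort, and computes the average radiance per pixel -- the
tumor-burden readout -- over the body mask or an arbitrary region of
interest.

Conventions: pixel origin is top-left, row index increases downward (head
at the top of the frame), all coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib
import numpy as np
import tifffile
from PIL import Image
from skimage import measure, morphology, transform

__all__ = [
    "CalibrationScale",
    "RawGroupImage",
    "CompositeMouseImage",
    "ImageQCError",
    "render_pseudocolor",
    "invert_pseudocolor",
    "load_group_image",
    "split_mice",
    "remove_tail",
    "principal_angle",
    "detect_slant",
    "normalize_and_align",
    "average_radiance",
    "rect_roi",
]


class ImageQCError(RuntimeError):
    """An image failed an automated quality-control check.

    Raised instead of returning partial results so batch drivers can log
    the offending file and exclude it from the automated run.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class CalibrationScale:
    """Radiance range (and color ramp) attached to a luminescence raster.

    ``radiance_min``/``radiance_max`` bound the displayed scale in
    photons s^-1 cm^-2 sr^-1; ``colormap_name`` identifies the pseudocolor
    ramp (any registered matplotlib colormap) and is only meaningful for
    the pseudocolor dialect.
    """

    radiance_min: float
    radiance_max: float
    colormap_name: str = "turbo"

    def __post_init__(self) -> None:
        if not self.radiance_min > 0:
            raise ValueError("radiance_min must be > 0")
        if not self.radiance_max > self.radiance_min:
            raise ValueError("radiance_max must exceed radiance_min")


@dataclass
class RawGroupImage:
    """A loaded acquisition: brightfield + calibrated radiance for 1-5 mice."""

    brightfield: np.ndarray
    radiance: np.ndarray
    acquisition_day: float
    group_id: str = ""
    experiment_id: str = ""
    calibration: CalibrationScale | None = None
    mouse_ids: tuple[str, ...] = ()
    dialect: str = "grayscale"

    def __post_init__(self) -> None:
        self.brightfield = np.asarray(self.brightfield, dtype=float)
        self.radiance = np.asarray(self.radiance, dtype=float)
        if self.brightfield.shape != self.radiance.shape:
            raise ValueError(
                "brightfield and luminescence dimensions differ: "
                f"{self.brightfield.shape} vs {self.radiance.shape}"
            )


@dataclass
class CompositeMouseImage:
    """Three co-registered layers for one mouse at one timepoint.

    ``radiance`` is zero outside ``mask``; ``pixel_area`` tracks the area of
    one pixel relative to the raw acquisition (it shrinks when the image is
    upscaled) so that total radiance ``radiance.sum() * pixel_area`` is
    conserved through resampling.  ``bbox`` locates the crop inside its
    parent group frame as (min_row, min_col, max_row, max_col), half-open.
    """

    radiance: np.ndarray
    mask: np.ndarray
    brightfield: np.ndarray
    mouse_id: str = ""
    acquisition_day: float = 0.0
    height_normalized: bool = False
    pixel_area: float = 1.0
    bbox: tuple[int, int, int, int] | None = None
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.brightfield = np.asarray(self.brightfield, dtype=float)
        if not (self.radiance.shape == self.mask.shape == self.brightfield.shape):
            raise ValueError("radiance, mask and brightfield must share dimensions")
        if not self.mask.any():
            raise ValueError("mouse mask is empty")
        # enforce the masking invariant
        self.radiance = np.where(self.mask, self.radiance, 0.0)

    @property
    def total_radiance(self) -> float:
        """Radiance integrated over the frame, corrected for pixel area."""
        return float(self.radiance.sum() * self.pixel_area)


# --------------------------------------------------------------------------
# pseudocolor rendering / inversion
# --------------------------------------------------------------------------

def _ramp_colors(name: str, n: int) -> np.ndarray:
    try:
        cmap = matplotlib.colormaps[name]
    except KeyError as exc:
        raise ValueError(f"unregistered colormap: {name!r}") from exc
    return np.asarray(cmap(np.linspace(0.0, 1.0, n)))[:, :3]


def render_pseudocolor(
    radiance: np.ndarray,
    cal: CalibrationScale,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Render a radiance field as an 8-bit RGB pseudocolor overlay.

    Pixels at or above ``radiance_min`` map log-linearly onto the color
    ramp (clipped at ``radiance_max``); dimmer pixels show the grayscale
    ``background`` (or black).  This is the forward model inverted by
    :func:`invert_pseudocolor` and is what the synthetic cohort writer uses
    for the pseudocolor dialect.
    """
    radiance = np.asarray(radiance, dtype=float)
    try:
        cmap = matplotlib.colormaps[cal.colormap_name]
    except KeyError as exc:
        raise ValueError(f"unregistered colormap: {cal.colormap_name!r}") from exc
    span = np.log(cal.radiance_max / cal.radiance_min)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.log(radiance / cal.radiance_min) / span
    u = np.clip(np.nan_to_num(u, nan=-1.0, neginf=-1.0), -1.0, 1.0)
    colored = radiance >= cal.radiance_min
    rgb = np.asarray(cmap(np.clip(u, 0.0, 1.0)))[..., :3]
    out = np.zeros(radiance.shape + (3,), dtype=np.uint8)
    if background is not None:
        g = np.clip(np.asarray(background, dtype=float), 0.0, 1.0)
        out[...] = np.round(g * 255.0)[..., None].astype(np.uint8)
    out[colored] = np.round(rgb[colored] * 255.0).astype(np.uint8)
    return out


def invert_pseudocolor(
    image: np.ndarray,
    cal: CalibrationScale,
    *,
    gray_spread: int = 40,
    lut_size: int = 8192,
) -> np.ndarray:
    """Map a pseudocolor overlay back to radiance.

    Each colored pixel is assigned the radiance whose ramp color is nearest
    in RGB space, placed log-linearly in [radiance_min, radiance_max]
    (radiance spans orders of magnitude, so the scale is interpolated on a
    log axis).  Near-gray pixels -- channel spread below ``gray_spread`` 8-bit
    counts -- are the uncolored brightfield background and map to 0.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[-1] < 3:
        raise ValueError("pseudocolor image must be an RGB raster")
    arr = arr[..., :3].astype(float)
    if arr.max() <= 1.0:
        arr = arr * 255.0
    # the ramp is sampled finely enough that every 8-bit-rendered ramp color
    # appears as a run of identical rounded entries; a rendered pixel is
    # placed at the center of its run (the best an 8-bit overlay can do)
    lut = np.round(_ramp_colors(cal.colormap_name, lut_size) * 255.0)
    keys = (lut[:, 0] * 65536 + lut[:, 1] * 256 + lut[:, 2]).astype(np.int64)
    uniq, first = np.unique(keys, return_index=True)
    centers = np.empty(len(uniq))
    for i, k in enumerate(uniq):
        pos = np.flatnonzero(keys == k)
        centers[i] = pos.mean()
    spread = arr.max(axis=-1) - arr.min(axis=-1)
    colored = spread > gray_spread
    out = np.zeros(arr.shape[:2], dtype=float)
    pix = np.round(arr[colored])
    if pix.size:
        pk = (pix[:, 0] * 65536 + pix[:, 1] * 256 + pix[:, 2]).astype(np.int64)
        loc = np.searchsorted(uniq, pk)
        loc = np.clip(loc, 0, len(uniq) - 1)
        exact = uniq[loc] == pk
        u = np.empty(len(pix))
        u[exact] = centers[loc[exact]]
        if (~exact).any():  # off-ramp color (e.g. blended): nearest entry
            miss = pix[~exact]
            d = ((miss[:, None, :] - lut[None, :, :]) ** 2).sum(axis=-1)
            u[~exact] = np.argmin(d, axis=1)
        u /= lut_size - 1
        ratio = cal.radiance_max / cal.radiance_min
        out[colored] = cal.radiance_min * ratio**u
    return out


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------

def _read_gray(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path).astype(float)
        if arr.ndim == 3:
            arr = arr.mean(axis=-1)
        if arr.max() > 1.5:  # integer-encoded grayscale
            arr = arr / 255.0
        return arr
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float) / 255.0


def load_group_image(
    brightfield_path: str | Path,
    luminescence_path: str | Path,
    meta: Mapping[str, object],
) -> RawGroupImage:
    """Load one acquisition (brightfield + luminescence) as a calibrated image.

    ``meta`` is one row of the cohort metadata table; recognised keys are
    ``experiment_id``, ``group_id``, ``mouse_ids`` (``;``-separated,
    left-to-right), ``day``, ``scale_min``, ``scale_max`` and ``colormap``.
    A float TIFF luminescence file is taken as calibrated radiance; an RGB
    PNG is the pseudocolor dialect and requires the calibration scale.
    """
    brightfield = _read_gray(brightfield_path)
    lpath = Path(luminescence_path)
    cal = None
    smin, smax = meta.get("scale_min"), meta.get("scale_max")
    if smin is not None and smax is not None and np.isfinite([smin, smax]).all():
        cal = CalibrationScale(
            float(smin), float(smax), str(meta.get("colormap", "turbo"))
        )
    if lpath.suffix.lower() in (".tif", ".tiff"):
        radiance = tifffile.imread(lpath).astype(float)
        dialect = "grayscale"
    else:
        with Image.open(lpath) as im:
            arr = np.asarray(im.convert("RGB"))
        if cal is None:
            raise ImageQCError(
                f"{lpath.name}: pseudocolor luminescence requires scale_min/scale_max "
                "calibration in the metadata row"
            )
        radiance = invert_pseudocolor(arr, cal)
        dialect = "pseudocolor"
    if radiance.shape != brightfield.shape:
        raise ImageQCError(
            f"{lpath.name}: luminescence {radiance.shape} does not match "
            f"brightfield {brightfield.shape}"
        )
    ids = meta.get("mouse_ids", "")
    mouse_ids = tuple(s for s in str(ids).split(";") if s) if ids else ()
    return RawGroupImage(
        brightfield=brightfield,
        radiance=radiance,
        acquisition_day=float(meta.get("day", 0.0)),
        group_id=str(meta.get("group_id", "")),
        experiment_id=str(meta.get("experiment_id", "")),
        calibration=cal,
        mouse_ids=mouse_ids,
        dialect=dialect,
    )


# --------------------------------------------------------------------------
# mouse isolation and cleanup
# --------------------------------------------------------------------------

def split_mice(
    img: RawGroupImage,
    *,
    bf_threshold: float = 0.2,
    min_area: int = 150,
    max_mice: int = 5,
    pad: int = 2,
) -> list[CompositeMouseImage]:
    """Isolate each mouse from a group acquisition, ordered left to right.

    The body map is the union of thresholded brightfield and nonzero
    luminescence, closed morphologically; connected components above
    ``min_area`` pixels are taken as mice.  Detecting 0 or more than
    ``max_mice`` bodies raises :class:`ImageQCError` so the image can be
    flagged for manual review.
    """
    body = (img.brightfield > bf_threshold) | (img.radiance > 0)
    body = morphology.closing(body, footprint=morphology.disk(3))
    labels = measure.label(body)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    if not 1 <= len(props) <= max_mice:
        raise ImageQCError(
            f"detected {len(props)} candidate bodies (expected 1-{max_mice}); "
            "image flagged for review"
        )
    props.sort(key=lambda p: p.centroid[1])
    out: list[CompositeMouseImage] = []
    H, W = img.radiance.shape
    for i, p in enumerate(props):
        r0, c0, r1, c1 = p.bbox
        rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
        rr1, cc1 = min(r1 + pad, H), min(c1 + pad, W)
        mask = labels[rr0:rr1, cc0:cc1] == p.label
        mouse_id = img.mouse_ids[i] if i < len(img.mouse_ids) else f"m{i}"
        out.append(
            CompositeMouseImage(
                radiance=img.radiance[rr0:rr1, cc0:cc1] * mask,
                mask=mask,
                brightfield=img.brightfield[rr0:rr1, cc0:cc1],
                mouse_id=mouse_id,
                acquisition_day=img.acquisition_day,
                bbox=(r0, c0, r1, c1),
            )
        )
    return out


def _tighten(m: CompositeMouseImage) -> CompositeMouseImage:
    """Crop all layers to the mask bounding box, updating ``bbox``."""
    rows = np.flatnonzero(m.mask.any(axis=1))
    cols = np.flatnonzero(m.mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    bbox = m.bbox
    if bbox is not None:
        bbox = (bbox[0] + r0, bbox[1] + c0, bbox[0] + r1, bbox[1] + c1)
    return replace(
        m,
        radiance=m.radiance[r0:r1, c0:c1],
        mask=m.mask[r0:r1, c0:c1],
        brightfield=m.brightfield[r0:r1, c0:c1],
        bbox=bbox,
        qc_flags=list(m.qc_flags),
    )


def remove_tail(
    m: CompositeMouseImage, *, tail_fraction: float = 0.25
) -> CompositeMouseImage:
    """Strip the caudal appendage from the body mask.

    The mask's row-wise width profile is scanned upward from the bottom of
    the frame: the maximal run of rows, below the widest torso row, whose
    width falls under ``tail_fraction`` of the torso width is classified as
    tail and cleared, and the crop is re-tightened.  A tail-less mouse is
    returned unchanged.
    """
    widths = m.mask.sum(axis=1)
    torso_row = int(np.argmax(widths))
    torso_w = widths[torso_row]
    thin = widths < tail_fraction * torso_w
    r = len(widths) - 1
    tail_rows = []
    while r > torso_row and thin[r]:
        tail_rows.append(r)
        r -= 1
    if not tail_rows:
        return m
    mask = m.mask.copy()
    mask[tail_rows, :] = False
    trimmed = replace(
        m,
        mask=mask,
        radiance=m.radiance * mask,
        qc_flags=list(m.qc_flags) + ["tail_removed"],
    )
    return _tighten(trimmed)


def principal_angle(mask: np.ndarray) -> float:
    """Deviation (degrees, >=0) of the mask's principal axis from vertical."""
    props = measure.regionprops(np.asarray(mask, dtype=int))
    if not props:
        raise ValueError("empty mask")
    return abs(float(np.degrees(props[0].orientation)))


def detect_slant(m: CompositeMouseImage, max_angle: float = 10.0) -> bool:
    """True (reject) iff the body's principal axis deviates from vertical by
    strictly more than ``max_angle`` degrees."""
    return principal_angle(m.mask) > max_angle


# --------------------------------------------------------------------------
# normalization / quantification
# --------------------------------------------------------------------------

def normalize_and_align(
    m: CompositeMouseImage,
    target_height: int,
    *,
    frame_width: int | None = None,
) -> CompositeMouseImage:
    """Rescale a (tail-free) mouse so its mask spans exactly ``target_height``
    rows, optionally embedding it centered in a frame of ``frame_width``
    columns.

    Scaling is isotropic so body proportions are preserved; ``pixel_area``
    is updated so that total radiance (sum x pixel area) is conserved
    through the resampling.
    """
    cur = _tighten(m)
    for _ in range(4):
        h, w = cur.mask.shape
        if h == target_height:
            break
        s = target_height / h
        new_w = max(1, round(w * s))
        kwargs = dict(preserve_range=True)
        rad = transform.resize(
            cur.radiance, (target_height, new_w), order=1,
            anti_aliasing=s < 1, **kwargs,
        )
        bf = transform.resize(
            cur.brightfield, (target_height, new_w), order=1,
            anti_aliasing=s < 1, **kwargs,
        )
        msk = transform.resize(
            cur.mask.astype(float), (target_height, new_w), order=1,
            anti_aliasing=False, **kwargs,
        ) >= 0.5
        area = cur.pixel_area * (h / target_height) * (w / new_w)
        cur = replace(
            cur,
            radiance=rad * msk,
            mask=msk,
            brightfield=bf,
            pixel_area=area,
            qc_flags=list(cur.qc_flags),
        )
        cur = _tighten(cur)
    cur = replace(cur, height_normalized=True, qc_flags=list(cur.qc_flags))
    if frame_width is None:
        return cur
    h, w = cur.mask.shape
    rad = np.zeros((target_height, frame_width))
    bf = np.zeros((target_height, frame_width))
    msk = np.zeros((target_height, frame_width), dtype=bool)
    centroid_c = float(np.mean(np.nonzero(cur.mask)[1]))
    off = int(round(frame_width / 2 - centroid_c))
    src0 = max(0, -off)
    dst0 = max(0, off)
    n = min(w - src0, frame_width - dst0)
    if n <= 0:
        raise ImageQCError("mouse wider than alignment frame")
    if n < w:
        cur.qc_flags.append("frame_clipped")
    rad[:, dst0 : dst0 + n] = cur.radiance[:, src0 : src0 + n]
    bf[:, dst0 : dst0 + n] = cur.brightfield[:, src0 : src0 + n]
    msk[:, dst0 : dst0 + n] = cur.mask[:, src0 : src0 + n]
    return replace(
        cur, radiance=rad, brightfield=bf, mask=msk, qc_flags=list(cur.qc_flags)
    )


def rect_roi(
    shape: tuple[int, int], r0: int, c0: int, r1: int, c1: int
) -> np.ndarray:
    """Boolean ROI for the half-open rectangle [r0:r1, c0:c1]."""
    roi = np.zeros(shape, dtype=bool)
    roi[r0:r1, c0:c1] = True
    return roi


def average_radiance(
    m: CompositeMouseImage, roi: np.ndarray | None = None
) -> float:
    """Mean radiance per pixel over mask (intersected with ``roi`` if given).

    Pixels with zero luminescence inside the mask contribute 0 to the mean
    rather than being excluded.  An empty intersection yields NaN.
    """
    if roi is None:
        sel = m.mask
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != m.mask.shape:
            raise ValueError("roi dimensions do not match the image frame")
        sel = m.mask & roi
    if not sel.any():
        return float("nan")
    return float(m.radiance[sel].mean())
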