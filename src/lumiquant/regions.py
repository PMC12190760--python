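"""Anatomical-region demarcation and per-region tumor dynamics.

Once every mouse image is tail-free, height-normalized and embedded in a
common frame, the cohort becomes a stack of co-registered three-layer
images.  Averaging each image's radiance within rows (or columns) gives a
per-image axis profile; a principal component analysis across images of
those profiles yields loading curves over the axis whose sign changes
(x-intercepts) fall at transitions between anatomically distinct zones.
Crossings of selected row components give horizontal boundaries, crossings
of selected column components give vertical ones, and together they
demarcate a grid of nine labeled anatomical regions (snout, lungs, liver,
the left/right leg bone-marrow regions bmL/bmR, ...).

Each region then gets its own radiance series per mouse, segmented by the
same phase thresholds as the whole-body series, enabling analyses of where
regional dynamics diverge from the whole-body trajectory and how strongly
regions track one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .imaging import CompositeMouseImage, average_radiance
from .phases import (
    CLASS_LABELS,
    PhaseSegmentation,
    RadianceSeries,
    segment_phases,
)

__all__ = [
    "RegionGridError",
    "RegionGrid",
    "RegionSeriesSet",
    "DEFAULT_REGION_LABELS",
    "build_average_images",
    "profile_pca",
    "ProfilePCA",
    "body_envelope",
    "zero_crossings",
    "demarcate_regions",
    "per_region_series",
    "divergence_analysis",
    "region_correlation",
]

#: 3x3 anatomical template, rows top-to-bottom, columns left-to-right in
#: image coordinates (head at the top of the frame).
DEFAULT_REGION_LABELS: tuple[tuple[str, ...], ...] = (
    ("headL", "snout", "headR"),
    ("flankL", "lungs", "flankR"),
    ("bmL", "liver", "bmR"),
)


class RegionGridError(RuntimeError):
    """The loading-curve crossings cannot produce the requested grid."""


@dataclass(frozen=True)
class RegionGrid:
    """Row/column boundaries partitioning the aligned frame into labeled
    cells.

    ``row_boundaries`` and ``col_boundaries`` are interior grid lines (row
    and column coordinates); cells are the half-open rectangles between
    consecutive boundaries (including the frame edges) and jointly cover
    the frame with no overlap.
    """

    shape: tuple[int, int]
    row_boundaries: tuple[int, ...]
    col_boundaries: tuple[int, ...]
    labels: tuple[tuple[str, ...], ...] = DEFAULT_REGION_LABELS

    def __post_init__(self) -> None:
        H, W = self.shape
        if any(not 0 < b < H for b in self.row_boundaries):
            raise ValueError("row boundaries must lie strictly inside the frame")
        if any(not 0 < b < W for b in self.col_boundaries):
            raise ValueError("col boundaries must lie strictly inside the frame")
        nr, nc = len(self.row_boundaries) + 1, len(self.col_boundaries) + 1
        if len(self.labels) != nr or any(len(r) != nc for r in self.labels):
            raise ValueError(
                f"label template is not {nr}x{nc} for these boundaries"
            )

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(name for row in self.labels for name in row)

    def cells(self) -> dict[str, tuple[slice, slice]]:
        """Mapping region name -> (row slice, column slice)."""
        H, W = self.shape
        redges = (0, *self.row_boundaries, H)
        cedges = (0, *self.col_boundaries, W)
        out: dict[str, tuple[slice, slice]] = {}
        for i in range(len(redges) - 1):
            for j in range(len(cedges) - 1):
                out[self.labels[i][j]] = (
                    slice(redges[i], redges[i + 1]),
                    slice(cedges[j], cedges[j + 1]),
                )
        return out

    def region_mask(self, name: str) -> np.ndarray:
        rs, cs = self.cells()[name]
        m = np.zeros(self.shape, dtype=bool)
        m[rs, cs] = True
        return m


# --------------------------------------------------------------------------
# stack summaries and profile PCA
# --------------------------------------------------------------------------

def _check_stack(images: Sequence[CompositeMouseImage]) -> tuple[int, int]:
    if not images:
        raise ValueError("empty image stack")
    shape = images[0].radiance.shape
    for im in images:
        if im.radiance.shape != shape:
            raise ValueError("stack images must share dimensions")
    return shape


def build_average_images(images: Sequence[CompositeMouseImage]) -> dict:
    """Pixelwise stack summaries: mean radiance, mean mask occupancy, mean
    brightfield, and the standard deviation of the boolean mask values."""
    _check_stack(images)
    rad = np.stack([im.radiance for im in images])
    msk = np.stack([im.mask.astype(float) for im in images])
    bf = np.stack([im.brightfield for im in images])
    return {
        "radiance_mean": rad.mean(axis=0),
        "mask_mean": msk.mean(axis=0),
        "brightfield_mean": bf.mean(axis=0),
        "mask_sd": msk.std(axis=0),
    }


@dataclass
class ProfilePCA:
    """PCA of per-image axis profiles: loading curves over the axis and
    explained-variance ratios (nonincreasing, summing to <= 1)."""

    axis: str
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    mean_profile: np.ndarray

    def component(self, number: int) -> np.ndarray:
        """1-based component access (component 1 = largest variance)."""
        return self.loadings[number - 1]


def profile_pca(
    images: Sequence[CompositeMouseImage],
    axis: str = "row",
    n_components: int | None = None,
) -> ProfilePCA:
    """PCA across images of per-row (or per-column) mean radiance profiles.

    Observations are images, features are the positions along the chosen
    axis (all pixel values within the same row -- or column -- averaged).
    Components are centered.  A constant stack has zero variance and is an
    error.
    """
    _check_stack(images)
    if axis not in ("row", "column"):
        raise ValueError("axis must be 'row' or 'column'")
    if len(images) < 2:
        raise ValueError("profile PCA needs at least 2 images")
    mean_ax = 1 if axis == "row" else 0
    X = np.stack([im.radiance.mean(axis=mean_ax) for im in images])
    if np.allclose(X.var(axis=0).sum(), 0.0):
        raise ValueError("stack profiles are constant; PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(X)
    return ProfilePCA(
        axis=axis,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean_profile=X.mean(axis=0),
    )


def body_envelope(
    images: Sequence[CompositeMouseImage],
    axis: str = "row",
    min_occupancy: float = 0.5,
) -> np.ndarray:
    """Boolean vector of rows (or columns) whose mean mask occupancy across
    the stack reaches ``min_occupancy`` -- the body envelope within which
    loading-curve crossings are trusted."""
    _check_stack(images)
    msk = np.stack([im.mask for im in images]).mean(axis=0)
    prof = msk.mean(axis=1 if axis == "row" else 0)
    return prof >= min_occupancy


def zero_crossings(
    curve: np.ndarray, envelope: np.ndarray | None = None
) -> list[float]:
    """Sub-pixel x-intercepts (sign changes) of a loading curve.

    A crossing between samples i and i+1 with opposite signs is placed by
    linear interpolation; an exact zero flanked by opposite signs counts
    as a crossing at that sample.  Crossings are reported only where both
    flanking samples lie inside ``envelope`` (when given).
    """
    c = np.asarray(curve, dtype=float)
    out: list[float] = []
    for i in range(len(c) - 1):
        if envelope is not None and not (envelope[i] and envelope[i + 1]):
            continue
        a, b = c[i], c[i + 1]
        if a == 0.0:
            j = i - 1
            while j >= 0 and c[j] == 0.0:
                j -= 1
            if j >= 0 and c[j] * b < 0:
                out.append(float(i))
        elif a * b < 0:
            out.append(i + a / (a - b))
    return out


def demarcate_regions(
    row_loadings: Iterable[np.ndarray],
    col_loadings: Iterable[np.ndarray],
    frame_shape: tuple[int, int],
    *,
    row_envelope: np.ndarray | None = None,
    col_envelope: np.ndarray | None = None,
    labels: tuple[tuple[str, ...], ...] = DEFAULT_REGION_LABELS,
    n_regions: int = 9,
) -> RegionGrid:
    """Build the region grid from selected loading curves.

    Horizontal boundaries are the rounded zero crossings of the selected
    row components, vertical boundaries those of the selected column
    components; curves without a sign change contribute no boundary.  The
    resulting grid must contain exactly ``n_regions`` cells, otherwise a
    :class:`RegionGridError` lists the crossings found.
    """
    rows = sorted(
        {int(round(x)) for c in row_loadings
         for x in zero_crossings(c, row_envelope)}
    )
    cols = sorted(
        {int(round(x)) for c in col_loadings
         for x in zero_crossings(c, col_envelope)}
    )
    if (len(rows) + 1) * (len(cols) + 1) != n_regions:
        raise RegionGridError(
            f"crossings yield {(len(rows) + 1)}x{(len(cols) + 1)} cells, "
            f"not {n_regions}: row crossings {rows}, column crossings {cols}"
        )
    return RegionGrid(
        shape=frame_shape,
        row_boundaries=tuple(rows),
        col_boundaries=tuple(cols),
        labels=labels,
    )


# --------------------------------------------------------------------------
# per-region series and cohort analyses
# --------------------------------------------------------------------------

@dataclass
class RegionSeriesSet:
    """One mouse's whole-body series plus one series per region, all on the
    same acquisition days, each with its phase segmentation.  The
    whole-body entry is keyed ``"all"``."""

    mouse_id: str
    series: dict[str, RadianceSeries]
    segmentations: dict[str, PhaseSegmentation]
    flags: dict[str, list[str]] = field(default_factory=dict)

    @property
    def labels(self) -> dict[str, str]:
        return {k: seg.label for k, seg in self.segmentations.items()}


def per_region_series(
    mouse_id: str,
    images_by_day: Sequence[tuple[float, CompositeMouseImage]],
    grid: RegionGrid,
    *,
    floor: float = 1e3,
    growth_end_ratio: float = 0.75,
    relapse_ratio: float = 3.0,
) -> RegionSeriesSet:
    """Quantify and segment one mouse's radiance per region over time.

    For each day, the average radiance per pixel is computed over the body
    mask within each grid cell (and over the whole mask for the ``"all"``
    series).  A region with no mask pixels on some day is held at the
    detection floor and flagged.  Each series is then segmented by the
    standard phase thresholds.
    """
    if not images_by_day:
        raise ValueError("no images supplied")
    days = np.array([d for d, _ in images_by_day], dtype=float)
    order = np.argsort(days)
    days = days[order]
    imgs = [images_by_day[i][1] for i in order]
    for im in imgs:
        if im.radiance.shape != grid.shape:
            raise ValueError("image frame does not match the region grid")
    names = ("all",) + grid.region_names
    cell_masks = {nm: grid.region_mask(nm) for nm in grid.region_names}
    values: dict[str, list[float]] = {nm: [] for nm in names}
    flags: dict[str, list[str]] = {nm: [] for nm in names}
    for day, im in zip(days, imgs):
        values["all"].append(average_radiance(im))
        for nm in grid.region_names:
            v = average_radiance(im, roi=cell_masks[nm])
            if np.isnan(v):
                flags[nm].append(f"empty@{day:g}")
                v = floor
            values[nm].append(v)
    series: dict[str, RadianceSeries] = {}
    segs: dict[str, PhaseSegmentation] = {}
    for nm in names:
        v = np.maximum(np.asarray(values[nm]), floor)
        s = RadianceSeries(
            mouse_id=mouse_id, days=days, values=v,
            scope="whole-body" if nm == "all" else nm,
        )
        series[nm] = s
        segs[nm] = segment_phases(
            s, growth_end_ratio, relapse_ratio, floor=floor
        )
    return RegionSeriesSet(
        mouse_id=mouse_id, series=series, segmentations=segs,
        flags={k: v for k, v in flags.items() if v},
    )


def _label_frame(sets: Sequence[RegionSeriesSet]) -> pd.DataFrame:
    rows = []
    for s in sets:
        row = {"mouse_id": s.mouse_id}
        row.update(s.labels)
        rows.append(row)
    return pd.DataFrame(rows).set_index("mouse_id")


def divergence_analysis(
    sets: Sequence[RegionSeriesSet],
    *,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Where do regional dynamics diverge from the whole-body trajectory?

    Returns two frames.  The first gives, per region, the fraction of mice
    whose regional class label differs from their whole-body label.  The
    second crosses overall class against regional class: for every
    (region, overall class, region class) cell it reports the observed
    fraction of mice, the identity-line expectation (the overall-class
    marginal on the diagonal, zero off it), their residual, a seeded
    bootstrap-over-mice confidence interval for that residual, and a flag
    for cells whose interval excludes zero.
    """
    if not sets:
        raise ValueError("no mice supplied")
    df = _label_frame(sets)
    regions = [c for c in df.columns if c != "all"]
    n = len(df)
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    overall = df["all"].to_numpy()
    classes = list(CLASS_LABELS)
    cls_idx = {c: i for i, c in enumerate(classes)}
    ov = np.array([cls_idx[c] for c in overall])

    div_rows, res_rows = [], []
    for region in regions:
        reg = np.array([cls_idx[c] for c in df[region].to_numpy()])
        div_rows.append(
            {"region": region, "divergence": float(np.mean(reg != ov)),
             "n_mice": n}
        )
        # observed and bootstrap cell fractions, vectorized over resamples
        flat = ov * len(classes) + reg
        obs = np.bincount(flat, minlength=len(classes) ** 2) / n
        marg = np.bincount(ov, minlength=len(classes)) / n
        boot = np.stack([
            np.bincount(flat[idx], minlength=len(classes) ** 2) / n
            for idx in boot_idx
        ])
        boot_marg = np.stack([
            np.bincount(ov[idx], minlength=len(classes)) / n
            for idx in boot_idx
        ])
        for a, ca in enumerate(classes):
            for b, cb in enumerate(classes):
                cell = a * len(classes) + b
                expected = marg[a] if a == b else 0.0
                resid = obs[cell] - expected
                bres = boot[:, cell] - (boot_marg[:, a] if a == b else 0.0)
                lo, hi = np.quantile(bres, [alpha / 2, 1 - alpha / 2])
                res_rows.append({
                    "region": region, "overall_class": ca, "region_class": cb,
                    "observed": float(obs[cell]), "expected": float(expected),
                    "residual": float(resid),
                    "ci_low": float(lo), "ci_high": float(hi),
                    "significant": bool(lo > 0.0 or hi < 0.0),
                })
    return pd.DataFrame(div_rows), pd.DataFrame(res_rows)


def region_correlation(
    sets: Sequence[RegionSeriesSet],
    *,
    method: str = "pearson",
    floor: float = 1e3,
) -> pd.DataFrame:
    """Pairwise correlation of log10 radiance between the whole body and
    every region, pooled across mice and days.

    Linear (Pearson) correlation on log10 values by default -- dynamics
    span decades -- with rank (Spearman) available via ``method``.  Values
    at/below the detection floor are treated as missing and dropped
    pairwise.  The matrix is symmetric with unit diagonal.
    """
    if len(sets) < 2:
        raise ValueError("need at least two mice")
    frames = []
    for s in sets:
        cols = {}
        for nm, series in s.series.items():
            v = series.values.astype(float).copy()
            v[v <= floor] = np.nan
            cols[nm] = np.log10(v)
        frames.append(pd.DataFrame(cols))
    pooled = pd.concat(frames, ignore_index=True)
    names = ["all"] + [c for c in pooled.columns if c != "all"]
    return pooled[names].corr(method=method)
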